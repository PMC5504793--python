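import numpy as np
import pytest
from scipy import stats

import treegs
from treegs.predict import (center_markers, gblup_to_marker_effects,
                            gibbs_fit, rrblup_effects)


class TestREML:
    def test_identity_kinship_reduces_to_ols_fixed_effects(self):
        rng = np.random.default_rng(0)
        n = 120
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        y = X @ np.array([2.0, 1.0]) + rng.normal(0, 1, n)
        fit = treegs.reml_fit(y, X, np.eye(n))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.b_hat, ols, atol=1e-6)

    def test_null_heritability_hits_boundary(self):
        rng = np.random.default_rng(1)
        h2s = []
        for seed in range(5):
            cfg = treegs.SimConfig(ne=30, n_chrom=3, chrom_len_bp=10_000_000,
                                   n_markers=500, n_families=10,
                                   progeny_per_family=15, fst=0.0, n_qtl=50,
                                   h2_true=0.0, missing_rate=0.0, seed=seed)
            sim = treegs.simulate_population(cfg)
            gi = treegs.impute_mean(treegs.filter_snps(sim.genotypes))
            G = treegs.grm_vanraden(gi).values
            y = sim.phenotypes["trait"].to_numpy()
            X = treegs.build_design(sim.phenotypes)
            h2s.append(treegs.reml_fit(y, X, G).vc.h2)
        assert np.median(h2s) < 0.05

    def test_variance_components_nonnegative_and_h2_bounded(self, small_sim,
                                                            small_imputed):
        y = small_sim.phenotypes["trait"].to_numpy()
        X = treegs.build_design(small_sim.phenotypes)
        G = treegs.grm_vanraden(small_imputed).values
        fit = treegs.reml_fit(y, X, G)
        assert fit.vc.sigma2_a >= 0 and fit.vc.sigma2_e >= 0
        assert 0 <= fit.vc.h2 <= 1
        assert fit.vc.sigma2_y == pytest.approx(
            fit.vc.sigma2_a + fit.vc.sigma2_e)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            treegs.reml_fit(np.ones(3), np.ones((3, 2)), np.eye(3))


class TestRRBLUP:
    def test_single_marker_closed_form(self):
        rng = np.random.default_rng(2)
        n = 50
        z = rng.normal(0, 1, n)
        X = np.ones((n, 1))
        y = 0.5 * z + rng.normal(0, 1, n)
        s2m, s2e = 0.3, 1.0
        m = rrblup_effects(y, X, z[:, None], s2m, s2e,
                           b_hat=np.array([y.mean()]))
        yc = y - y.mean()
        # scalar ridge: m = z'yc / (z'z + s2e/s2m)
        expected = float(z @ yc / (z @ z + s2e / s2m))
        assert m[0] == pytest.approx(expected, rel=1e-8)

    def test_zero_markers_give_zero_effects(self):
        y = np.random.default_rng(3).normal(0, 1, 30)
        m = rrblup_effects(y, np.ones((30, 1)), np.zeros((30, 5)), 0.1, 1.0)
        np.testing.assert_allclose(m, 0.0, atol=1e-12)

    def test_gblup_equivalence_small(self):
        rng = np.random.default_rng(4)
        Z = rng.integers(0, 3, size=(80, 200)).astype(float)
        X = np.ones((80, 1))
        y = (Z - Z.mean(0)) @ rng.normal(0, 0.1, 200) + rng.normal(0, 1, 80)
        fit, m, Zc, _ = gblup_to_marker_effects(y, X, Z)
        np.testing.assert_allclose(Zc @ m, fit.a_hat,
                                   atol=1e-6 * y.std())


class TestGibbs:
    def test_brr_fixed_variances_matches_conjugate_ridge(self):
        rng = np.random.default_rng(5)
        n, p = 80, 20
        Z = rng.integers(0, 3, size=(n, p)).astype(float)
        X = np.ones((n, 1))
        y = (Z - Z.mean(0)) @ rng.normal(0, 0.3, p) + rng.normal(0, 1, n)
        s2m, s2e = 0.09, 1.0
        post = gibbs_fit(y, X, Z, "brr", n_iter=6000, burn_in=1000, thin=1,
                         seed=7, fixed_sigma2_m=s2m, fixed_sigma2_e=s2e)
        Zc, _ = center_markers(Z)
        A = Zc.T @ Zc + (s2e / s2m) * np.eye(p)
        m_exact = np.linalg.solve(A, Zc.T @ (y - y.mean()))
        post_sd = np.sqrt(np.diag(np.linalg.inv(A)) * s2e)
        # 3 Monte-Carlo standard errors with a conservative ESS
        mcse = 3 * post_sd / np.sqrt(500)
        assert np.all(np.abs(post.marker_effect_means - m_exact) < mcse)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        Z = rng.integers(0, 3, size=(40, 30)).astype(float)
        y = rng.normal(0, 1, 40)
        X = np.ones((40, 1))
        a = gibbs_fit(y, X, Z, "bayes_c_pi", n_iter=300, burn_in=100, thin=2,
                      seed=11)
        b = gibbs_fit(y, X, Z, "bayes_c_pi", n_iter=300, burn_in=100, thin=2,
                      seed=11)
        np.testing.assert_array_equal(a.marker_effect_means,
                                      b.marker_effect_means)
        np.testing.assert_array_equal(a.h2_samples, b.h2_samples)

    def test_null_trait_posterior_h2_near_zero(self):
        # spike-and-slab prior: under a null trait the model empties and the
        # genomic variance share concentrates at zero
        rng = np.random.default_rng(7)
        Z = rng.integers(0, 3, size=(300, 200)).astype(float)
        y = rng.normal(0, 1, 300)          # independent of Z
        X = np.ones((300, 1))
        post = gibbs_fit(y, X, Z, "bayes_c_pi", n_iter=1500, burn_in=500,
                         thin=2, seed=8)
        assert np.median(post.h2_samples) < 0.1

    def test_bayes_b_localizes_signal_on_qtl(self):
        rng = np.random.default_rng(9)
        n, p, nq = 200, 300, 10
        Z = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        qtl = rng.choice(p, nq, replace=False)
        beta = np.zeros(p)
        beta[qtl] = rng.choice([-1, 1], nq) * 0.6
        Zc = Z - Z.mean(0)
        g = Zc @ beta
        y = g + rng.normal(0, g.std() * 0.7, n)
        post = gibbs_fit(y, np.ones((n, 1)), Z, "bayes_b", n_iter=2000,
                         burn_in=500, thin=2, seed=10)
        absm = np.abs(post.marker_effect_means)
        null = np.setdiff1d(np.arange(p), qtl)
        stat = stats.mannwhitneyu(absm[qtl], absm[null],
                                  alternative="greater")
        assert stat.pvalue < 0.01

    @pytest.mark.parametrize("method", ["brr", "bayes_a", "bayes_b",
                                        "bayes_c_pi", "bl"])
    def test_all_methods_run_and_recover_signal_direction(self, method):
        rng = np.random.default_rng(12)
        n, p = 120, 60
        Z = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        beta = rng.normal(0, 0.3, p)
        y = (Z - Z.mean(0)) @ beta + rng.normal(0, 1.0, n)
        post = gibbs_fit(y, np.ones((n, 1)), Z, method, n_iter=800,
                         burn_in=300, thin=2, seed=13)
        gebv = (Z - Z.mean(0)) @ post.marker_effect_means
        truth = (Z - Z.mean(0)) @ beta
        assert np.corrcoef(gebv, truth)[0, 1] > 0.5
        assert 0 <= post.h2_mean <= 1

    def test_bad_chain_rejected(self):
        with pytest.raises(ValueError):
            gibbs_fit(np.ones(10), np.ones((10, 1)), np.zeros((10, 2)),
                      "brr", n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            gibbs_fit(np.ones(10), np.ones((10, 1)), np.zeros((10, 2)),
                      "bogus")


class TestPredictiveAbility:
    def test_identity_and_antiordered(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert treegs.predictive_ability(y, y) == pytest.approx(1.0)
        assert treegs.predictive_ability(y, -y) == pytest.approx(-1.0)

    def test_toy_hand_computed(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        g = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # by hand: sum of cross products 8, both sums of squares 10 -> 0.8
        assert treegs.predictive_ability(y, g) == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            treegs.predictive_ability(np.ones(5), np.arange(5.0))


class TestCrossValidation:
    def test_folds_partition_everyone(self, small_sim, small_imputed):
        y = small_sim.phenotypes["trait"].to_numpy()
        X = treegs.build_design(small_sim.phenotypes)
        G = treegs.grm_vanraden(small_imputed).values
        cv = treegs.cross_validate(y, X, "gblup", K=G, k_folds=5, seed=3)
        assert len(cv.fold_assignments) == len(y)
        assert set(cv.fold_assignments) == set(range(5))
        assert np.all(np.abs(cv.fold_r) <= 1)
        assert cv.mean_r == pytest.approx(cv.fold_r.mean())

    def test_null_trait_cv_centered_on_zero(self):
        rs = []
        for seed in range(3):
            cfg = treegs.SimConfig(ne=30, n_chrom=3, chrom_len_bp=10_000_000,
                                   n_markers=500, n_families=10,
                                   progeny_per_family=12, fst=0.0, n_qtl=50,
                                   h2_true=0.0, missing_rate=0.0, seed=seed)
            sim = treegs.simulate_population(cfg)
            gi = treegs.impute_mean(treegs.filter_snps(sim.genotypes))
            G = treegs.grm_vanraden(gi).values
            y = sim.phenotypes["trait"].to_numpy()
            X = treegs.build_design(sim.phenotypes)
            rs.append(treegs.cross_validate(y, X, "gblup", K=G, k_folds=5,
                                            seed=seed).mean_r)
        assert abs(np.mean(rs)) < 0.15

    def test_kinship_and_marker_routes_agree_in_cv(self, small_sim,
                                                   small_imputed):
        y = small_sim.phenotypes["trait"].to_numpy()
        X = treegs.build_design(small_sim.phenotypes)
        G = treegs.grm_vanraden(small_imputed).values
        cv_k = treegs.cross_validate(y, X, "gblup", K=G, k_folds=4, seed=5)
        cv_m = treegs.cross_validate(y, X, "rrblup", Z=small_imputed.dosage,
                                     k_folds=4, seed=5)
        np.testing.assert_allclose(cv_k.fold_r, cv_m.fold_r, atol=0.02)

    def test_invalid_folds_rejected(self, small_sim, small_imputed):
        y = small_sim.phenotypes["trait"].to_numpy()
        X = treegs.build_design(small_sim.phenotypes)
        with pytest.raises(ValueError):
            treegs.cross_validate(y, X, "gblup", K=np.eye(len(y)), k_folds=1)
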