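import numpy as np
import pandas as pd
import pytest

import treegs
from treegs.geno import GenotypeMatrix


def _geno(dos):
    n, p = dos.shape
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)],
                          markers=[f"m{j}" for j in range(p)],
                          dosage=np.asarray(dos, float),
                          chrom=np.repeat("Chr01", p),
                          pos_bp=(np.arange(p) + 1) * 1000)


class TestPedigreeA:
    def test_half_sibs_quarter_unrelated_zero(self):
        ped = pd.DataFrame({"id": ["a", "b", "c"],
                            "mother": ["M1", "M1", "M2"]})
        A = treegs.pedigree_A(ped)
        np.testing.assert_allclose(np.diag(A.values), 1.0)
        assert A.values[0, 1] == 0.25
        assert A.values[0, 2] == 0.0

    def test_matches_bruteforce_tabular_rule(self, small_sim):
        A = treegs.pedigree_A(small_sim.pedigree)
        moms = small_sim.pedigree["mother"].to_numpy()
        n = len(moms)
        expected = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                expected[i, j] = 1.0 if i == j else \
                    (0.25 if moms[i] == moms[j] else 0.0)
        np.testing.assert_array_equal(A.values, expected)

    def test_missing_family_rejected(self):
        ped = pd.DataFrame({"id": ["a"], "mother": [np.nan]})
        with pytest.raises(ValueError):
            treegs.pedigree_A(ped)

    def test_singleton_families_have_zero_offdiagonal(self):
        ped = pd.DataFrame({"id": list("abcd"),
                            "mother": ["M1", "M2", "M3", "M4"]})
        A = treegs.pedigree_A(ped).values
        assert np.all(A[~np.eye(4, dtype=bool)] == 0)


class TestGRM:
    def test_vanraden_matches_formula_on_toy(self):
        dos = np.array([[0, 1, 2, 1], [2, 1, 0, 1], [1, 1, 1, 1],
                        [0, 0, 2, 2], [2, 2, 0, 0]], float)
        G = treegs.grm_vanraden(_geno(dos)).values
        p = dos.mean(0) / 2
        W = dos - 2 * p
        expected = W @ W.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(G, expected, atol=1e-12)

    def test_clone_offdiagonal_equals_diagonal(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.4, size=50).astype(float)
        dos = np.vstack([base, base,
                         rng.binomial(2, 0.4, size=(6, 50)).astype(float)])
        G = treegs.grm_vanraden(_geno(dos)).values
        assert G[0, 1] == pytest.approx(G[0, 0], abs=1e-10)
        P = treegs.grm_powell(_geno(dos)).values
        # Powell diagonal uses the within-individual (1+F) estimator, so the
        # clone off-diagonal only tracks it approximately, but it towers over
        # unrelated pairs
        assert P[0, 1] == pytest.approx(0.5 * (P[0, 0] + P[1, 1]), abs=0.25)
        others = P[0, 2:]
        assert P[0, 1] > others.max() + 0.3

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.3, size=(20, 40)).astype(float)
        G1 = treegs.grm_vanraden(_geno(dos)).values
        G2 = treegs.grm_vanraden(_geno(2.0 - dos)).values
        np.testing.assert_allclose(G1, G2, atol=1e-10)

    def test_mean_diagonal_near_one_on_equilibrium(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 300),
                           size=(200, 300)).astype(float)
        G = treegs.grm_vanraden(_geno(dos)).values
        assert abs(np.diag(G).mean() - 1.0) < 0.1

    def test_powell_unrelated_near_zero_and_tracks_vanraden(self, small_imputed):
        G = treegs.grm_vanraden(small_imputed).values
        P = treegs.grm_powell(small_imputed).values
        off = ~np.eye(G.shape[0], dtype=bool)
        r = np.corrcoef(G[off], P[off])[0, 1]
        assert r > 0.9
        # equilibrium unrelated panel: Powell off-diagonals center on zero
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, rng.uniform(0.2, 0.5, 400),
                           size=(100, 400)).astype(float)
        P2 = treegs.grm_powell(_geno(dos)).values
        off2 = ~np.eye(100, dtype=bool)
        assert abs(P2[off2].mean()) < 0.02

    def test_missing_rejected(self, small_sim):
        with pytest.raises(ValueError, match="impute"):
            treegs.grm_vanraden(treegs.filter_snps(small_sim.genotypes))


class TestPCA:
    def test_eigenvalue_sum_equals_trace(self, small_imputed):
        G = treegs.grm_vanraden(small_imputed).values
        scores, w = treegs.pca(small_imputed,
                               n_components=small_imputed.n_samples)
        assert w.sum() == pytest.approx(np.trace(G), rel=1e-8)
        assert (np.diff(w) <= 1e-9).all()

    def test_agrees_with_svd_route(self, small_imputed):
        dos = small_imputed.dosage
        p = dos.mean(0) / 2
        W = (dos - 2 * p) / np.sqrt(2 * np.sum(p * (1 - p)))
        U, s, _ = np.linalg.svd(W, full_matrices=False)
        svd_scores = U[:, :3] * s[:3]
        scores, _ = treegs.pca(small_imputed, 3)
        for k in range(3):
            agree = min(np.abs(svd_scores[:, k] - scores[:, k]).max(),
                        np.abs(svd_scores[:, k] + scores[:, k]).max())
            assert agree < 1e-8

    def test_clones_coincide(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, 0.4, size=100).astype(float)
        dos = np.vstack([base, base,
                         rng.binomial(2, 0.4, size=(10, 100)).astype(float)])
        scores, _ = treegs.pca(_geno(dos), 3)
        np.testing.assert_allclose(scores[0], scores[1], atol=1e-8)

    def test_recovers_island_labels(self):
        from treegs.kinship import _kmeans2
        accs = []
        for seed in range(3):
            cfg = treegs.SimConfig(
                ne=40, n_chrom=3, chrom_len_bp=10_000_000, n_markers=2000,
                n_families=30, progeny_per_family=5, fst=0.1, n_qtl=50,
                h2_true=0.4, n_blocks=5, missing_rate=0.0, seed=seed)
            sim = treegs.simulate_population(cfg)
            gi = treegs.impute_mean(treegs.filter_snps(sim.genotypes))
            scores, _ = treegs.pca(gi, 2)
            lab = _kmeans2(scores[:, :2], np.random.default_rng(0))
            truth = sim.truth["subpop"]
            accs.append(max((lab == truth).mean(), (lab != truth).mean()))
        assert np.mean(accs) >= 0.95, accs

    def test_too_many_components_rejected(self, small_imputed):
        with pytest.raises(ValueError):
            treegs.pca(small_imputed, small_imputed.n_samples + 1)


class TestSplit:
    def test_unrelated_split_reduces_cross_set_relationship(
            self, small_sim, small_imputed):
        scores, _ = treegs.pca(small_imputed, 2)
        ids = list(small_sim.phenotypes["id"])
        plan = treegs.make_split(scores, ids, mode="unrelated", seed=0)
        assert not set(plan.train_ids) & set(plan.valid_ids)
        G = treegs.grm_vanraden(small_imputed).values
        pos = {s: i for i, s in enumerate(ids)}
        t = [pos[s] for s in plan.train_ids]
        v = [pos[s] for s in plan.valid_ids]
        cross = G[np.ix_(t, v)].mean()
        within_t = G[np.ix_(t, t)][~np.eye(len(t), dtype=bool)].mean()
        within_v = G[np.ix_(v, v)][~np.eye(len(v), dtype=bool)].mean()
        assert cross < 0.5 * (within_t + within_v)

    def test_random_split_sizes(self, small_sim, small_imputed):
        scores, _ = treegs.pca(small_imputed, 2)
        ids = list(small_sim.phenotypes["id"])
        plan = treegs.make_split(scores, ids, mode="random", sizes=(60, 40),
                                 seed=1)
        assert len(plan.train_ids) == 60 and len(plan.valid_ids) == 40
        assert not set(plan.train_ids) & set(plan.valid_ids)

    def test_psd_repair(self):
        K = treegs.KinshipMatrix(ids=["a", "b"],
                                 values=np.array([[1.0, 1.2], [1.2, 1.0]]),
                                 method="vanraden")
        fixed = K.ensure_psd()
        assert np.linalg.eigvalsh(fixed.values).min() >= -1e-12
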