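import numpy as np
import pandas as pd
import pytest

import treegs
import treegs.simpop as sp


def hudson_fst(p1, p2, n1, n2):
    """Brute-force Hudson allele-frequency Fst estimator."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return num[ok].sum() / den[ok].sum()


class TestConfig:
    @pytest.mark.parametrize("bad", [
        dict(ne=1), dict(fst=1.0), dict(fst=-0.1), dict(h2_true=1.5),
        dict(n_qtl=10_000), dict(n_blocks=0), dict(missing_rate=1.0),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            treegs.SimConfig(n_markers=500, **bad)

    def test_qtl_without_heritability_is_degenerate(self):
        cfg = treegs.SimConfig(ne=10, n_markers=100, n_qtl=0, h2_true=0.3,
                               fst=0.0, n_families=5, progeny_per_family=4)
        pool = sp.simulate_base(cfg, generations=0)
        g, ped = sp.sample_op_families(pool, cfg)
        with pytest.raises(ValueError, match="degenerate"):
            sp.simulate_trait(g, ped, cfg)


class TestBasePool:
    def test_no_drift_preserves_initial_frequencies(self):
        cfg = treegs.SimConfig(ne=200, n_chrom=1, chrom_len_bp=1_000_000,
                               n_markers=400, ascertainment_oversample=1,
                               fst=0.0, seed=3)
        pool = sp.simulate_base(cfg, generations=0)
        realized = pool.haplotypes.mean(axis=0)
        # realized frequencies are binomial draws around the initialization
        r = np.corrcoef(realized, pool.init_freq)[0, 1]
        assert r > 0.95

    def test_marker_count_exceeding_sites_rejected(self):
        cfg = treegs.SimConfig(ne=5, n_chrom=1, chrom_len_bp=50,
                               n_markers=40, n_qtl=0, fst=0.0,
                               ascertainment_oversample=2)
        with pytest.raises(ValueError, match="sites"):
            sp.simulate_base(cfg, generations=0)

    def test_two_island_fst_matches_target(self):
        fsts = []
        for seed in range(3):
            cfg = treegs.SimConfig(ne=50, n_chrom=4, chrom_len_bp=30_000_000,
                                   n_markers=800, fst=0.1, seed=seed,
                                   missing_rate=0.0)
            pool = sp.simulate_base(cfg)
            rows = pool.subpop.repeat(2)
            a = pool.haplotypes[rows == 0].mean(axis=0)
            b = pool.haplotypes[rows == 1].mean(axis=0)
            fsts.append(hudson_fst(a, b, 2 * cfg.ne, 2 * cfg.ne))
        assert 0.05 <= np.mean(fsts) <= 0.15


class TestFamilies:
    def test_family_layout_and_dosage_domain(self, small_cfg, small_sim):
        g, ped = small_sim.genotypes, small_sim.pedigree
        assert g.n_samples == small_cfg.n_families * small_cfg.progeny_per_family
        assert ped.groupby("family").size().nunique() == 1
        vals = g.dosage[~np.isnan(g.dosage)]
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0}
        assert np.all(g.maf[~np.isnan(g.maf)] <= 0.5 + 1e-12)
        # every individual has exactly one mother, block, subpopulation
        assert ped["mother"].notna().all()
        assert small_sim.phenotypes["block"].notna().all()

    def test_family_demand_exceeding_pool_rejected(self):
        cfg = treegs.SimConfig(ne=5, n_markers=50, n_qtl=10, n_families=10,
                               fst=0.0)
        pool = sp.simulate_base(cfg, generations=0)
        with pytest.raises(ValueError, match="exceeds"):
            sp.sample_op_families(pool, cfg)

    def test_within_family_genomic_relationship_near_quarter(self):
        vals = []
        for seed in range(3):
            cfg = treegs.SimConfig(ne=60, n_chrom=3, chrom_len_bp=20_000_000,
                                   n_markers=1000, n_families=24,
                                   progeny_per_family=8, fst=0.0,
                                   missing_rate=0.0, seed=seed)
            sim = treegs.simulate_population(cfg)
            gi = treegs.impute_mean(treegs.filter_snps(sim.genotypes))
            G = treegs.grm_vanraden(gi).values
            fam = sim.pedigree["family"].to_numpy()
            same = fam[:, None] == fam[None, :]
            off = ~np.eye(len(fam), dtype=bool)
            vals.append(G[same & off].mean())
        assert abs(np.mean(vals) - 0.25) < 0.05

    def test_dosage_is_sum_of_two_gametes(self, small_sim):
        dos = small_sim.genotypes.dosage
        vals = dos[~np.isnan(dos)]
        assert vals.min() >= 0 and vals.max() <= 2


class TestTrait:
    def test_realized_h2_matches_target(self, small_cfg, small_sim):
        assert abs(small_sim.truth["realized_h2"] - small_cfg.h2_true) < 0.1

    def test_zero_heritability_gives_uninformative_phenotype(self):
        cfg = treegs.SimConfig(ne=30, n_chrom=2, chrom_len_bp=10_000_000,
                               n_markers=400, n_families=10,
                               progeny_per_family=20, fst=0.0, n_qtl=50,
                               h2_true=0.0, missing_rate=0.0, seed=5)
        sim = treegs.simulate_population(cfg)
        r = np.corrcoef(sim.truth["bv"],
                        sim.phenotypes["trait"].to_numpy())[0, 1]
        # sampling noise of a correlation at n=200 is ~0.07
        assert abs(r) < 0.25
        assert sim.truth["realized_h2"] < 0.01

    def test_full_heritability_no_blocks_recovers_bv_exactly(self):
        cfg = treegs.SimConfig(ne=30, n_chrom=2, chrom_len_bp=10_000_000,
                               n_markers=400, n_families=10,
                               progeny_per_family=10, fst=0.0, n_qtl=50,
                               h2_true=1.0, block_sd=0.0, missing_rate=0.0,
                               seed=6)
        sim = treegs.simulate_population(cfg)
        y = sim.phenotypes["trait"].to_numpy()
        np.testing.assert_allclose(y, sim.truth["bv"], atol=1e-10)

    def test_breeding_values_uncorrelated_with_residuals(self, small_sim):
        r = np.corrcoef(small_sim.truth["bv"], small_sim.truth["residual"])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(small_sim.truth["bv"]))

    def test_rcbd_spreads_families_over_blocks(self, small_sim, small_cfg):
        phe = small_sim.phenotypes
        # with progeny == blocks, every family occupies every block once
        counts = phe.groupby(["family", "block"]).size()
        assert counts.max() == 1


class TestDeterminismAndLD:
    def test_same_seed_bit_identical(self, small_cfg, small_sim):
        again = treegs.simulate_population(small_cfg)
        np.testing.assert_array_equal(
            np.nan_to_num(again.genotypes.dosage, nan=-1),
            np.nan_to_num(small_sim.genotypes.dosage, nan=-1))
        pd.testing.assert_frame_equal(again.phenotypes, small_sim.phenotypes)

    def test_ld_decays_with_distance_and_with_ne(self):
        """Binned LD decay is non-increasing and smaller Ne gives higher
        short-range LD (slower decay)."""
        means = {}
        for ne in (35, 50):
            r2_short = []
            curves = []
            for seed in range(3):
                cfg = treegs.SimConfig(
                    ne=ne, n_chrom=3, chrom_len_bp=30_000_000, n_markers=900,
                    n_families=min(20, ne), progeny_per_family=10, fst=0.0,
                    missing_rate=0.0, seed=seed)
                sim = treegs.simulate_population(cfg)
                gi = treegs.impute_mean(treegs.filter_snps(sim.genotypes))
                ld = treegs.pairwise_ld(gi, max_dist_bp=10_000_000)
                bins = pd.cut(ld["dist_bp"], bins=np.linspace(0, 1e7, 11))
                curve = ld.groupby(bins, observed=True)["r2"].mean()
                curves.append(curve.to_numpy())
                r2_short.append(
                    ld.loc[ld["dist_bp"] < 2e6, "r2"].mean())
            means[ne] = np.mean(r2_short)
            avg_curve = np.nanmean(np.vstack(curves), axis=0)
            diffs = np.diff(avg_curve)
            # allow small noise wiggles but require overall decay
            assert avg_curve[0] > avg_curve[-1]
            assert (diffs < 0.05).all()
        assert means[35] > means[50]


class TestGeneAnnotation:
    def test_interval_fraction_and_marker_partition(self):
        cfg = treegs.SimConfig(ne=20, n_chrom=2, chrom_len_bp=5_000_000,
                               n_markers=500, n_qtl=50, fst=0.0,
                               n_families=10, progeny_per_family=5, seed=1)
        pool = sp.simulate_base(cfg, generations=0)
        genes = sp.annotate_genes(pool.chrom, pool.pos_bp, cfg.chrom_len_bp,
                                  genic_fraction=0.5, seed=1)
        covered = (genes["end"] - genes["start"]).sum()
        total = 2 * cfg.chrom_len_bp
        assert abs(covered / total - 0.5) < 0.05
        # non-overlapping within chromosome
        for _, sub in genes.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()
        # genic and intergenic sets partition markers (brute-force membership)
        g, _ = sp.sample_op_families(pool, cfg)
        genic = treegs.sample_subset(g, treegs.SubsetSpec(scheme="genic"),
                                     annotation=genes)
        inter = treegs.sample_subset(g, treegs.SubsetSpec(scheme="intergenic"),
                                     annotation=genes)
        assert set(genic) | set(inter) == set(g.markers)
        assert not set(genic) & set(inter)
        # ~50% genic coverage puts the genic share near half (paper-like
        # 7254/6533 split is ~53% genic)
        assert 0.4 < len(genic) / g.n_markers < 0.6

    def test_fraction_bounds_rejected(self):
        with pytest.raises(ValueError):
            sp.annotate_genes(np.array(["Chr01"]), np.array([10]), 100,
                              genic_fraction=1.0)
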