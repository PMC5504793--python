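import numpy as np
import pytest

import treegs


@pytest.fixture(scope="session")
def small_cfg():
    return treegs.SimConfig(
        ne=30, n_chrom=3, chrom_len_bp=10_000_000, n_markers=600,
        n_families=10, progeny_per_family=10, fst=0.10, n_qtl=50,
        h2_true=0.4, n_blocks=10, block_sd=0.5, missing_rate=0.02, seed=42)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return treegs.simulate_population(small_cfg)


@pytest.fixture(scope="session")
def small_imputed(small_sim):
    return treegs.impute_mean(treegs.filter_snps(small_sim.genotypes))


@pytest.fixture
def toy_geno():
    """5 markers: m3 monomorphic, m4 with 60% call rate, others clean."""
    dosage = np.array([
        # m1  m2  m3  m4      m5
        [0,   1,  2,  0,      1],
        [1,   0,  2,  np.nan, 0],
        [2,   1,  2,  np.nan, 1],
        [0,   2,  2,  0,      2],
        [1,   1,  2,  0,      0],
    ], dtype=float)
    return treegs.GenotypeMatrix(
        samples=[f"s{i}" for i in range(5)],
        markers=["m1", "m2", "m3", "m4", "m5"],
        dosage=dosage,
        chrom=np.repeat("Chr01", 5),
        pos_bp=np.array([100, 200, 300, 400, 500]),
    )
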