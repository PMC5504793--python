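"""Shared settings for the analysis drivers.

Two emulated open-pollinated breeding populations, scaled to the study
conditions: population A (Ne ~ 50, ~13.8k SNPs, 40 families) and population
B (Ne ~ 35, ~19.5k SNPs, 35 families, two subpopulations). Every driver
imports these configs and writes under results/.
"""

from pathlib import Path

import treegs

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"
SEED = 2024

POP_A = treegs.SimConfig(
    ne=50, n_chrom=11, chrom_len_bp=50_000_000, n_markers=13_787,
    n_families=40, progeny_per_family=13, fst=0.0, n_qtl=300, h2_true=0.30,
    n_blocks=42, block_sd=0.5, missing_rate=0.014, seed=SEED)

POP_B = treegs.SimConfig(
    ne=35, n_chrom=11, chrom_len_bp=50_000_000, n_markers=19_506,
    n_families=35, progeny_per_family=21, fst=0.10, n_qtl=300, h2_true=0.45,
    n_blocks=40, block_sd=0.5, missing_rate=0.008, seed=SEED + 1)

# reduced MCMC schedule for the driver runs (posterior means of h2 and
# marker effects stabilize within a few hundred sweeps at these sample
# sizes); the library default remains the long production schedule
# (200k/50k/5)
CHAIN = {"n_iter": 1000, "burn_in": 300, "thin": 3}
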