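"""Genotype QC: call-rate/MAF filtering, the alternative MAF >= 0.05 panel,
and LD pruning. Writes the retained-marker counts table and pruned marker
lists.

Requires: analysis/01_simulate.py
"""

import importlib.util
from pathlib import Path

import pandas as pd

HERE = Path(__file__).resolve().parent
spec = importlib.util.spec_from_file_location("cfg", HERE / "00_config.py")
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

import treegs
from treegs import io


def main():
    rows = []
    for name in ("popA", "popB"):
        g = io.read_plink(cfg.DATA / name / "genotypes")
        poly = treegs.filter_snps(g, cr_min=0.90, maf_min=0.0)
        maf05 = treegs.filter_snps(g, cr_min=0.90, maf_min=0.05)
        pruned = treegs.ld_prune(treegs.impute_mean(poly), window_kb=100,
                                 step_snps=1, r2_max=0.2)
        io.write_plink(poly, cfg.DATA / name / "filtered")
        io.write_marker_list(pruned, cfg.DATA / name / "ld_pruned.txt")
        rows.append({"population": name, "genotyped": g.n_markers,
                     "polymorphic_maf_gt0": poly.n_markers,
                     "maf_ge_0.05": maf05.n_markers,
                     "ld_pruned": len(pruned)})
        print(f"{name}: {g.n_markers} -> {poly.n_markers} polymorphic, "
              f"{maf05.n_markers} at MAF>=0.05, {len(pruned)} after pruning")
    table = pd.DataFrame(rows)
    table.to_csv(cfg.RESULTS / "qc_counts.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
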