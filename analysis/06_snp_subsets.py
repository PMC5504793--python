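"""Predictive ability under the six SNP-subsetting schemes: the cumulative
random ladder, non-cumulative random sets, evenly spaced SNPs, genic vs
intergenic SNPs, the LD-pruned panel and single chromosomes. GBLUP with
10-fold CV per subset.

Requires: analysis/02_qc_filter.py
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
from treegs.geno import SubsetSpec, sample_subset


def cv_for(ids, g, y, X):
    G = treegs.grm_vanraden(g.subset_markers(ids)).values
    h2 = treegs.reml_fit(y, X, G).vc.h2
    cv = treegs.cross_validate(y, X, "gblup", K=G, k_folds=10, seed=cfg.SEED)
    return h2, cv.mean_r, cv.se_r


def main():
    name = "popB"     # the larger population carries the subset study
    g = treegs.impute_mean(io.read_plink(cfg.DATA / name / "filtered"))
    phe = io.read_phenotypes(cfg.DATA / name / "phenotypes.csv")
    genes = pd.read_csv(cfg.DATA / name / "genes.bed", sep="\t", header=None,
                        names=["chrom", "start", "end"])
    y = phe["trait"].to_numpy()
    X = treegs.build_design(phe)
    rows = []

    def record(scheme, detail, ids):
        h2, r, se = cv_for(ids, g, y, X)
        rows.append({"scheme": scheme, "detail": detail, "n_snps": len(ids),
                     "h2": round(h2, 3), "r_gy": round(r, 3),
                     "se_r": round(se, 3)})
        print(rows[-1])

    sizes, nested = sample_subset(
        g, SubsetSpec(scheme="random_stratified_cumulative", seed=cfg.SEED,
                      sizes=[500, 1500, 3000, 5000, 10_000]))
    for s, ids in zip(sizes, nested):
        record("cumulative_random", str(s), ids)
    for w in (100_000, 500_000, 1_000_000):
        record("evenly_spaced", f"{w // 1000}kb",
               sample_subset(g, SubsetSpec(scheme="evenly_spaced",
                                           window_bp=w)))
    record("genic", "", sample_subset(g, SubsetSpec(scheme="genic"),
                                      annotation=genes))
    record("intergenic", "", sample_subset(g, SubsetSpec(scheme="intergenic"),
                                           annotation=genes))
    record("ld_pruned", "",
           io.read_marker_list(cfg.DATA / name / "ld_pruned.txt"))
    for chrom in ("Chr01", "Chr06"):
        record("single_chromosome", chrom,
               sample_subset(g, SubsetSpec(scheme="single_chromosome",
                                           chrom=chrom)))
    record("all", "", list(g.markers))
    pd.DataFrame(rows).to_csv(cfg.RESULTS / "subsets_cv.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
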