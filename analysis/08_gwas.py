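"""Genome-wide association: single-SNP linear scans with (MLMA) and without
(LMA) the polygenic GRM control, Bonferroni and Benjamini-Hochberg
adjustment, and Q-Q / Manhattan tables with genomic-inflation factors.

Requires: analysis/02_qc_filter.py
"""

import importlib.util
import json
from pathlib import Path

import numpy as np

HERE = Path(__file__).resolve().parent
spec = importlib.util.spec_from_file_location("cfg", HERE / "00_config.py")
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

import treegs
from treegs import io
from treegs.gwas import lma_scan, mlma_scan, scan_summaries


def main():
    summary = {}
    for name in ("popA", "popB"):
        g = treegs.impute_mean(io.read_plink(cfg.DATA / name / "filtered"))
        phe = io.read_phenotypes(cfg.DATA / name / "phenotypes.csv")
        y = phe["trait"].to_numpy()
        scores, _ = treegs.pca(g, 1)
        cov = np.hstack([treegs.build_design(phe), scores[:, :1]])
        G = treegs.grm_vanraden(g).values
        lma = lma_scan(y, cov, g).with_adjusted()
        mlma = mlma_scan(y, cov, g, G).with_adjusted()
        mlma.table.to_csv(cfg.RESULTS / f"gwas_mlma_{name}.tsv", sep="\t",
                          index=False)
        qq, manhattan, lam = scan_summaries(mlma)
        qq.to_csv(cfg.RESULTS / f"gwas_qq_{name}.tsv", sep="\t", index=False)
        manhattan.to_csv(cfg.RESULTS / f"gwas_manhattan_{name}.tsv",
                         sep="\t", index=False)
        summary[name] = {
            "lambda_lma": round(lma.lambda_gc, 3),
            "lambda_mlma": round(lam, 3),
            "bonf_hits_lma": int(lma.table["sig_bonf"].sum()),
            "bonf_hits_mlma": int(mlma.table["sig_bonf"].sum()),
            "bh_hits_mlma": int(mlma.table["sig_bh"].sum()),
        }
        print(name, summary[name])
    (cfg.RESULTS / "gwas_summary.json").write_text(
        json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
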