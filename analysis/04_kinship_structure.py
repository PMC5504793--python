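"""Relationship matrices (pedigree A, VanRaden and Powell G), genotype PCA
and the relatedness-minimized train/validation split.

Requires: analysis/02_qc_filter.py
"""

import importlib.util
import json
from pathlib import Path

import numpy as np
import pandas as pd

HERE = Path(__file__).resolve().parent
spec = importlib.util.spec_from_file_location("cfg", HERE / "00_config.py")
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

import treegs
from treegs import io


def main():
    summary = {}
    for name in ("popA", "popB"):
        g = treegs.impute_mean(io.read_plink(cfg.DATA / name / "filtered"))
        ped = pd.read_csv(cfg.DATA / name / "pedigree.csv")
        A = treegs.pedigree_A(ped)
        G = treegs.grm_vanraden(g)
        io.write_kinship_tsv(A.ids, A.values, cfg.RESULTS / f"A_{name}.tsv")
        io.write_kinship_tsv(G.ids, G.values, cfg.RESULTS / f"G_{name}.tsv")
        scores, eigvals = treegs.pca(g, 10)
        np.savetxt(cfg.RESULTS / f"pca_{name}.tsv", scores, delimiter="\t")
        plan = treegs.make_split(scores, list(ped["id"]), mode="unrelated",
                                 seed=cfg.SEED)
        (cfg.RESULTS / f"split_{name}.json").write_text(json.dumps({
            "train_ids": plan.train_ids, "valid_ids": plan.valid_ids,
            "excluded_outliers": plan.excluded_outliers}, indent=1))
        fam = ped["family"].to_numpy()
        same = fam[:, None] == fam[None, :]
        off = ~np.eye(len(fam), dtype=bool)
        summary[name] = {
            "mean_G_within_family": round(float(G.values[same & off].mean()), 3),
            "mean_G_between_family": round(float(G.values[~same & off].mean()), 3),
            "pc1_pc2_variance_pct": [
                round(100 * float(v) / float(np.trace(G.values)), 2)
                for v in eigvals[:2]],
            "split_sizes": [len(plan.train_ids), len(plan.valid_ids)],
            "n_outliers": len(plan.excluded_outliers),
        }
        print(name, summary[name])
    (cfg.RESULTS / "kinship_summary.json").write_text(
        json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
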