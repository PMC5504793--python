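"""Relatedness versus historical LD: predictive ability when training and
validation sets are PCA-separated subpopulations (minimal relatedness)
against size-matched random splits.

Requires: analysis/04_kinship_structure.py
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
from treegs.kinship import SplitPlan, make_split
from treegs.pipeline import _split_r


def main():
    name = "popB"     # the structured population
    g = treegs.impute_mean(io.read_plink(cfg.DATA / name / "filtered"))
    phe = io.read_phenotypes(cfg.DATA / name / "phenotypes.csv")
    y = phe["trait"].to_numpy()
    X = treegs.build_design(phe)
    G = treegs.grm_vanraden(g).values
    ids = list(phe["id"])
    split = json.loads((cfg.RESULTS / f"split_{name}.json").read_text())
    plan = SplitPlan(train_ids=split["train_ids"],
                     valid_ids=split["valid_ids"], basis="pca_clusters",
                     excluded_outliers=split["excluded_outliers"])
    scores = np.loadtxt(cfg.RESULTS / f"pca_{name}.tsv", delimiter="\t")

    r_unrel = _split_r(y, X, G, ids, plan)
    r_rand = [
        _split_r(y, X, G, ids,
                 make_split(scores, ids, mode="random",
                            sizes=(len(plan.train_ids), len(plan.valid_ids)),
                            seed=cfg.SEED + rep))
        for rep in range(10)]
    out = {"r_gy_unrelated_split": round(r_unrel, 4),
           "r_gy_random_split_mean": round(float(np.mean(r_rand)), 4),
           "r_gy_random_split_sd": round(float(np.std(r_rand, ddof=1)), 4),
           "train_size": len(plan.train_ids),
           "valid_size": len(plan.valid_ids)}
    print(out)
    (cfg.RESULTS / "relatedness_split.json").write_text(
        json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
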