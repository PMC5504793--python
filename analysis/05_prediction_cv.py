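"""Cross-validated breeding-value prediction: ABLUP, GBLUP and the five
Bayesian whole-genome regressions, each with 10-fold CV, reporting h2 and
predictive ability r_gy per method (the study's main comparison table).

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
from treegs.predict import BAYES_METHODS, gibbs_fit


def main():
    rows = []
    for name in ("popA", "popB"):
        g = treegs.impute_mean(io.read_plink(cfg.DATA / name / "filtered"))
        ped = pd.read_csv(cfg.DATA / name / "pedigree.csv")
        phe = io.read_phenotypes(cfg.DATA / name / "phenotypes.csv")
        y = phe["trait"].to_numpy()
        X = treegs.build_design(phe)
        A = treegs.pedigree_A(ped).values
        G = treegs.grm_vanraden(g).values

        for method in ("ablup", "gblup") + BAYES_METHODS:
            if method in ("ablup", "gblup"):
                K = A if method == "ablup" else G
                h2 = treegs.reml_fit(y, X, K).vc.h2
                cv = treegs.cross_validate(y, X, method, K=K, k_folds=10,
                                           seed=cfg.SEED)
            else:
                post = gibbs_fit(y, X, g.dosage, method=method,
                                 seed=cfg.SEED, **cfg.CHAIN)
                h2 = post.h2_mean
                cv = treegs.cross_validate(y, X, method, Z=g.dosage,
                                           k_folds=10, seed=cfg.SEED,
                                           chain=cfg.CHAIN)
            rows.append({"population": name, "method": method,
                         "h2": round(h2, 3), "r_gy": round(cv.mean_r, 3),
                         "se_r": round(cv.se_r, 3)})
            print(rows[-1])
    pd.DataFrame(rows).to_csv(cfg.RESULTS / "prediction_cv.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
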