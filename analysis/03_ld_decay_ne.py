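"""LD characterization: raw and kinship/structure-corrected pairwise r2,
decay-curve fits with the r2 = 0.2 crossing distance, and the LD-based
effective population size with its parametric CI.

Requires: analysis/02_qc_filter.py
"""

import dataclasses
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


def main():
    summary = {}
    rng = np.random.default_rng(cfg.SEED)
    for name in ("popA", "popB"):
        g = treegs.impute_mean(io.read_plink(cfg.DATA / name / "filtered"))
        # subsample markers for the pairwise table to keep it tractable
        if g.n_markers > 3000:
            pick = np.sort(rng.choice(g.n_markers, 3000, replace=False))
            g_ld = g.subset_markers(pick)
        else:
            g_ld = g
        P = treegs.grm_powell(g_ld).values
        scores, _ = treegs.pca(g_ld, 1)
        table = treegs.pairwise_ld(g_ld, max_dist_bp=3_000_000,
                                   corrections="all", grm=P,
                                   structure_covariates=scores[:, 0])
        table.to_csv(cfg.RESULTS / f"ld_pairs_{name}.tsv", sep="\t",
                     index=False)
        fit_raw = treegs.fit_decay(table, n=g.n_samples, r2_col="r2")
        fit_vs = treegs.fit_decay(table, n=g.n_samples, r2_col="r2_vs")
        ne = treegs.estimate_ne(g, maf_cutoff=0.05, max_pairs=4000,
                                seed=cfg.SEED)
        summary[name] = {
            "mean_r2": round(float(table["r2"].mean()), 4),
            "mean_r2_vs": round(float(table["r2_vs"].mean()), 4),
            "d02_raw_kb": round(fit_raw.d_threshold_bp / 1000, 1),
            "d02_vs_kb": round(fit_vs.d_threshold_bp / 1000, 1),
            "ne": dataclasses.asdict(ne),
        }
        print(f"{name}: mean r2 {summary[name]['mean_r2']}, corrected "
              f"{summary[name]['mean_r2_vs']}; decay to 0.2 at "
              f"{summary[name]['d02_raw_kb']} kb (raw) / "
              f"{summary[name]['d02_vs_kb']} kb (corrected); "
              f"Ne = {ne.ne_hat:.1f} [{ne.ci_low:.1f}, {ne.ci_high:.1f}]")
    (cfg.RESULTS / "ld_ne_summary.json").write_text(
        json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
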