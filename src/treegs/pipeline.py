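"""End-to-end orchestration: simulate a breeding population and replay the
full study design on it (QC, LD/Ne, kinship, cross-validated prediction,
SNP subsets, relatedness-controlled splits, GWAS), writing per-stage tables
and a JSON report.

One global seed spawns independent per-stage child seeds through
``numpy.random.SeedSequence`` so every stage is reproducible in isolation
and the whole report is bit-identical on rerun.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import geno, gwas, io, kinship, ldstats, predict, simpop

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

log = logging.getLogger("treegs")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "treegs_run",
    "trait_name": "trait",
    "sim": {
        "ne": 50, "n_chrom": 11, "chrom_len_bp": 20_000_000,
        "n_markers": 3000, "n_families": 30, "progeny_per_family": 10,
        "fst": 0.10, "n_qtl": 200, "h2_true": 0.30, "n_blocks": 30,
        "block_sd": 0.5, "missing_rate": 0.01,
    },
    "filter": {"cr_min": 0.90, "maf_min": 0.0},
    "ld": {"max_dist_bp": 100_000, "corrections": "all", "decay_level": 0.2,
           "max_markers": 1500},
    "ne": {"maf_cutoff": 0.05, "max_pairs": 3000},
    "predict": {"methods": ["ablup", "gblup", "brr"], "k_folds": 10,
                "chain": {"n_iter": 2000, "burn_in": 500, "thin": 5}},
    "subsets": {"enabled": True, "sizes": [500, 1500], "method": "gblup"},
    "split": {"enabled": True, "n_pcs": 2, "outlier_sd": 6.0},
    "gwas": {"enabled": True, "alpha": 0.05, "fdr": 0.05},
}

_VALID_METHODS = {"ablup", "gblup", "rrblup"} | set(predict.BAYES_METHODS)


def validate_config(config: dict | None) -> dict:
    """Merge a user config over the defaults; reject unknown keys and
    inconsistent values with one aggregated error message."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    errors = []

    def merge(dst, src, path=""):
        for k, v in (src or {}).items():
            if k not in dst:
                errors.append(f"unknown key {path + k!r}")
            elif isinstance(dst[k], dict):
                if not isinstance(v, dict):
                    errors.append(f"{path + k!r} must be a mapping")
                else:
                    merge(dst[k], v, path + k + ".")
            else:
                dst[k] = v

    merge(cfg, config or {})
    if cfg["predict"]["k_folds"] < 2:
        errors.append("predict.k_folds must be >= 2")
    bad = [m for m in cfg["predict"]["methods"] if m not in _VALID_METHODS]
    if bad:
        errors.append(f"unknown prediction methods: {bad}")
    ch = cfg["predict"]["chain"]
    if ch["n_iter"] <= ch["burn_in"]:
        errors.append("predict.chain.n_iter must exceed burn_in")
    try:
        simpop.SimConfig(seed=0, **cfg["sim"])
    except ValueError as exc:
        errors.append(str(exc))
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    return cfg


def _spawn_seeds(seed: int, names):
    """Deterministic per-stage child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(names, children)}


def run_pipeline(config: dict | None = None) -> dict:
    """Run the full synthetic study; returns the report dict and writes
    artifacts under ``config['out_dir']``."""
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(cfg["seed"], [
        "sim", "ld", "ne", "cv", "subset", "split", "gwas"])
    # the echoed config omits out_dir so reports at different paths stay
    # byte-identical for the same seed
    report = {"config": {k: v for k, v in cfg.items() if k != "out_dir"},
              "stage_seeds": seeds}
    t0 = time.time()

    # --- simulate ---
    sim_cfg = simpop.SimConfig(seed=seeds["sim"], **cfg["sim"])
    sim = simpop.simulate_population(sim_cfg)
    io.write_phenotypes(sim.phenotypes, out / "phenotypes.csv")
    report["sim"] = {
        "n_individuals": sim.genotypes.n_samples,
        "n_markers": sim.genotypes.n_markers,
        "realized_h2": sim.truth["realized_h2"],
    }
    log.info("simulated %d individuals x %d markers",
             sim.genotypes.n_samples, sim.genotypes.n_markers)

    # --- QC filter ---
    g = geno.filter_snps(sim.genotypes, **cfg["filter"])
    report["filter"] = {"markers_in": sim.genotypes.n_markers,
                        "markers_kept": g.n_markers}
    g_imp = geno.impute_mean(g)

    # --- kinship & structure ---
    A = kinship.pedigree_A(sim.pedigree)
    G = kinship.grm_vanraden(g_imp)
    P = kinship.grm_powell(g_imp)
    scores, eigvals = kinship.pca(g_imp, n_components=5)
    struct_cov = scores[:, 0]
    io.write_kinship_tsv(G.ids, G.values, out / "grm_vanraden.tsv")
    report["kinship"] = {
        "mean_G_diag": float(np.diag(G.values).mean()),
        "pc_variance_fraction": (eigvals / np.trace(G.values)).tolist(),
    }

    # --- LD and Ne ---
    rng_ld = np.random.default_rng(seeds["ld"])
    if g.n_markers > cfg["ld"]["max_markers"]:
        pick = np.sort(rng_ld.choice(g.n_markers, cfg["ld"]["max_markers"],
                                     replace=False))
        g_ld = g_imp.subset_markers(pick)
    else:
        g_ld = g_imp
    ld = ldstats.pairwise_ld(g_ld, max_dist_bp=cfg["ld"]["max_dist_bp"],
                             corrections=cfg["ld"]["corrections"],
                             grm=P.values, structure_covariates=struct_cov)
    ld.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
    decay = ldstats.fit_decay(ld, n=g.n_samples,
                              level=cfg["ld"]["decay_level"])
    report["ld"] = {
        "n_pairs": len(ld),
        "mean_r2": float(ld["r2"].mean()),
        "mean_r2_vs": float(ld["r2_vs"].mean()) if "r2_vs" in ld else None,
        "decay_c_per_bp": decay.c_per_bp,
        "decay_d02_bp": decay.d_threshold_bp,
    }
    ne = ldstats.estimate_ne(g_imp, maf_cutoff=cfg["ne"]["maf_cutoff"],
                             max_pairs=cfg["ne"]["max_pairs"],
                             seed=seeds["ne"])
    report["ne"] = {"ne_hat": ne.ne_hat, "ci_low": ne.ci_low,
                    "ci_high": ne.ci_high, "n_pairs": ne.n_pairs}

    # --- cross-validated prediction (Table-2-style rows) ---
    y = sim.phenotypes["trait"].to_numpy()
    X = predict.build_design(sim.phenotypes)
    rows = []
    for method in cfg["predict"]["methods"]:
        K = A.values if method == "ablup" else G.values
        if method in ("ablup", "gblup"):
            fit = predict.reml_fit(y, X, K)
            h2 = fit.vc.h2
            cv = predict.cross_validate(y, X, method, K=K,
                                        k_folds=cfg["predict"]["k_folds"],
                                        seed=seeds["cv"])
        elif method == "rrblup":
            fit, _, _, _ = predict.gblup_to_marker_effects(y, X, g_imp.dosage)
            h2 = fit.vc.h2
            cv = predict.cross_validate(y, X, method, Z=g_imp.dosage,
                                        k_folds=cfg["predict"]["k_folds"],
                                        seed=seeds["cv"])
        else:
            post = predict.gibbs_fit(y, X, g_imp.dosage, method=method,
                                     seed=seeds["cv"],
                                     **cfg["predict"]["chain"])
            h2 = post.h2_mean
            cv = predict.cross_validate(y, X, method, Z=g_imp.dosage,
                                        k_folds=cfg["predict"]["k_folds"],
                                        seed=seeds["cv"],
                                        chain=cfg["predict"]["chain"])
        rows.append({"trait": cfg["trait_name"], "method": method, "h2": h2,
                     "r_gy": cv.mean_r, "se_r": cv.se_r})
    pred_table = pd.DataFrame(rows)
    pred_table.to_csv(out / "prediction_cv.tsv", sep="\t", index=False)
    report["predict"] = rows

    # --- SNP subsets (Table-3-style) ---
    if cfg["subsets"]["enabled"]:
        sub_rows = []
        for size in cfg["subsets"]["sizes"]:
            if size >= g.n_markers:
                continue
            spec = geno.SubsetSpec(scheme="random_noncumulative", size=size,
                                   seed=seeds["subset"])
            ids = geno.sample_subset(g_imp, spec)
            g_sub = g_imp.subset_markers(ids)
            G_sub = kinship.grm_vanraden(g_sub)
            cv = predict.cross_validate(y, X, "gblup", K=G_sub.values,
                                        k_folds=cfg["predict"]["k_folds"],
                                        seed=seeds["cv"])
            sub_rows.append({"scheme": "random", "n_snps": size,
                             "r_gy": cv.mean_r, "se_r": cv.se_r})
        cv_all = predict.cross_validate(y, X, "gblup", K=G.values,
                                        k_folds=cfg["predict"]["k_folds"],
                                        seed=seeds["cv"])
        sub_rows.append({"scheme": "all", "n_snps": g.n_markers,
                         "r_gy": cv_all.mean_r, "se_r": cv_all.se_r})
        pd.DataFrame(sub_rows).to_csv(out / "subsets_cv.tsv", sep="\t",
                                      index=False)
        report["subsets"] = sub_rows

    # --- relatedness-controlled split (Fig-3-style) ---
    if cfg["split"]["enabled"]:
        plan = kinship.make_split(scores, sim.phenotypes["id"],
                                  mode="unrelated",
                                  n_pcs=cfg["split"]["n_pcs"],
                                  outlier_sd=cfg["split"]["outlier_sd"],
                                  seed=seeds["split"])
        r_unrel = _split_r(y, X, G.values, sim.phenotypes["id"], plan)
        rand = kinship.make_split(scores, sim.phenotypes["id"], mode="random",
                                  sizes=(len(plan.train_ids),
                                         len(plan.valid_ids)),
                                  seed=seeds["split"])
        r_rand = _split_r(y, X, G.values, sim.phenotypes["id"], rand)
        report["split"] = {
            "train_size": len(plan.train_ids),
            "valid_size": len(plan.valid_ids),
            "n_outliers": len(plan.excluded_outliers),
            "r_unrelated": r_unrel, "r_random": r_rand,
        }

    # --- GWAS (Fig-4-style) ---
    if cfg["gwas"]["enabled"]:
        cov = np.hstack([X, struct_cov[:, None]])
        lma = gwas.lma_scan(y, cov, g_imp).with_adjusted(
            alpha=cfg["gwas"]["alpha"], fdr=cfg["gwas"]["fdr"])
        mlma = gwas.mlma_scan(y, cov, g_imp, G.values).with_adjusted(
            alpha=cfg["gwas"]["alpha"], fdr=cfg["gwas"]["fdr"])
        mlma.table.to_csv(out / "gwas_mlma.tsv", sep="\t", index=False)
        report["gwas"] = {
            "lambda_lma": lma.lambda_gc,
            "lambda_mlma": mlma.lambda_gc,
            "hits_bonf_lma": int(lma.table["sig_bonf"].sum()),
            "hits_bonf_mlma": int(mlma.table["sig_bonf"].sum()),
            "hits_bh_mlma": int(mlma.table["sig_bh"].sum()),
        }

    # report.json must be bit-identical across reruns with the same seed,
    # so wall-clock time goes to the log only
    log.info("pipeline finished in %.1f s", time.time() - t0)
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    return report


def _split_r(y, X, G, ids, plan) -> float:
    """Train on plan.train_ids, predict plan.valid_ids, return r_gy."""
    pos = {s: i for i, s in enumerate(ids)}
    t = np.array([pos[s] for s in plan.train_ids])
    v = np.array([pos[s] for s in plan.valid_ids])
    cols = predict._drop_null_columns(X[t])
    fit = predict.reml_fit(y[t], X[t][:, cols], G[np.ix_(t, t)])
    gebv = predict.predict_gebv(fit, G[np.ix_(v, t)])
    y_adj = y[v] - X[v][:, cols] @ fit.b_hat
    return predict.predictive_ability(y_adj, gebv)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
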