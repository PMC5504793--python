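"""Single-SNP association scans with and without a polygenic control.

LMA fits each SNP by ordinary least squares alongside the fixed covariates
(intercept, block, optional structure covariate). MLMA adds a polygenic
random effect g ~ N(0, G sigma2_g) whose variance components are estimated
once under the null model (no candidate SNP); every SNP is then tested by
generalized least squares under the fitted covariance — the usual
population-parameters-previously-determined approximation, with the
candidate's chromosome left in the GRM (plain MLMA, not leave-one-out).

Genomic inflation lambda_gc is the median association chi-square divided by
the null median 0.4549.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .geno import GenotypeMatrix, impute_mean
from .predict import reml_fit

__all__ = ["GWASResult", "lma_scan", "mlma_scan", "adjust_pvalues",
           "scan_summaries", "CHI2_NULL_MEDIAN"]

CHI2_NULL_MEDIAN = 0.45493642311957174   # median of chi-square(1)


@dataclass
class GWASResult:
    table: pd.DataFrame      # marker, chrom, pos_bp, maf, beta, se, p, flags
    model: str               # lma | mlma
    lambda_gc: float

    def with_adjusted(self, alpha: float = 0.05, fdr: float = 0.05):
        adj = adjust_pvalues(self.table["p"].to_numpy(), method="bonferroni",
                             alpha=alpha)
        bh = adjust_pvalues(self.table["p"].to_numpy(), method="bh", fdr=fdr)
        t = self.table.copy()
        t["p_bonf"] = adj["adjusted"]
        t["sig_bonf"] = adj["significant"]
        t["q_bh"] = bh["adjusted"]
        t["sig_bh"] = bh["significant"]
        return GWASResult(table=t, model=self.model, lambda_gc=self.lambda_gc)


def _scan_core(yt: np.ndarray, Xt: np.ndarray, St: np.ndarray) -> pd.DataFrame:
    """Per-SNP Wald tests after a common linear transform.

    yt, Xt, St are the (possibly whitened) phenotype, covariate design and
    SNP matrix. Each SNP is tested as an extra fixed covariate; residual
    variance is re-estimated per SNP, giving t-based two-sided p-values.
    """
    n, q = Xt.shape
    Q, _ = np.linalg.qr(Xt)
    y_r = yt - Q @ (Q.T @ yt)
    S_r = St - Q @ (Q.T @ St)
    sxx = np.einsum("ij,ij->j", S_r, S_r)
    sxy = S_r.T @ y_r
    syy = float(y_r @ y_r)
    df = n - q - 1

    ok = sxx > 1e-10 * n          # degenerate: monomorphic or collinear
    beta = np.zeros(len(sxx))
    beta[ok] = sxy[ok] / sxx[ok]
    rss = syy - beta * sxy
    sigma2 = np.full(len(sxx), np.nan)
    sigma2[ok] = np.maximum(rss[ok], 0.0) / df
    se = np.full(len(sxx), np.nan)
    se[ok] = np.sqrt(sigma2[ok] / sxx[ok])
    tstat = np.zeros(len(sxx))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat[ok] = beta[ok] / se[ok]
    p = np.ones(len(sxx))
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"beta": beta, "se": se, "p": p, "degenerate": ~ok})


def _lambda_gc(p: np.ndarray) -> float:
    chi = stats.chi2.isf(np.clip(p, np.finfo(float).tiny, 1.0), df=1)
    return float(np.median(chi) / CHI2_NULL_MEDIAN)


def lma_scan(y: np.ndarray, covariates: np.ndarray,
             g: GenotypeMatrix) -> GWASResult:
    """Linear-model association: per-SNP OLS with fixed covariates."""
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(covariates, float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")
    S = impute_mean(g).dosage
    core = _scan_core(y, X, S)
    table = pd.DataFrame({
        "marker": g.markers, "chrom": g.chrom, "pos_bp": g.pos_bp,
        "maf": g.maf,
    })
    table = pd.concat([table, core], axis=1)
    return GWASResult(table=table, model="lma",
                      lambda_gc=_lambda_gc(core["p"].to_numpy()))


def mlma_scan(y: np.ndarray, covariates: np.ndarray, g: GenotypeMatrix,
              grm: np.ndarray) -> GWASResult:
    """Mixed-linear-model association with a polygenic GRM random effect.

    Null variance components come from one REML fit; SNPs are then tested in
    the whitened space V^{-1/2} = U diag(1/sqrt(s2g*lambda_k + s2e)) U'.
    With GRM = I the whitening is a scalar and the scan reduces exactly to
    LMA.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(covariates, float))
    fit = reml_fit(y, X, grm)
    s2g, s2e = fit.vc.sigma2_a, fit.vc.sigma2_e
    w, U = np.linalg.eigh(0.5 * (grm + grm.T))
    w = np.maximum(w, 0.0)
    scale = 1.0 / np.sqrt(s2g * w + s2e)
    T = (U * scale) @ U.T

    S = impute_mean(g).dosage
    core = _scan_core(T @ y, T @ X, T @ S)
    table = pd.DataFrame({
        "marker": g.markers, "chrom": g.chrom, "pos_bp": g.pos_bp,
        "maf": g.maf,
    })
    table = pd.concat([table, core], axis=1)
    return GWASResult(table=table, model="mlma",
                      lambda_gc=_lambda_gc(core["p"].to_numpy()))


def adjust_pvalues(p, method: str = "bonferroni", alpha: float = 0.05,
                   fdr: float = 0.05) -> dict:
    """Bonferroni or Benjamini-Hochberg adjustment with significance calls.

    Returns ``{"adjusted": array, "significant": bool array}``; Bonferroni is
    called at ``alpha``, BH at ``fdr``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if method == "bonferroni":
        adj = np.minimum(p * m, 1.0)
        return {"adjusted": adj, "significant": adj <= alpha}
    if method == "bh":
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        # step-up: running minimum from the largest p
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        return {"adjusted": adj, "significant": adj <= fdr}
    raise ValueError(f"unknown adjustment method {method!r}")


def scan_summaries(result: GWASResult):
    """Q-Q and Manhattan tables plus the genomic-inflation factor.

    Q-Q expected quantiles use the (i - 0.5)/m convention on -log10 scale.
    """
    p = result.table["p"].to_numpy()
    if p.size == 0:
        raise ValueError("empty scan result")
    m = p.size
    obs = -np.log10(np.sort(p))
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame({"expected": exp, "observed": obs})
    manhattan = result.table[["chrom", "pos_bp", "marker"]].copy()
    manhattan["neglog10p"] = -np.log10(result.table["p"].to_numpy())
    return qq, manhattan, result.lambda_gc
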