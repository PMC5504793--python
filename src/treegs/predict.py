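"""Breeding-value prediction: REML mixed models (ABLUP/GBLUP), RR-BLUP
marker effects, Bayesian whole-genome regression, and cross-validated
predictive ability.

The core mixed model is

    y = X b + Z a + e,    a ~ N(0, K sigma2_a),   e ~ N(0, I sigma2_e),

with b fixed block (and optional structure) effects and K a pedigree or
genomic relationship matrix. REML uses the single-random-effect spectral
method: after projecting off X, the restricted likelihood is a 1-D function
of the variance ratio phi = sigma2_a / sigma2_e, maximized on the log scale.

The Bayesian whole-genome regressions share the base model

    y = X b + Z m + e,    b ~ N(0, 1e6 I),  sigma2_e ~ scaled-inv-chi2(nu_e, S_e),

and differ in the prior on marker effects m: a common normal variance (BRR),
per-marker variances (Bayes A), per-marker variances with a point mass at
zero (Bayes B), a common variance with a point mass and Beta-updated
inclusion probability (Bayes Cpi), or a double-exponential prior via its
exponential scale mixture (Bayesian Lasso). Default hyperparameters follow
the usual genome-wide-regression conventions: nu_e = nu_m = 5 with scale
parameters solved so the prior mode implies a 50% genomic variance share.

Predictive ability r_gy is the Pearson correlation between validation
phenotypes (block effects removed using training estimates) and GEBVs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from ._samplers import marker_sweep

__all__ = [
    "VarianceComponents", "MixedModelFit", "PosteriorSummary", "CVResult",
    "reml_fit", "predict_gebv", "rrblup_effects", "gblup_to_marker_effects",
    "gibbs_fit", "cross_validate", "predictive_ability", "build_design",
    "center_markers", "BAYES_METHODS",
]

BAYES_METHODS = ("brr", "bayes_a", "bayes_b", "bayes_c_pi", "bl")


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    h2: float
    boundary: bool = False
    loglik: float = np.nan

    @property
    def sigma2_y(self) -> float:
        return self.sigma2_a + self.sigma2_e


@dataclass
class MixedModelFit:
    vc: VarianceComponents
    b_hat: np.ndarray
    a_hat: np.ndarray            # BLUP of breeding values (= GEBV for GBLUP)
    X: np.ndarray
    K: np.ndarray
    y: np.ndarray


@dataclass
class PosteriorSummary:
    marker_effect_means: np.ndarray
    b_mean: np.ndarray
    h2_samples: np.ndarray
    h2_mean: float
    sigma2_e_mean: float
    inclusion_prob: Optional[np.ndarray]
    hyper: dict
    chain: dict


@dataclass
class CVResult:
    fold_r: np.ndarray
    mean_r: float
    se_r: float
    fold_assignments: np.ndarray


def build_design(phenotypes: pd.DataFrame, block_col: str = "block",
                 structure: Optional[np.ndarray] = None) -> np.ndarray:
    """Fixed-effect design: intercept + block indicators (reference level
    dropped) + optional structure covariate column(s)."""
    n = len(phenotypes)
    blocks = pd.get_dummies(phenotypes[block_col].astype("category"),
                            drop_first=True, dtype=float)
    X = np.hstack([np.ones((n, 1)), blocks.to_numpy()])
    if structure is not None:
        X = np.hstack([X, np.atleast_2d(np.asarray(structure, float)).reshape(n, -1)])
    return X


def center_markers(Z: np.ndarray, means: Optional[np.ndarray] = None):
    """Column-center a dosage matrix; returns (Zc, means used)."""
    Z = np.asarray(Z, dtype=np.float64)
    if means is None:
        means = Z.mean(axis=0)
    return Z - means, means


def _drop_null_columns(X: np.ndarray):
    """Indices of non-degenerate design columns (nonzero variance or the
    intercept). Needed when a CV fold leaves a block level unobserved."""
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    return np.array(keep, dtype=int)


def reml_fit(y: np.ndarray, X: np.ndarray, K: np.ndarray,
             log_phi_bounds=(-14.0, 14.0), tol: float = 1e-8) -> MixedModelFit:
    """REML for the single-kinship mixed model via the spectral method.

    Eigen-decomposes K projected off X once; the restricted likelihood is then
    a cheap 1-D function of phi = sigma2_a / sigma2_e, maximized by a grid
    pass plus Brent refinement on log phi. Boundary solutions (h2 -> 0 or 1)
    are flagged, not raised.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n, q = X.shape
    if n < q + 2:
        raise ValueError("too few observations for the fixed-effect design")
    K = 0.5 * (K + K.T)

    # restricted space: complement of col(X)
    Qfull, _ = np.linalg.qr(X, mode="complete")
    Q2 = Qfull[:, q:]
    M = Q2.T @ K @ Q2
    xi, U = np.linalg.eigh(M)
    xi = np.maximum(xi, 0.0)
    eta = U.T @ (Q2.T @ y)
    m = n - q

    def neg_restricted_ll(log_phi):
        phi = np.exp(log_phi)
        denom = phi * xi + 1.0
        s2e = float(np.sum(eta * eta / denom) / m)
        return m * np.log(max(s2e, 1e-300)) + float(np.sum(np.log(denom)))

    lo, hi = log_phi_bounds
    grid = np.linspace(lo, hi, 57)
    vals = [neg_restricted_ll(g) for g in grid]
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(a, b),
                                   method="bounded",
                                   options={"xatol": tol})
    log_phi = float(res.x)
    boundary = log_phi <= lo + 0.05 or log_phi >= hi - 0.05
    phi = np.exp(log_phi)
    denom = phi * xi + 1.0
    s2e = float(np.sum(eta * eta / denom) / m)
    s2a = phi * s2e
    h2 = s2a / (s2a + s2e)

    # GLS fixed effects and BLUP at the optimum via eigendecomp of K
    w, Uk = np.linalg.eigh(K)
    w = np.maximum(w, 0.0)
    dinv = 1.0 / (s2a * w + s2e)
    Xt = Uk.T @ X
    yt = Uk.T @ y
    XtVX = (Xt * dinv[:, None]).T @ Xt
    XtVy = (Xt * dinv[:, None]).T @ yt
    b_hat = np.linalg.solve(XtVX, XtVy)
    r = yt - Xt @ b_hat
    a_hat = Uk @ (s2a * w * dinv * r)

    vc = VarianceComponents(sigma2_a=s2a, sigma2_e=s2e, h2=h2,
                            boundary=boundary, loglik=-0.5 * res.fun)
    return MixedModelFit(vc=vc, b_hat=b_hat, a_hat=a_hat, X=X, K=K, y=y)


def predict_gebv(fit: MixedModelFit, K_cross: np.ndarray) -> np.ndarray:
    """BLUP projection of breeding values onto new individuals.

    ``K_cross`` holds relationships between new individuals (rows) and the
    training individuals (columns): a_new = s2a K_vt V_tt^-1 (y - X b).
    """
    s2a, s2e = fit.vc.sigma2_a, fit.vc.sigma2_e
    V = s2a * fit.K + s2e * np.eye(len(fit.y))
    resid = fit.y - fit.X @ fit.b_hat
    return s2a * (K_cross @ np.linalg.solve(V, resid))


def rrblup_effects(y: np.ndarray, X: np.ndarray, Zc: np.ndarray,
                   sigma2_m: float, sigma2_e: float,
                   b_hat: Optional[np.ndarray] = None) -> np.ndarray:
    """Ridge (RR-BLUP) marker effects at fixed variance components:
    m_hat = s2m Zc' V^-1 (y - X b), V = s2m Zc Zc' + s2e I."""
    y = np.asarray(y, float).ravel()
    n = len(y)
    if Zc.shape[0] != n:
        raise ValueError("Z rows do not match y")
    V = sigma2_m * (Zc @ Zc.T) + sigma2_e * np.eye(n)
    if b_hat is None:
        Vi_X = np.linalg.solve(V, X)
        b_hat = np.linalg.solve(X.T @ Vi_X, Vi_X.T @ y)
    resid = y - X @ b_hat
    return sigma2_m * (Zc.T @ np.linalg.solve(V, resid))


def gblup_to_marker_effects(y, X, Z):
    """Fit GBLUP through the VanRaden G built from ``Z`` and back-solve the
    equivalent RR-BLUP marker effects.

    Returns ``(fit, m_hat, Zc, means)`` where ``Zc @ m_hat`` reproduces the
    GBLUP GEBVs (the kinship-route / marker-route identity).
    """
    Z = np.asarray(Z, float)
    p_k = Z.mean(axis=0) / 2.0
    Zc = Z - 2.0 * p_k
    c = 2.0 * np.sum(p_k * (1.0 - p_k))
    if c <= 0:
        raise ValueError("all markers monomorphic")
    G = (Zc @ Zc.T) / c
    fit = reml_fit(y, X, G)
    s2m = fit.vc.sigma2_a / c
    m_hat = rrblup_effects(y, X, Zc, s2m, fit.vc.sigma2_e, b_hat=fit.b_hat)
    return fit, m_hat, Zc, 2.0 * p_k


def _scaled_inv_chi2(rng, df: float, scale_sum: float) -> float:
    """Draw from scaled-inverse-chi2: scale_sum / chi2_df."""
    return scale_sum / rng.chisquare(df)


def gibbs_fit(y: np.ndarray, X: np.ndarray, Z: np.ndarray, method: str,
              n_iter: int = 200_000, burn_in: int = 50_000, thin: int = 5,
              seed: int = 0,
              nu_e: float = 5.0, nu_m: float = 5.0, r2_prior: float = 0.5,
              pi_zero_init: float = 0.99, update_pi: bool = True,
              fixed_sigma2_m: Optional[float] = None,
              fixed_sigma2_e: Optional[float] = None,
              keep_effect_samples: bool = False) -> PosteriorSummary:
    """Gibbs sampler for the five Bayesian whole-genome regressions.

    ``method`` is one of brr | bayes_a | bayes_b | bayes_c_pi | bl.
    ``fixed_sigma2_m`` / ``fixed_sigma2_e`` freeze the variance components
    (conjugate checking); chains are deterministic given ``seed``.
    """
    if method not in BAYES_METHODS:
        raise ValueError(f"unknown Bayesian method {method!r}")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n, q = X.shape
    if np.isnan(Z).any():
        raise ValueError("Z contains missing genotypes; mean-impute first")
    Zc, _ = center_markers(Z)
    Zc = np.asfortranarray(Zc)
    p = Zc.shape[1]
    zsq = np.einsum("ij,ij->j", Zc, Zc)

    vy = float(np.var(y))
    msx = float(zsq.sum() / n)            # sum of marker variances
    ssvs = 1 if method in ("bayes_b", "bayes_c_pi") else 0
    pi_zero = pi_zero_init if ssvs else 0.0
    incl_frac = max(1.0 - pi_zero, 1.0 / p) if ssvs else 1.0

    # prior scales: mode of scaled-inv-chi2(nu, S) is nu*S/(nu+2)
    S_e = (1.0 - r2_prior) * vy * (nu_e + 2.0) / nu_e
    S_m = r2_prior * vy * (nu_m + 2.0) / (nu_m * max(msx * incl_frac, 1e-12))

    b = np.zeros(q)
    m = np.zeros(p)
    incl = np.ones(p, dtype=np.int8)
    s2e = fixed_sigma2_e if fixed_sigma2_e is not None else 0.5 * vy
    if method == "bl":
        tau2 = np.full(p, S_m / max(s2e, 1e-12))
        lam2 = 1.0 / max(np.mean(tau2), 1e-12)
        s2m_vec = tau2 * s2e
    elif method in ("brr", "bayes_c_pi"):
        s2m_common = fixed_sigma2_m if fixed_sigma2_m is not None \
            else nu_m * S_m / (nu_m + 2.0)
        s2m_vec = np.full(p, s2m_common)
    else:  # bayes_a, bayes_b
        s2m_vec = np.full(p, nu_m * S_m / (nu_m + 2.0))
    e = y - X @ b - Zc @ m

    XtX = X.T @ X
    prior_prec_b = 1e-6      # b ~ N(0, 1e6 I)

    n_kept = 0
    m_sum = np.zeros(p)
    b_sum = np.zeros(q)
    incl_sum = np.zeros(p)
    h2_samples = []
    s2e_samples = []
    pi_samples = []
    effect_samples = [] if keep_effect_samples else None

    for it in range(n_iter):
        # --- fixed effects (joint normal update) ---
        r_fix = e + X @ b
        prec = XtX / s2e + prior_prec_b * np.eye(q)
        L = np.linalg.cholesky(prec)
        mean_b = np.linalg.solve(prec, X.T @ r_fix / s2e)
        b = mean_b + np.linalg.solve(L.T, rng.standard_normal(q))
        e = r_fix - X @ b

        # --- marker effects ---
        log_odds_excl = 0.0
        if ssvs:
            pz = min(max(pi_zero, 1e-12), 1.0 - 1e-12)
            log_odds_excl = np.log(pz / (1.0 - pz))
        marker_sweep(Zc, zsq, m, e, incl, s2m_vec, s2e, log_odds_excl,
                     ssvs, rng.standard_normal(p), rng.random(p))

        # --- variance / hyperparameter updates ---
        k_in = int(incl.sum()) if ssvs else p
        if method == "brr":
            if fixed_sigma2_m is None:
                s2m_vec[:] = _scaled_inv_chi2(
                    rng, nu_m + p, float(m @ m) + nu_m * S_m)
        elif method == "bayes_a":
            s2m_vec = (m * m + nu_m * S_m) / rng.chisquare(nu_m + 1.0, size=p)
        elif method == "bayes_b":
            chi = rng.chisquare(nu_m + incl.astype(float))
            s2m_vec = (m * m + nu_m * S_m) / chi
            if update_pi:
                pi_zero = rng.beta(1.0 + p - k_in, 1.0 + k_in)
        elif method == "bayes_c_pi":
            s2m_vec[:] = _scaled_inv_chi2(
                rng, nu_m + k_in, float(m @ m) + nu_m * S_m)
            if update_pi:
                pi_zero = rng.beta(1.0 + p - k_in, 1.0 + k_in)
        elif method == "bl":
            mj2 = np.maximum(m * m, 1e-20)
            inv_tau2 = rng.wald(np.sqrt(lam2 * s2e / mj2), lam2)
            tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
            lam2 = rng.gamma(shape=p + 1.0,
                             scale=1.0 / (0.5 * float(tau2.sum()) + 1e-4))
            s2m_vec = tau2 * s2e

        if fixed_sigma2_e is None:
            s2e = _scaled_inv_chi2(rng, nu_e + n,
                                   float(e @ e) + nu_e * S_e)
            if method == "bl":
                s2m_vec = tau2 * s2e
        if not np.isfinite(s2e) or s2e > 1e12:
            raise FloatingPointError("residual variance diverged; check "
                                     "scaling of y and Z")

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_kept += 1
            m_sum += m
            b_sum += b
            incl_sum += incl
            g = Zc @ m
            vg = float(np.var(g))
            h2_samples.append(vg / (vg + s2e))
            s2e_samples.append(s2e)
            if ssvs:
                pi_samples.append(pi_zero)
            if keep_effect_samples:
                effect_samples.append(m.copy())

    hyper = {"nu_e": nu_e, "nu_m": nu_m, "S_e": S_e, "S_m": S_m,
             "r2_prior": r2_prior}
    if ssvs:
        hyper["pi_zero_mean"] = float(np.mean(pi_samples))
    if method == "bl":
        hyper["lambda2_last"] = float(lam2)
    if keep_effect_samples:
        hyper["effect_samples"] = np.asarray(effect_samples)
    h2_samples = np.asarray(h2_samples)
    return PosteriorSummary(
        marker_effect_means=m_sum / n_kept,
        b_mean=b_sum / n_kept,
        h2_samples=h2_samples,
        h2_mean=float(h2_samples.mean()),
        sigma2_e_mean=float(np.mean(s2e_samples)),
        inclusion_prob=(incl_sum / n_kept) if ssvs else None,
        hyper=hyper,
        chain={"n_iter": n_iter, "burn_in": burn_in, "thin": thin,
               "seed": seed, "kept": n_kept},
    )


def predictive_ability(y_obs: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation r(y, GEBV)."""
    y_obs = np.asarray(y_obs, float).ravel()
    gebv = np.asarray(gebv, float).ravel()
    if len(y_obs) != len(gebv) or len(y_obs) < 3:
        raise ValueError("need >= 3 aligned pairs")
    if y_obs.std() == 0 or gebv.std() == 0:
        raise ValueError("zero variance in observed or predicted values")
    return float(np.corrcoef(y_obs, gebv)[0, 1])


def cross_validate(y: np.ndarray, X: np.ndarray, method: str,
                   K: Optional[np.ndarray] = None,
                   Z: Optional[np.ndarray] = None,
                   k_folds: int = 10, seed: int = 0,
                   adjust_validation: bool = True,
                   chain: Optional[dict] = None) -> CVResult:
    """K-fold cross-validated predictive ability.

    ``method``: 'ablup'/'gblup' use the kinship route (``K`` required; for
    GBLUP pass the VanRaden G); 'rrblup' and the Bayesian methods use the
    marker route (``Z`` raw dosages required). Fold predictive ability is the
    correlation between validation phenotypes (block effects removed with
    training estimates when ``adjust_validation``) and validation GEBVs.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = np.asarray(y, float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k_folds)):
        assign[chunk] = f
    chain = dict(chain or {})

    fold_r = []
    for f in range(k_folds):
        v = np.flatnonzero(assign == f)
        t = np.flatnonzero(assign != f)
        if len(v) < 3:
            raise ValueError("fold with fewer than 3 validation individuals")
        cols = _drop_null_columns(X[t])
        Xt, Xv = X[t][:, cols], X[v][:, cols]

        if method in ("ablup", "gblup"):
            if K is None:
                raise ValueError(f"{method} requires a kinship matrix")
            fit = reml_fit(y[t], Xt, K[np.ix_(t, t)])
            gebv = predict_gebv(fit, K[np.ix_(v, t)])
            b_hat = fit.b_hat
        elif method == "rrblup":
            if Z is None:
                raise ValueError("rrblup requires marker dosages Z")
            fit, m_hat, _, center = gblup_to_marker_effects(y[t], Xt, Z[t])
            gebv = (Z[v] - center) @ m_hat
            b_hat = fit.b_hat
        elif method in BAYES_METHODS:
            if Z is None:
                raise ValueError("Bayesian methods require marker dosages Z")
            Zt_c, means = center_markers(Z[t])
            post = gibbs_fit(y[t], Xt, Z[t], method=method,
                             seed=seed * 1000 + f, **chain)
            gebv = (Z[v] - means) @ post.marker_effect_means
            b_hat = post.b_mean
        else:
            raise ValueError(f"unknown prediction method {method!r}")

        y_v = y[v] - Xv @ b_hat if adjust_validation else y[v]
        fold_r.append(predictive_ability(y_v, gebv))

    fold_r = np.asarray(fold_r)
    return CVResult(fold_r=fold_r, mean_r=float(fold_r.mean()),
                    se_r=float(fold_r.std(ddof=1) / np.sqrt(k_folds)),
                    fold_assignments=assign)
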