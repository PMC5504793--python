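"""Relationship matrices, genotype PCA and relatedness-controlled splits.

Pedigree A assumes a single generation of maternal half-sib families
(diagonal 1, 0.25 between individuals sharing a mother, 0 otherwise).
The genomic relationship matrix follows VanRaden's first method,

    G = W W' / (2 sum_k p_k (1 - p_k)),   W = dosage - 2 p_k,

and the Powell-Visscher-Balding unified estimator standardizes identity
per locus before averaging (the GCTA formulation). PCA is the eigen
decomposition of the VanRaden G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geno import GenotypeMatrix

__all__ = ["KinshipMatrix", "SplitPlan", "pedigree_A", "grm_vanraden",
           "grm_powell", "pca", "make_split"]


@dataclass
class KinshipMatrix:
    ids: list
    values: np.ndarray
    method: str   # pedigree_A | vanraden | powell

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kinship shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    def ensure_psd(self, tol: float = -1e-8) -> "KinshipMatrix":
        """Minimal-ridge PSD repair: add (|lambda_min| + 1e-8) I if needed."""
        w = np.linalg.eigvalsh(self.values)
        if w.min() < tol:
            delta = abs(w.min()) + 1e-8
            return KinshipMatrix(self.ids, self.values + delta * np.eye(len(self.ids)),
                                 self.method)
        return self


@dataclass
class SplitPlan:
    train_ids: list
    valid_ids: list
    basis: str                      # pca_clusters | random
    excluded_outliers: list = field(default_factory=list)

    def __post_init__(self):
        if set(self.train_ids) & set(self.valid_ids):
            raise ValueError("train and validation sets overlap")


def pedigree_A(pedigree: pd.DataFrame, id_col: str = "id",
               mother_col: str = "mother") -> KinshipMatrix:
    """Expected additive relationship under one generation of OP half-sib
    families: A_ii = 1, A_ij = 0.25 for maternal half-sibs, else 0."""
    if pedigree[mother_col].isna().any():
        raise ValueError("individual with no family label")
    ids = list(pedigree[id_col])
    mothers = pedigree[mother_col].to_numpy()
    same = (mothers[:, None] == mothers[None, :]).astype(np.float64)
    A = 0.25 * same
    np.fill_diagonal(A, 1.0)
    return KinshipMatrix(ids=ids, values=A, method="pedigree_A")


def _check_imputed(g: GenotypeMatrix) -> np.ndarray:
    if np.isnan(g.dosage).any():
        raise ValueError("genotypes contain missing values; impute first")
    return g.dosage


def grm_vanraden(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden method-1 GRM from imputed dosages.

    Zero-variance (monomorphic) markers contribute nothing to either the
    numerator or the scaling constant.
    """
    dos = _check_imputed(g)
    p = dos.mean(axis=0) / 2.0
    W = dos - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM undefined")
    G = (W @ W.T) / denom
    return KinshipMatrix(ids=list(g.samples), values=0.5 * (G + G.T),
                         method="vanraden")


def grm_powell(g: GenotypeMatrix) -> KinshipMatrix:
    """Powell-Visscher-Balding unified relatedness (per-locus standardized
    identity averaged over loci; the GCTA estimator). Used for LD
    corrections."""
    dos = _check_imputed(g)
    p = dos.mean(axis=0) / 2.0
    het = 2.0 * p * (1.0 - p)
    use = het > 0
    if not use.any():
        raise ValueError("all markers monomorphic; GRM undefined")
    x = dos[:, use]
    pk = p[use]
    hk = het[use]
    m = use.sum()
    W = (x - 2.0 * pk) / np.sqrt(hk)
    G = (W @ W.T) / m
    # diagonal uses the within-individual estimator 1 + F
    diag = 1.0 + np.mean(
        (x * x - (1.0 + 2.0 * pk) * x + 2.0 * pk * pk) / hk, axis=1)
    np.fill_diagonal(G, diag)
    return KinshipMatrix(ids=list(g.samples), values=0.5 * (G + G.T),
                         method="powell")


def pca(g: GenotypeMatrix, n_components: int = 10):
    """Genotype PCA via eigen decomposition of the VanRaden GRM.

    Returns ``(scores, eigenvalues)`` with scores = U_k sqrt(lambda_k);
    eigenvalues are non-increasing and sum to the trace of G.
    """
    if g.n_samples < 2:
        raise ValueError("PCA needs at least 2 individuals")
    if n_components > g.n_samples:
        raise ValueError("n_components exceeds sample count")
    G = grm_vanraden(g).values
    w, U = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w = w[order][:n_components]
    U = U[:, order][:, :n_components]
    scores = U * np.sqrt(np.maximum(w, 0.0))
    # deterministic sign: largest-magnitude loading positive
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(scores[:, k]))
        if scores[j, k] < 0:
            scores[:, k] = -scores[:, k]
    return scores, w


def make_split(scores: np.ndarray, ids: list, mode: str = "unrelated",
               n_pcs: int = 2, outlier_sd: float = 6.0,
               sizes: Optional[tuple] = None,
               seed: int = 0) -> SplitPlan:
    """Training/validation split for relatedness-controlled prediction.

    ``unrelated`` removes outliers (any leading-PC score beyond
    ``outlier_sd`` standard deviations), clusters the rest with k-means
    (k = 2) on the leading PCs, and uses the larger cluster for training.
    ``random`` reproduces given set sizes with uniformly random membership.
    """
    ids = list(ids)
    rng = np.random.default_rng(seed)
    if mode == "random":
        if sizes is None:
            raise ValueError("random mode requires target (train, valid) sizes")
        n_train, n_valid = sizes
        if n_train + n_valid > len(ids):
            raise ValueError("requested sizes exceed available individuals")
        perm = rng.permutation(len(ids))
        return SplitPlan(train_ids=[ids[i] for i in perm[:n_train]],
                         valid_ids=[ids[i] for i in perm[n_train:n_train + n_valid]],
                         basis="random")
    if mode != "unrelated":
        raise ValueError(f"unknown split mode {mode!r}")

    X = np.asarray(scores)[:, :n_pcs]
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    out_mask = (np.abs(X - X.mean(axis=0)) > outlier_sd * sd).any(axis=1)
    keep = np.flatnonzero(~out_mask)
    if len(keep) < 4:
        raise ValueError("too few individuals after outlier removal")
    labels = _kmeans2(X[keep], rng)
    n0 = int((labels == 0).sum())
    n1 = int((labels == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("degenerate clustering: an empty cluster")
    train_lab = 0 if n0 >= n1 else 1
    train = [ids[i] for i, l in zip(keep, labels) if l == train_lab]
    valid = [ids[i] for i, l in zip(keep, labels) if l != train_lab]
    return SplitPlan(train_ids=train, valid_ids=valid, basis="pca_clusters",
                     excluded_outliers=[ids[i] for i in np.flatnonzero(out_mask)])


def _kmeans2(X: np.ndarray, rng: np.random.Generator,
             n_restarts: int = 10, n_iter: int = 100) -> np.ndarray:
    """Seeded k-means with k = 2 (small, deterministic; avoids thread-order
    nondeterminism in library implementations)."""
    best_inertia = np.inf
    best = None
    for _ in range(n_restarts):
        centers = X[rng.choice(len(X), size=2, replace=False)]
        for _ in range(n_iter):
            d = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
            lab = d.argmin(axis=1)
            new = np.array([X[lab == k].mean(axis=0) if (lab == k).any()
                            else centers[k] for k in range(2)])
            if np.allclose(new, centers):
                break
            centers = new
        inertia = ((X - centers[lab]) ** 2).sum()
        if inertia < best_inertia - 1e-12:
            best_inertia = inertia
            best = lab
    return best
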