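"""Genotype container, QC filters, mean imputation, LD pruning and SNP
subset sampling schemes.

The dosage table codes each genotype as the count of the minor allele
(0, 1, 2) with ``NaN`` marking missing calls, the coding used throughout
whole-genome regression (Z takes 2/1/0 for AA/Aa/aa with `a` the least
frequent allele).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SubsetSpec",
    "filter_snps",
    "impute_mean",
    "ld_prune",
    "sample_subset",
    "CUMULATIVE_LADDER",
    "EVEN_WINDOWS_BP",
]

log = logging.getLogger("treegs")

# subset-size ladder for stratified random sampling: small steps below 2000,
# then +1000 increments up to the full panel
CUMULATIVE_LADDER = [100, 150, 200, 250, 300, 500, 750, 1000, 1250, 1500, 2000]
# window widths for the evenly spaced scheme
EVEN_WINDOWS_BP = [10_000, 50_000, 100_000, 250_000, 500_000, 1_000_000]


@dataclass
class GenotypeMatrix:
    """Individuals x markers minor-allele dosage table with a physical map."""

    samples: list
    markers: list
    dosage: np.ndarray           # (n, p) float, NaN = missing
    chrom: np.ndarray            # (p,) chromosome label
    pos_bp: np.ndarray           # (p,) 1-based physical position

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        n, p = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError("sample ids do not match dosage rows")
        if len(self.markers) != p or len(self.chrom) != p or len(self.pos_bp) != p:
            raise ValueError("marker metadata does not match dosage columns")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.markers)) != p:
            raise ValueError("duplicate marker ids")
        for c in np.unique(self.chrom):
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    @property
    def allele_freq(self) -> np.ndarray:
        """Observed frequency of the counted allele (= minor if coded so)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.allele_freq
        return np.minimum(f, 1.0 - f)

    @property
    def marker_map(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.markers,
            "chrom": self.chrom,
            "pos_bp": self.pos_bp,
            "maf": self.maf,
            "call_rate": self.call_rate,
        })

    def subset_markers(self, keep) -> "GenotypeMatrix":
        """New matrix restricted to markers given by ids or integer index."""
        if len(keep) and isinstance(keep[0], str):
            lookup = {m: i for i, m in enumerate(self.markers)}
            idx = np.array([lookup[m] for m in keep], dtype=int)
        else:
            idx = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=[self.markers[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
            chrom=self.chrom[idx].copy(),
            pos_bp=self.pos_bp[idx].copy(),
        )

    def subset_samples(self, keep) -> "GenotypeMatrix":
        if len(keep) and isinstance(keep[0], str):
            lookup = {s: i for i, s in enumerate(self.samples)}
            idx = np.array([lookup[s] for s in keep], dtype=int)
        else:
            idx = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            markers=list(self.markers),
            dosage=self.dosage[idx].copy(),
            chrom=self.chrom.copy(),
            pos_bp=self.pos_bp.copy(),
        )


@dataclass
class SubsetSpec:
    """Parameters of one SNP-subset sampling scheme."""

    scheme: str
    size: Optional[int] = None
    window_bp: Optional[int] = None
    chrom: Optional[str] = None
    seed: Optional[int] = None
    sizes: Optional[Sequence[int]] = None   # cumulative ladder override

    _SCHEMES = {"random_stratified_cumulative", "random_noncumulative",
                "evenly_spaced", "genic", "intergenic", "ld_pruned",
                "single_chromosome"}

    def __post_init__(self):
        if self.scheme not in self._SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        need = {
            "random_stratified_cumulative": ("seed",),
            "random_noncumulative": ("size", "seed"),
            "evenly_spaced": ("window_bp",),
            "genic": (),
            "intergenic": (),
            "ld_pruned": (),
            "single_chromosome": ("chrom",),
        }[self.scheme]
        missing = [k for k in need if getattr(self, k) is None]
        if missing:
            raise ValueError(
                f"scheme {self.scheme!r} requires {', '.join(missing)}")


def filter_snps(g: GenotypeMatrix, cr_min: float = 0.90,
                maf_min: float = 0.0) -> GenotypeMatrix:
    """QC filter on call rate and minor-allele frequency.

    Markers are kept when ``call_rate >= cr_min`` and, with ``maf_min == 0``,
    when they are polymorphic (MAF > 0, strict); with ``maf_min > 0`` the
    threshold is inclusive (MAF >= maf_min). The input is not modified.
    """
    if not (0.0 <= cr_min <= 1.0 and 0.0 <= maf_min <= 0.5):
        raise ValueError("thresholds out of range")
    cr_ok = g.call_rate >= cr_min
    maf = g.maf
    maf_ok = (maf > 0.0) if maf_min == 0.0 else (maf >= maf_min)
    keep = cr_ok & maf_ok
    log.info("filter_snps: %d markers in, %d removed by CR, %d by MAF, %d kept",
             g.n_markers, int((~cr_ok).sum()),
             int((cr_ok & ~maf_ok).sum()), int(keep.sum()))
    if not keep.any():
        raise ValueError("no markers pass the QC filter")
    return g.subset_markers(np.flatnonzero(keep))


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing genotypes with the marker's observed mean dosage."""
    dos = g.dosage
    miss = np.isnan(dos)
    if not miss.any():
        return g.subset_markers(np.arange(g.n_markers))
    if miss.all(axis=0).any():
        raise ValueError("marker with no observed genotypes; filter first "
                         "(filter_snps with cr_min > 0)")
    out = dos.copy()
    col_mean = np.nanmean(dos, axis=0)
    rows, cols = np.where(miss)
    out[rows, cols] = col_mean[cols]
    return GenotypeMatrix(samples=list(g.samples), markers=list(g.markers),
                          dosage=out, chrom=g.chrom.copy(),
                          pos_bp=g.pos_bp.copy())


def ld_prune(g: GenotypeMatrix, window_kb: float = 100.0, step_snps: int = 1,
             r2_max: float = 0.2) -> list:
    """Greedy within-chromosome LD pruning (PLINK --indep-pairwise style).

    Slides a ``window_kb`` window one SNP at a time; whenever a retained pair
    within the window has r^2 > ``r2_max``, the member with the lower MAF is
    dropped (ties: the later position). r^2 is computed on mean-imputed
    dosages, so the pass is deterministic. Returns retained marker ids; no
    surviving within-window pair exceeds the threshold.
    """
    if window_kb <= 0:
        raise ValueError("window must be positive")
    window_bp = int(window_kb * 1000)
    dos = impute_mean(g).dosage
    # standardize columns once; zero-variance markers never prune anything
    mu = dos.mean(axis=0)
    sd = dos.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(dos)
    z[:, ok] = (dos[:, ok] - mu[ok]) / sd[ok]
    n = dos.shape[0]
    maf = g.maf

    keep = np.ones(g.n_markers, dtype=bool)
    for c in np.unique(g.chrom):
        cidx = np.flatnonzero(g.chrom == c)
        pos = g.pos_bp[cidx]
        for a_local in range(0, len(cidx), step_snps):
            a = cidx[a_local]
            if not keep[a]:
                continue
            hi = np.searchsorted(pos, pos[a_local] + window_bp, side="right")
            for b_local in range(a_local + 1, hi):
                b = cidx[b_local]
                if not keep[a]:
                    break
                if not keep[b]:
                    continue
                r = z[:, a] @ z[:, b] / n
                if r * r > r2_max:
                    if maf[a] < maf[b]:
                        keep[a] = False
                    elif maf[b] < maf[a]:
                        keep[b] = False
                    else:   # tie: drop the later position
                        keep[b] = False
    return [g.markers[i] for i in np.flatnonzero(keep)]


def _stratified_order(g: GenotypeMatrix, rng: np.random.Generator) -> np.ndarray:
    """Global marker order that interleaves chromosomes proportionally.

    Markers are permuted within each chromosome, then merged by their
    fractional rank within the chromosome; any prefix of the result is a
    chromosome-proportional stratified sample and prefixes are nested.
    """
    frac = np.empty(g.n_markers)
    for c in np.unique(g.chrom):
        cidx = np.flatnonzero(g.chrom == c)
        perm = rng.permutation(len(cidx))
        frac[cidx] = (perm + 0.5) / len(cidx)
    # stable tie-break by a second random key
    jitter = rng.random(g.n_markers) * 1e-9
    return np.argsort(frac + jitter)


def sample_subset(g: GenotypeMatrix, spec: SubsetSpec,
                  annotation: Optional[pd.DataFrame] = None):
    """SNP subsets under the six sampling schemes.

    Returns a list of marker ids, except ``random_stratified_cumulative``
    which returns ``(sizes, [list per size])`` with nested sets.
    ``annotation`` (chrom, start, end; BED convention) is required for the
    genic/intergenic schemes.
    """
    p = g.n_markers
    if spec.scheme == "random_stratified_cumulative":
        rng = np.random.default_rng(spec.seed)
        order = _stratified_order(g, rng)
        sizes = list(spec.sizes) if spec.sizes is not None else \
            [s for s in CUMULATIVE_LADDER if s < p] + \
            list(range(3000, p, 1000)) + [p]
        if max(sizes) > p:
            raise ValueError("requested size exceeds available markers")
        return sizes, [[g.markers[i] for i in order[:s]] for s in sizes]

    if spec.scheme == "random_noncumulative":
        if spec.size > p:
            raise ValueError("requested size exceeds available markers")
        rng = np.random.default_rng(spec.seed)
        order = _stratified_order(g, rng)
        return sorted([g.markers[i] for i in order[:spec.size]],
                      key={m: i for i, m in enumerate(g.markers)}.get)

    if spec.scheme == "evenly_spaced":
        keep = []
        for c in np.unique(g.chrom):
            cidx = np.flatnonzero(g.chrom == c)
            pos = g.pos_bp[cidx]
            win = pos // spec.window_bp
            mid = win * spec.window_bp + spec.window_bp // 2
            for w in np.unique(win):
                members = cidx[win == w]
                d = np.abs(g.pos_bp[members] - mid[win == w][0])
                keep.append(members[np.argmin(d)])
        keep = np.sort(np.asarray(keep))
        return [g.markers[i] for i in keep]

    if spec.scheme in ("genic", "intergenic"):
        if annotation is None:
            raise ValueError(f"scheme {spec.scheme!r} requires an annotation")
        genic = _in_intervals(g, annotation)
        mask = genic if spec.scheme == "genic" else ~genic
        return [g.markers[i] for i in np.flatnonzero(mask)]

    if spec.scheme == "ld_pruned":
        return ld_prune(g)

    if spec.scheme == "single_chromosome":
        cidx = np.flatnonzero(g.chrom == spec.chrom)
        if len(cidx) == 0:
            raise ValueError(f"no markers on chromosome {spec.chrom!r}")
        return [g.markers[i] for i in cidx]

    raise ValueError(f"unknown scheme {spec.scheme!r}")


def _in_intervals(g: GenotypeMatrix, annotation: pd.DataFrame) -> np.ndarray:
    """Boolean genic membership per marker (BED half-open; positions 1-based)."""
    out = np.zeros(g.n_markers, dtype=bool)
    for c, sub in annotation.groupby("chrom"):
        cmask = g.chrom == c
        if not cmask.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = sub.sort_values("start")["end"].to_numpy()
        pos0 = g.pos_bp[cmask] - 1     # 0-based coordinate of the site
        k = np.searchsorted(starts, pos0, side="right") - 1
        hit = (k >= 0) & (pos0 < ends[np.clip(k, 0, None)])
        out[np.flatnonzero(cmask)] = hit
    return out
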