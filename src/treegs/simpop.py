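"""Forward simulation of open-pollinated half-sib breeding populations.

The simulator emulates the data-generating process behind a typical
first-generation forest-tree breeding trial: a small effective number of
parents (Ne in the tens) whose drift-generated linkage disequilibrium is the
signal exploited both by genomic prediction and by LD-based Ne estimation;
optional divergence into two subpopulations (K = 2 structure); seed collected
from open-pollinated mothers so that progeny within a family are maternal
half-sibs; and an additive quantitative trait measured in a randomized
complete block design.

Model summary
-------------
* Discrete-generation Wright-Fisher diploids, random mating (selfing
  allowed), no selection or mutation.
* Uniform recombination at 1 cM/Mbp; chromosomes assort independently.
* Markers start at uniform-random allele frequencies and drift for
  ``equilibration_factor * ne`` generations so that LD reaches its
  drift-recombination equilibrium for the target Ne; the candidate pool is
  oversampled and thinned back to segregating sites, emulating the
  polymorphism ascertainment of genotyping chips.
* Structure: the population descends from a larger ancestral stand
  (``ancestral_factor * ne`` diploids); two islands of ``ne`` diploids are
  founded from it and drift independently for ``t = round(2 * ne * fst)``
  generations (Fst ~ t / (2 Ne) for small t). The larger ancestral phase
  keeps the K = 2 divergence, not within-island coancestry, as the leading
  axis of genetic structure.
* Trait: ``n_qtl`` causal loci with normal effects rescaled so the additive
  variance share equals ``h2_true`` (phenotypic variance fixed at 1 before
  block effects); block effects N(0, block_sd^2) in an RCBD layout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geno import GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimOutput",
    "HaplotypePool",
    "simulate_base",
    "sample_op_families",
    "simulate_trait",
    "annotate_genes",
    "simulate_population",
]

# 1 cM per Mbp expressed as Morgans per base pair
MORGAN_PER_BP = 1e-8

log = logging.getLogger("treegs")


@dataclass
class SimConfig:
    """Parameters of one simulated breeding population.

    Defaults emulate a tropical eucalypt progeny trial: Ne ~ 50, 11
    chromosomes, ~14k polymorphic chip SNPs, 40 open-pollinated families of
    ~13 trees (520 genotyped individuals), two weakly diverged subpopulations,
    and a growth trait with moderate heritability scored in 40 blocks.
    """

    ne: int = 50
    n_chrom: int = 11
    chrom_len_bp: int = 50_000_000
    n_markers: int = 13_787
    n_families: int = 40
    progeny_per_family: int = 13
    fst: float = 0.10
    n_qtl: int = 300
    h2_true: float = 0.30
    n_blocks: int = 40
    block_sd: float = 0.5
    missing_rate: float = 0.01
    seed: int = 0
    equilibration_factor: float = 4.0
    # candidate sites simulated per retained marker: drift fixes most loci,
    # and genotyping chips are ascertained to be polymorphic, so the pool is
    # thinned back to n_markers segregating sites after equilibration
    ascertainment_oversample: float = 8.0
    # structured populations descend from a larger ancestral stand
    # (ancestral_factor * ne diploids) so that the K=2 divergence, not
    # within-island coancestry, is the leading axis of structure
    ancestral_factor: float = 4.0

    def __post_init__(self) -> None:
        errs = []
        if self.ne < 2:
            errs.append("ne must be >= 2")
        if not (0.0 <= self.fst < 1.0):
            errs.append("fst must be in [0, 1)")
        if not (0.0 <= self.h2_true <= 1.0):
            errs.append("h2_true must be in [0, 1]")
        if self.n_qtl > self.n_markers:
            errs.append("n_qtl cannot exceed n_markers")
        for name in ("n_chrom", "chrom_len_bp", "n_markers", "n_families",
                     "progeny_per_family", "n_blocks"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be positive")
        if self.n_qtl < 0:
            errs.append("n_qtl must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            errs.append("missing_rate must be in [0, 1)")
        if errs:
            raise ValueError("invalid SimConfig: " + "; ".join(errs))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class HaplotypePool:
    """Phased haplotypes of the parental (adult) generation.

    ``haplotypes`` has shape (2 * n_adults, p): rows 2i and 2i+1 are the two
    gametic haplotypes of adult i. ``subpop`` labels each adult 0 or 1.
    """

    haplotypes: np.ndarray
    chrom: np.ndarray          # chromosome label per marker, e.g. "Chr01"
    pos_bp: np.ndarray         # 1-based position per marker
    subpop: np.ndarray         # per-adult subpopulation label
    init_freq: np.ndarray = None   # initialization frequency per marker

    @property
    def n_adults(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class SimOutput:
    """Genotypes, pedigree, phenotypes and the generating truth."""

    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame     # id, mother, family, subpop
    phenotypes: pd.DataFrame   # id, family, block, subpop, trait
    truth: dict = field(default_factory=dict)


def _marker_layout(cfg: SimConfig, rng: np.random.Generator,
                   n_sites: Optional[int] = None):
    """Distribute candidate sites across chromosomes with sorted uniform
    positions."""
    total = cfg.n_markers if n_sites is None else n_sites
    base = total // cfg.n_chrom
    counts = np.full(cfg.n_chrom, base, dtype=int)
    counts[: total - base * cfg.n_chrom] += 1
    chrom = []
    pos = []
    for c in range(cfg.n_chrom):
        if counts[c] > cfg.chrom_len_bp:
            raise ValueError("marker count exceeds distinguishable sites")
        p = np.sort(rng.choice(cfg.chrom_len_bp, size=counts[c], replace=False)) + 1
        chrom.append(np.repeat(f"Chr{c + 1:02d}", counts[c]))
        pos.append(p.astype(np.int64))
    return np.concatenate(chrom), np.concatenate(pos)


def _chrom_bounds(chrom: np.ndarray):
    """Start/stop index of each chromosome block (markers are chrom-sorted)."""
    _, starts = np.unique(chrom, return_index=True)
    starts = np.sort(starts)
    stops = np.append(starts[1:], len(chrom))
    return starts, stops


def _make_gamete(h0: np.ndarray, h1: np.ndarray, starts, stops, pos_bp,
                 rng: np.random.Generator) -> np.ndarray:
    """Recombinant gamete from one diploid parent.

    Crossover count per chromosome is Poisson with mean ``L * 1e-8`` Morgans;
    chromosomes assort independently (fresh starting haplotype each).
    """
    gamete = np.empty_like(h0)
    for s, t in zip(starts, stops):
        length = pos_bp[t - 1] - pos_bp[s] + 1
        n_co = rng.poisson(length * MORGAN_PER_BP)
        start = rng.integers(2)
        if n_co == 0:
            gamete[s:t] = h0[s:t] if start == 0 else h1[s:t]
            continue
        co_pos = np.sort(rng.integers(pos_bp[s], pos_bp[t - 1], size=n_co))
        seg = np.searchsorted(co_pos, pos_bp[s:t], side="left")
        use_h1 = (start + seg) % 2 == 1
        block = np.where(use_h1, h1[s:t], h0[s:t])
        gamete[s:t] = block
    return gamete


def _drift(hap: np.ndarray, n_adults: int, generations: int, starts, stops,
           pos_bp, rng: np.random.Generator) -> np.ndarray:
    """Evolve a panmictic pool of ``n_adults`` diploids for ``generations``."""
    for _ in range(generations):
        new = np.empty_like(hap)
        mothers = rng.integers(n_adults, size=n_adults)
        fathers = rng.integers(n_adults, size=n_adults)
        for i in range(n_adults):
            m, f = mothers[i], fathers[i]
            new[2 * i] = _make_gamete(hap[2 * m], hap[2 * m + 1],
                                      starts, stops, pos_bp, rng)
            new[2 * i + 1] = _make_gamete(hap[2 * f], hap[2 * f + 1],
                                          starts, stops, pos_bp, rng)
        hap = new
    return hap


def simulate_base(cfg: SimConfig, rng: Optional[np.random.Generator] = None,
                  generations: Optional[int] = None) -> HaplotypePool:
    """Wright-Fisher forward simulation of the adult (parental) pool.

    Returns phased haplotypes for ``ne`` diploids per subpopulation: one
    pool equilibrated for ``equilibration_factor * ne`` generations when
    ``fst == 0``, otherwise two islands founded from a larger ancestral
    stand and drifted apart for ``2 * ne * fst`` generations (see the module
    docstring). Candidate sites are ascertained back to ``n_markers``
    segregating markers. ``generations`` overrides the equilibration (or
    ancestral-phase) length, e.g. 0 for the no-drift edge case.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_sites = int(round(cfg.n_markers * max(cfg.ascertainment_oversample, 1.0)))
    chrom, pos_bp = _marker_layout(cfg, rng, n_sites=n_sites)
    starts, stops = _chrom_bounds(chrom)

    # independent-locus initialization at uniform-random frequencies;
    # drift builds the LD
    freqs = rng.uniform(0.05, 0.95, size=n_sites)

    if cfg.fst > 0.0:
        # two-phase demography: a larger ancestral stand (so within-island
        # coancestry stays small relative to the split), then two islands of
        # ne diploids drifting apart for t ~ 2 * ne * fst generations
        n_anc = max(cfg.ne, int(round(cfg.ancestral_factor * cfg.ne)))
        hap = (rng.random((2 * n_anc, n_sites)) < freqs).astype(np.int8)
        t_anc = cfg.ne if generations is None else int(generations)
        hap = _drift(hap, n_anc, t_anc, starts, stops, pos_bp, rng)
        t_split = max(1, int(round(2 * cfg.ne * cfg.fst)))
        founders = rng.choice(n_anc, 2 * cfg.ne, replace=False)
        rows_a = np.repeat(2 * founders[:cfg.ne], 2) + np.tile([0, 1], cfg.ne)
        rows_b = np.repeat(2 * founders[cfg.ne:], 2) + np.tile([0, 1], cfg.ne)
        pool_a = _drift(hap[rows_a].copy(), cfg.ne, t_split,
                        starts, stops, pos_bp, rng)
        pool_b = _drift(hap[rows_b].copy(), cfg.ne, t_split,
                        starts, stops, pos_bp, rng)
        hap = np.vstack([pool_a, pool_b])
        subpop = np.repeat([0, 1], cfg.ne)
    else:
        hap = (rng.random((2 * cfg.ne, n_sites)) < freqs).astype(np.int8)
        t_eq = int(round(cfg.equilibration_factor * cfg.ne)) \
            if generations is None else int(generations)
        hap = _drift(hap, cfg.ne, t_eq, starts, stops, pos_bp, rng)
        subpop = np.zeros(cfg.ne, dtype=int)

    # ascertain segregating sites, thinned evenly back to the target panel
    freq_now = hap.mean(axis=0)
    seg = np.flatnonzero((freq_now > 0.0) & (freq_now < 1.0))
    if len(seg) > cfg.n_markers:
        pick = seg[np.round(np.linspace(0, len(seg) - 1,
                                        cfg.n_markers)).astype(int)]
    else:
        log.warning("only %d of %d candidate sites remain segregating",
                    len(seg), n_sites)
        pick = seg
    return HaplotypePool(haplotypes=np.ascontiguousarray(hap[:, pick]),
                         chrom=chrom[pick], pos_bp=pos_bp[pick],
                         subpop=subpop, init_freq=freqs[pick])


def sample_op_families(pool: HaplotypePool, cfg: SimConfig,
                       rng: Optional[np.random.Generator] = None):
    """Open-pollinated family sampling from the adult pool.

    Mothers are drawn without replacement; each offspring receives one
    recombinant maternal gamete and one gamete from a random non-maternal
    adult of the mother's subpopulation (the pollen pool). Returns
    ``(genotypes, pedigree)`` with dosages coded as minor-allele counts and
    missingness applied completely at random at ``cfg.missing_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n_adults = pool.n_adults
    if cfg.n_families > n_adults:
        raise ValueError(
            f"n_families={cfg.n_families} exceeds adult pool size {n_adults}")
    starts, stops = _chrom_bounds(pool.chrom)

    mothers = rng.choice(n_adults, size=cfg.n_families, replace=False)
    n_off = cfg.n_families * cfg.progeny_per_family
    dosage = np.empty((n_off, pool.n_markers), dtype=np.float64)
    rows = []
    idx = 0
    for fam, mom in enumerate(mothers):
        sp = pool.subpop[mom]
        pollen_pool = np.flatnonzero((pool.subpop == sp)
                                     & (np.arange(n_adults) != mom))
        for _ in range(cfg.progeny_per_family):
            dad = pollen_pool[rng.integers(len(pollen_pool))]
            g_m = _make_gamete(pool.haplotypes[2 * mom],
                               pool.haplotypes[2 * mom + 1],
                               starts, stops, pool.pos_bp, rng)
            g_p = _make_gamete(pool.haplotypes[2 * dad],
                               pool.haplotypes[2 * dad + 1],
                               starts, stops, pool.pos_bp, rng)
            dosage[idx] = g_m.astype(np.float64) + g_p
            rows.append({"id": f"T{idx + 1:04d}", "mother": f"M{mom:03d}",
                         "family": fam, "subpop": int(sp)})
            idx += 1
    pedigree = pd.DataFrame(rows)

    # recode to minor-allele counts so 0 <= maf <= 0.5 holds by construction
    freq = dosage.mean(axis=0) / 2.0
    flip = freq > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]

    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan

    g = GenotypeMatrix(
        samples=list(pedigree["id"]),
        markers=[f"snp{k + 1:05d}" for k in range(pool.n_markers)],
        dosage=dosage,
        chrom=pool.chrom.copy(),
        pos_bp=pool.pos_bp.copy(),
    )
    return g, pedigree


def simulate_trait(genotypes: GenotypeMatrix, pedigree: pd.DataFrame,
                   cfg: SimConfig,
                   rng: Optional[np.random.Generator] = None):
    """Additive trait in a randomized complete block design.

    QTL are sampled uniformly among markers and their N(0,1) effects rescaled
    so that Var(additive) / Var(additive + residual) = ``h2_true`` with the
    genetic-plus-residual variance fixed at 1. ``h2_true == 0`` keeps nonzero
    QTL effects and instead inflates the residual variance so the realized
    additive share is negligible (1e-4). Block effects are N(0, block_sd^2);
    within each family progeny are spread one-per-block where counts permit.

    Returns ``(phenotypes, truth)``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    if cfg.n_qtl == 0 and cfg.h2_true > 0:
        raise ValueError("degenerate config: h2_true > 0 requires n_qtl > 0")

    n = genotypes.n_samples
    # truth is built from complete dosages: mask applied downstream only
    dos = genotypes.dosage.copy()
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.where(np.isnan(dos))
        dos[nan_r, nan_c] = col_mean[nan_c]

    if cfg.n_qtl > 0:
        qtl_idx = np.sort(rng.choice(genotypes.n_markers, size=cfg.n_qtl,
                                     replace=False))
        beta = rng.standard_normal(cfg.n_qtl)
        bv_raw = dos[:, qtl_idx] @ beta
        var_a = bv_raw.var()
        if var_a <= 0:
            raise ValueError("all sampled QTL are monomorphic; cannot scale")
        if cfg.h2_true > 0:
            beta = beta * np.sqrt(cfg.h2_true / var_a)
            var_e = 1.0 - cfg.h2_true
        else:
            beta = beta / np.sqrt(var_a)          # additive variance 1 ...
            var_e = 1e4                           # ... swamped by residual
        bv = dos[:, qtl_idx] @ beta
    else:
        qtl_idx = np.array([], dtype=int)
        beta = np.array([])
        bv = np.zeros(n)
        var_e = 1.0
    bv = bv - bv.mean()

    if cfg.h2_true >= 1.0 and cfg.n_qtl > 0:
        resid = np.zeros(n)
    else:
        resid = rng.normal(0.0, np.sqrt(var_e), size=n)

    # RCBD layout: shuffle each family's progeny over blocks, one per block
    # where family size permits (wraps if progeny > blocks)
    block = np.empty(n, dtype=int)
    for fam, idx in pedigree.groupby("family").indices.items():
        order = rng.permutation(len(idx))
        block[idx] = (order % cfg.n_blocks)
    block_eff = rng.normal(0.0, cfg.block_sd, size=cfg.n_blocks)

    y = bv + resid + block_eff[block]
    denom = bv.var() + resid.var()
    realized_h2 = float(bv.var() / denom) if denom > 0 else 0.0

    phenotypes = pd.DataFrame({
        "id": pedigree["id"].to_numpy(),
        "family": pedigree["family"].to_numpy(),
        "block": block,
        "subpop": pedigree["subpop"].to_numpy(),
        "trait": y,
    })
    truth = {
        "qtl_idx": qtl_idx,
        "qtl_marker": [genotypes.markers[i] for i in qtl_idx],
        "qtl_beta": beta,
        "bv": bv,
        "residual": resid,
        "block_effects": block_eff,
        "realized_h2": realized_h2,
        "subpop": pedigree["subpop"].to_numpy(),
    }
    return phenotypes, truth


def annotate_genes(chrom: np.ndarray, pos_bp: np.ndarray, chrom_len_bp: int,
                   genic_fraction: float = 0.5,
                   seed: int = 0,
                   mean_gene_bp: float = 5_000.0) -> pd.DataFrame:
    """Synthetic gene-model intervals covering ~``genic_fraction`` of each
    chromosome.

    Alternates exponential gene and gap lengths (gap mean solved from the
    target fraction), giving non-overlapping intervals in BED convention
    (0-based half-open). Returns a DataFrame (chrom, start, end).
    """
    if not (0.0 < genic_fraction < 1.0):
        raise ValueError("genic_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    mean_gap = mean_gene_bp * (1.0 / genic_fraction - 1.0)
    rows = []
    for c in np.unique(chrom):
        cursor = 0.0
        while cursor < chrom_len_bp:
            cursor += rng.exponential(mean_gap)
            start = int(cursor)
            cursor += rng.exponential(mean_gene_bp)
            end = min(int(cursor), chrom_len_bp)
            if start >= chrom_len_bp or end <= start:
                break
            rows.append({"chrom": c, "start": start, "end": end})
    return pd.DataFrame(rows)


def simulate_population(cfg: SimConfig) -> SimOutput:
    """Full simulation: adult pool, OP families, trait. Seeded and
    bit-reproducible given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    pool = simulate_base(cfg, rng=rng)
    genotypes, pedigree = sample_op_families(pool, cfg, rng=rng)
    phenotypes, truth = simulate_trait(genotypes, pedigree, cfg, rng=rng)
    return SimOutput(genotypes=genotypes, pedigree=pedigree,
                     phenotypes=phenotypes, truth=truth)
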