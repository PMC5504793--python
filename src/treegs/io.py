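"""Readers and writers for the standard interchange formats.

VCF writing is plain-text v4.2 with GT only (dosages are hard genotype
calls, phase unknown). VCF reading uses cyvcf2 when available. The PLINK-1
binary trio (.bed/.bim/.fam) codec is implemented directly: the format is a
3-byte magic followed by SNP-major 2-bit genotype codes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geno import GenotypeMatrix

__all__ = [
    "write_vcf", "read_vcf",
    "write_plink", "read_plink",
    "write_phenotypes", "read_phenotypes",
    "write_truth_json",
    "write_bed_intervals",
    "write_marker_list", "read_marker_list",
    "write_kinship_tsv", "read_kinship_tsv",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])   # PLINK-1, SNP-major
# 2-bit codes: 00 hom minor (dosage 2), 01 missing, 10 het, 11 hom major (0)
_CODE_FOR_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_FOR_CODE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Plain-text VCF v4.2 with GT field; REF=A (major), ALT=B (minor)."""
    path = Path(path)
    gt_for = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=treegs\n")
        for c in pd.unique(pd.Series(g.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        dos = g.dosage
        for j in range(g.n_markers):
            col = dos[:, j]
            gts = "\t".join(
                "./." if np.isnan(v) else gt_for[int(round(v))] for v in col)
            fh.write(f"{g.chrom[j]}\t{g.pos_bp[j]}\t{g.markers[j]}"
                     f"\tA\tB\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read GT dosages from a VCF via cyvcf2 (counted allele = ALT)."""
    from cyvcf2 import VCF   # optional dependency

    vcf = VCF(str(path), gts012=True)   # gt_types: 0/1/2 = dosage, 3 missing
    samples = list(vcf.samples)
    markers, chrom, pos, rows = [], [], [], []
    for var in vcf:
        markers.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        # gt_types: 0 hom-ref, 1 het, 2 hom-alt (cyvcf2 gts012), 3 unknown
        t = np.asarray(var.gt_types, dtype=float)
        t[t == 3] = np.nan
        rows.append(t)
    vcf.close()
    dosage = np.vstack(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, markers=markers,
                          dosage=dosage, chrom=np.asarray(chrom),
                          pos_bp=np.asarray(pos, dtype=np.int64))


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """PLINK-1 binary trio: <prefix>.bed/.bim/.fam (SNP-major)."""
    prefix = Path(prefix)
    n = g.n_samples
    # vectorized 2-bit packing: dosage 2/1/0 -> codes 00/10/11, missing -> 01
    lut = np.array([0b11, 0b10, 0b00], dtype=np.uint8)
    dos = g.dosage
    codes = np.where(np.isnan(dos), 0b01,
                     lut[np.nan_to_num(dos).astype(int)]).astype(np.uint8)
    pad = (-n) % 4
    if pad:
        codes = np.vstack([codes, np.zeros((pad, g.n_markers), np.uint8)])
    quads = codes.T.reshape(g.n_markers, -1, 4)
    weights = np.array([1, 4, 16, 64], dtype=np.uint8)
    packed = (quads * weights).sum(axis=2, dtype=np.uint16).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(g.n_markers):
            fh.write(f"{g.chrom[j]}\t{g.markers[j]}\t0\t{g.pos_bp[j]}\tB\tA\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in g.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK-1 binary trio written in SNP-major order."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep="\t", header=None,
                      names=["chrom", "marker", "cm", "pos_bp", "a1", "a2"])
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    n, p = len(fam), len(bim)
    bpl = (n + 3) // 4   # bytes per locus
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK-1 .bed file")
    body = raw[3:].reshape(p, bpl)
    dosage = np.empty((n, p), dtype=np.float64)
    idx = np.arange(n)
    shifts = 2 * (idx % 4)
    bytepos = idx // 4
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    for j in range(p):
        codes = (body[j, bytepos] >> shifts) & 0b11
        dosage[:, j] = lut[codes]
    return GenotypeMatrix(samples=list(fam["iid"].astype(str)),
                          markers=list(bim["marker"].astype(str)),
                          dosage=dosage,
                          chrom=bim["chrom"].to_numpy().astype(str),
                          pos_bp=bim["pos_bp"].to_numpy())


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_json(truth: dict, path) -> None:
    def conv(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v
    with open(path, "w") as fh:
        json.dump({k: conv(v) for k, v in truth.items()}, fh, indent=1)


def write_bed_intervals(intervals: pd.DataFrame, path) -> None:
    """Gene intervals as 3-column BED (0-based half-open)."""
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_marker_list(markers, path) -> None:
    Path(path).write_text("\n".join(markers) + "\n")


def read_marker_list(path) -> list:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_kinship_tsv(ids, values: np.ndarray, path) -> None:
    """Square relationship matrix as TSV with a header row of ids."""
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, sep="\t")


def read_kinship_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index.astype(str)), df.to_numpy(dtype=np.float64)
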