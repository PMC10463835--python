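"""Genotype matrices, VCF input/output and variant-level filters.

Genotypes are stored as additive dosages of the alternate allele
(0 = hom ref, 1 = het, 2 = hom alt) in an accessions x SNPs ``int8``
array, with :data:`MISSING` (-1) marking uncalled genotypes.  Variant
metadata lives in a pandas DataFrame sorted by (chrom, pos); positions
are 1-based throughout, matching VCF convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be decoded into a biallelic dosage matrix."""


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage matrix plus its variant table.

    Parameters
    ----------
    dosages:
        ``(n_accessions, n_snps)`` int8 array with entries in {0, 1, 2, -1}.
    accession_ids:
        Ordered, unique accession labels (rows of ``dosages``).
    variants:
        DataFrame with columns ``id, chrom, pos, ref, alt`` sorted by
        (chrom, pos); one row per column of ``dosages``.
    """

    dosages: np.ndarray
    accession_ids: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.accession_ids = list(self.accession_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (accessions x SNPs)")
        if self.dosages.shape[0] != len(self.accession_ids):
            raise ValueError("row count does not match accession_ids")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("column count does not match variant table")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicate accession ids")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")
        self.variants = self.variants.reset_index(drop=True)
        pos = self.variants["pos"].to_numpy()
        if len(pos) and (pos < 1).any():
            raise ValueError("positions must be >= 1")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP id: {snp_id}")
        return int(idx[0])

    def take_snps(self, cols: np.ndarray) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        return GenotypeMatrix(
            self.dosages[:, cols],
            self.accession_ids,
            self.variants.iloc[cols].reset_index(drop=True),
        )

    def take_accessions(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            self.dosages[rows, :],
            [self.accession_ids[i] for i in rows],
            self.variants.copy(),
        )

    def region(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """Subset to SNPs on ``chrom`` with 1-based pos in [start, end]."""
        v = self.variants
        mask = (v["chrom"] == chrom) & (v["pos"] >= start) & (v["pos"] <= end)
        return self.take_snps(np.flatnonzero(mask.to_numpy()))


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic diploid VCF into a :class:`GenotypeMatrix`.

    GT fields decode as 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2 and ./. ->
    missing; phased separators are accepted.  Multiallelic records are
    skipped with a single summary warning.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} declares no samples")

    rows: list[np.ndarray] = []
    records: list[tuple] = []
    n_multi = 0
    try:
        for var in vcf:
            if len(var.ALT) != 1:
                n_multi += 1
                continue
            gt = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
            gt[gt == 3] = MISSING
            rows.append(gt)
            vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
            records.append((vid, var.CHROM, var.POS, var.REF, var.ALT[0]))
    except Exception as exc:
        raise VcfParseError(f"malformed VCF record in {path}: {exc}") from exc
    finally:
        vcf.close()

    if not records:
        raise VcfParseError(f"VCF {path} contains no usable biallelic records")
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic record(s) in {path}")

    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    dosages = np.column_stack(rows).astype(np.int8)
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    return GenotypeMatrix(dosages[:, order], samples, variants.iloc[order])


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 file (GT only, ./. for missing)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(header[:7] + ["INFO", "FORMAT"] + gm.accession_ids) + "\n")
        for j, row in enumerate(gm.variants.itertuples(index=False)):
            gts = "\t".join(_GT_STRING[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def allele_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP alternate-allele frequency, MAF and missing fraction.

    MAF = min(p, 1-p) with p the alt frequency over non-missing calls.
    SNPs with every call missing get NaN frequencies and ``all_missing``
    set, rather than raising.
    """
    if gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    d = gm.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(p, 1.0 - p)
    out = gm.variants.copy()
    out["alt_freq"] = p
    out["maf"] = maf
    out["missing_frac"] = 1.0 - n_called / gm.n_accessions
    out["all_missing"] = n_called == 0
    return out


def filter_variants(
    gm: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.2
) -> tuple[GenotypeMatrix, dict]:
    """Keep SNPs with MAF strictly above ``maf_min`` and missing fraction
    strictly below ``max_missing``; original order is preserved.

    Returns the filtered matrix and a ``{"kept": k, "dropped": d}`` summary.
    An empty result warns instead of raising.
    """
    for name, val in (("maf_min", maf_min), ("max_missing", max_missing)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    if gm.n_snps == 0:
        return gm, {"kept": 0, "dropped": 0}
    stats = allele_stats(gm)
    keep = (stats["maf"].to_numpy() > maf_min) & (
        stats["missing_frac"].to_numpy() < max_missing
    )
    keep &= ~stats["all_missing"].to_numpy()
    counts = {"kept": int(keep.sum()), "dropped": int((~keep).sum())}
    if counts["kept"] == 0:
        warnings.warn("all SNPs removed by variant filters")
    return gm.take_snps(np.flatnonzero(keep)), counts


def write_variant_report(gm: GenotypeMatrix, path: str, maf_min: float = 0.05,
                         max_missing: float = 0.2) -> pd.DataFrame:
    """TSV report of per-variant stats with the kept flag applied."""
    stats = allele_stats(gm)
    stats["kept"] = (stats["maf"] > maf_min) & (stats["missing_frac"] < max_missing)
    stats.to_csv(path, sep="\t", index=False)
    return stats
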