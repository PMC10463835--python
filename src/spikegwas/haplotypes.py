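"""Gene-region haplotype assignment, trait effects and frequency tables.

Haplotypes here are distinct combinations of SNP genotype categories
(unphased 0/1/2 dosage strings) over a gene region, the natural unit in
a predominantly selfing crop where heterozygosity is rare.  Groups are
ranked by carrier count; those reaching ``min_freq`` of accessions are
the major haplotypes Hap-1, Hap-2, ... and everything else pools into
"minor".  Accessions with missing calls in the region are assigned to a
major haplotype only when they match exactly one of them at every
called site, otherwise they fall into "minor".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .quantgen import lsd_groups


class HaplotypeAssignment:
    """Per-accession haplotype labels over a gene region."""

    def __init__(self, labels: pd.Series, defining: pd.DataFrame,
                 patterns: dict[str, tuple[int, ...]]):
        #: accession -> "Hap-1", "Hap-2", ... or "minor"
        self.labels = labels
        #: SNP table of the region (id, chrom, pos, ref, alt)
        self.defining_snps = defining
        #: haplotype label -> dosage tuple over the region SNPs
        self.patterns = patterns

    @property
    def counts(self) -> pd.Series:
        order = sorted(self.patterns) + ["minor"]
        c = self.labels.value_counts()
        return c.reindex([o for o in order if o in c.index]).astype(int)

    @property
    def coverage(self) -> float:
        """Share of accessions carrying a major haplotype."""
        major = self.labels != "minor"
        return float(major.mean())


def major_coverage_percent(counts: list[int] | np.ndarray, n_total: int) -> float:
    """Combined major-haplotype coverage, as a percentage of accessions."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * float(np.sum(counts)) / n_total, 2)


def assign_haplotypes(gm_region: GenotypeMatrix,
                      min_freq: float = 0.05) -> HaplotypeAssignment:
    """Group accessions by identical dosage strings over the region SNPs.

    Raises if the region has no polymorphic SNP.  Labels Hap-1, Hap-2,
    ... go to groups (of fully called accessions) whose frequency is at
    least ``min_freq``, in descending carrier count (ties broken by
    dosage string for determinism).
    """
    d = gm_region.dosages
    if d.shape[1] == 0:
        raise ValueError("region contains no SNPs")
    poly = np.array([len(set(col[col != MISSING])) > 1 for col in d.T])
    if not poly.any():
        raise ValueError("region contains no polymorphic SNP")
    d = d[:, poly]
    variants = gm_region.variants[poly].reset_index(drop=True)

    complete = ~(d == MISSING).any(axis=1)
    strings = [tuple(int(x) for x in row) for row in d]
    groups: dict[tuple, list[int]] = {}
    for i in np.flatnonzero(complete):
        groups.setdefault(strings[i], []).append(i)

    n = gm_region.n_accessions
    ranked = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    patterns: dict[str, tuple[int, ...]] = {}
    labels = pd.Series("minor", index=gm_region.accession_ids, name="haplotype")
    hap_no = 0
    for pat, members in ranked:
        if len(members) / n >= min_freq:
            hap_no += 1
            name = f"Hap-{hap_no}"
            patterns[name] = pat
            for i in members:
                labels.iloc[i] = name

    # accessions with missing calls: unique match against major patterns
    for i in np.flatnonzero(~complete):
        row = d[i]
        called = row != MISSING
        matches = [name for name, pat in patterns.items()
                   if np.array_equal(row[called], np.asarray(pat)[called])]
        if len(matches) == 1:
            labels.iloc[i] = matches[0]
    return HaplotypeAssignment(labels, variants, patterns)


def haplotype_trait_effects(
    assign: HaplotypeAssignment,
    blues: pd.DataFrame,
    traits: list[str] | None = None,
    reference: str | None = None,
    alpha: float = 0.05,
    min_carriers: int = 3,
) -> pd.DataFrame:
    """Per-haplotype trait means, differences vs a reference and LSD letters.

    For each trait: group BLUE means per major haplotype, the percent
    difference of each haplotype against ``reference`` (default Hap-1)
    computed as (mean_hap - mean_ref) / mean_ref * 100 together with the
    absolute difference, and compact LSD letters.  Haplotypes with fewer
    than ``min_carriers`` accessions are tabulated but excluded from the
    significance test.
    """
    traits = traits if traits is not None else list(blues.columns)
    counts = assign.labels.value_counts()
    majors = [h for h in assign.patterns if counts.get(h, 0) > 0]
    if len([h for h in majors if counts[h] >= min_carriers]) < 2:
        raise ValueError("need >= 2 major haplotypes with enough carriers")
    reference = reference if reference is not None else majors[0]
    if reference not in majors:
        raise ValueError(f"reference haplotype {reference} not among majors")

    rows = []
    for trait in traits:
        vals = blues[trait].reindex(assign.labels.index)
        ok = vals.notna() & assign.labels.isin(majors)
        testable = [h for h in majors
                    if (ok & (assign.labels == h)).sum() >= min_carriers]
        letters = {}
        if len(testable) >= 2:
            mask = ok & assign.labels.isin(testable)
            tab = lsd_groups(vals[mask], assign.labels[mask], alpha=alpha)
            letters = tab["letters"].to_dict()
        ref_mean = vals[ok & (assign.labels == reference)].mean()
        for h in majors:
            sel = ok & (assign.labels == h)
            mean = vals[sel].mean()
            rows.append({
                "trait": trait,
                "haplotype": h,
                "n": int(sel.sum()),
                "mean": mean,
                "pct_vs_ref": (mean - ref_mean) / ref_mean * 100.0
                if ref_mean else np.nan,
                "abs_vs_ref": mean - ref_mean,
                "letters": letters.get(h, ""),
            })
    return pd.DataFrame(rows)


def _decade_bin(year: int) -> str:
    """Release-period bins: everything to 1970, then 10-year bins to 2020."""
    if year <= 1970:
        return "<=1970"
    lo = 1971 + 10 * ((year - 1971) // 10)
    return f"{lo}-{lo + 9}"


def haplotype_frequencies(
    assign: HaplotypeAssignment,
    metadata: pd.DataFrame,
    group_by: str = "region",
) -> pd.DataFrame:
    """Haplotype counts and percentages per geographic region or release
    decade; accessions without metadata count under "unknown".

    Percentages sum to 100 within each group.
    """
    if group_by not in ("region", "decade"):
        raise ValueError("group_by must be 'region' or 'decade'")
    meta = metadata.set_index("accession")
    if group_by == "region":
        grp = meta["region"].reindex(assign.labels.index).fillna("unknown")
    else:
        years = meta["release_year"].reindex(assign.labels.index)
        grp = years.map(lambda v: "unknown" if pd.isna(v) else _decade_bin(int(v)))
    df = pd.DataFrame({"group": grp, "haplotype": assign.labels})
    counts = df.groupby(["group", "haplotype"], observed=True).size().rename("count")
    out = counts.reset_index()
    totals = out.groupby("group")["count"].transform("sum")
    out["percent"] = 100.0 * out["count"] / totals
    return out
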