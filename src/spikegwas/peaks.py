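"""From significant SNPs to genomic intervals, peaks and candidate genes.

Significant SNPs of one trait are delineated into intervals as the
connected components of the graph whose edges join SNPs on the same
chromosome with r2 > 0.1.  Adjacent intervals whose lead (most
significant) SNPs lie less than 5 Mb apart are merged, and merged
intervals holding more than 10 significant SNPs are flagged as peaks.
Candidate genes are collected within 500 kb either side of a peak's
lead SNP and screened for expression during spike development
(FPKM across stages ZM1-ZM6).  All defaults follow the interval rules
stated with the association analysis this package reimplements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotype_io import GenotypeMatrix
from .popgen import _pairwise_r2


@dataclass
class Peak:
    """A genomic interval of associated SNPs (1-based inclusive bounds)."""

    chrom: str
    start: int
    end: int
    snp_ids: list[str]
    lead_snp: str
    lead_pos: int
    best_neglog10p: float
    traits: list[str] = field(default_factory=list)
    is_peak: bool = False

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def _lead(members: pd.DataFrame) -> pd.Series:
    """Most significant member; ties broken by smaller position."""
    best = members.sort_values(["neglog10p", "pos"],
                               ascending=[False, True]).iloc[0]
    return best


def delineate_intervals(
    sig_snps: pd.DataFrame, gm: GenotypeMatrix, r2_min: float = 0.1
) -> list[Peak]:
    """Group significant SNPs into LD intervals per chromosome.

    ``sig_snps`` is an association-result subset (columns ``snp, chrom,
    pos, neglog10p`` at least).  Edges join SNP pairs with r2 strictly
    greater than ``r2_min``; intervals are the connected components,
    bounded by their members' min/max positions.
    """
    if sig_snps.empty:
        return []
    intervals: list[Peak] = []
    for chrom, grp in sig_snps.groupby("chrom", sort=True):
        grp = grp.sort_values("pos").reset_index(drop=True)
        idx = np.asarray([gm.snp_index(s) for s in grp["snp"]])
        r2 = _pairwise_r2(gm.dosages[:, idx])
        adj = np.nan_to_num(r2, nan=0.0) > r2_min
        np.fill_diagonal(adj, True)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        for comp in range(n_comp):
            members = grp[labels == comp]
            lead = _lead(members)
            intervals.append(Peak(
                chrom=str(chrom),
                start=int(members["pos"].min()),
                end=int(members["pos"].max()),
                snp_ids=list(members["snp"]),
                lead_snp=str(lead["snp"]),
                lead_pos=int(lead["pos"]),
                best_neglog10p=float(lead["neglog10p"]),
                traits=sorted(set(members["trait"])) if "trait" in members else [],
            ))
    intervals.sort(key=lambda p: (p.chrom, p.lead_pos))
    return intervals


def merge_and_call_peaks(
    intervals: list[Peak],
    sig_snps: pd.DataFrame | None = None,
    max_lead_gap_bp: int = 5_000_000,
    min_snps: int = 10,
) -> list[Peak]:
    """Merge adjacent intervals with lead SNPs < ``max_lead_gap_bp`` apart
    (strict), re-deriving the lead after each merge until stable, then
    flag intervals with more than ``min_snps`` members (strict) as peaks.

    ``sig_snps`` supplies per-SNP positions/scores for lead re-derivation;
    if omitted it is reconstructed from the intervals themselves.
    """
    if sig_snps is None:
        rows = []
        for iv in intervals:
            for s in iv.snp_ids:
                rows.append({"snp": s, "chrom": iv.chrom, "pos": iv.lead_pos,
                             "neglog10p": iv.best_neglog10p})
        sig_snps = pd.DataFrame(rows)
    snp_info = sig_snps.drop_duplicates("snp").set_index("snp")

    merged: list[Peak] = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        chrom_ivs = sorted((iv for iv in intervals if iv.chrom == chrom),
                           key=lambda p: p.lead_pos)
        changed = True
        while changed:
            changed = False
            out: list[Peak] = []
            for iv in chrom_ivs:
                if out and abs(iv.lead_pos - out[-1].lead_pos) < max_lead_gap_bp:
                    prev = out.pop()
                    ids = prev.snp_ids + [s for s in iv.snp_ids
                                          if s not in set(prev.snp_ids)]
                    members = snp_info.loc[ids].reset_index()
                    lead = _lead(members)
                    out.append(Peak(
                        chrom=chrom,
                        start=min(prev.start, iv.start),
                        end=max(prev.end, iv.end),
                        snp_ids=ids,
                        lead_snp=str(lead["snp"]),
                        lead_pos=int(lead["pos"]),
                        best_neglog10p=float(lead["neglog10p"]),
                        traits=sorted(set(prev.traits) | set(iv.traits)),
                    ))
                    changed = True
                else:
                    out.append(iv)
            chrom_ivs = sorted(out, key=lambda p: p.lead_pos)
        merged.extend(chrom_ivs)

    for iv in merged:
        iv.is_peak = iv.n_snps > min_snps
    merged.sort(key=lambda p: (p.chrom, p.start))
    return merged


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": p.chrom, "start": p.start, "end": p.end,
        "n_snps": p.n_snps, "lead_snp": p.lead_snp, "lead_pos": p.lead_pos,
        "best_neglog10p": p.best_neglog10p, "is_peak": p.is_peak,
        "traits": ",".join(p.traits),
    } for p in peaks])


def cross_trait_summary(peaks_by_trait: dict[str, list[Peak]],
                        ratio_traits: set[str] | None = None) -> pd.DataFrame:
    """Collapse overlapping per-trait peaks into unified regions.

    Any base-pair overlap between peaks (of any traits) on the same
    chromosome joins them into one region.  Each region reports its
    supporting traits, the best -log10 p per trait, and — when
    ``ratio_traits`` is given — whether it is exclusive to the derived
    ratio traits (the assimilate-partitioning signal absent from every
    measured component trait).
    """
    rows = []
    for trait, plist in peaks_by_trait.items():
        for p in plist:
            rows.append({"trait": trait, "chrom": p.chrom, "start": p.start,
                         "end": p.end, "best": p.best_neglog10p})
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_traits",
                                     "traits", "ratio_only"])
    df = pd.DataFrame(rows).sort_values(["chrom", "start", "end"])

    regions = []
    for chrom, grp in df.groupby("chrom", sort=True):
        cur_start = cur_end = None
        cur_members: list[pd.Series] = []
        for _, row in grp.iterrows():
            if cur_end is None or row["start"] > cur_end:
                if cur_members:
                    regions.append((chrom, cur_start, cur_end, cur_members))
                cur_start, cur_end, cur_members = row["start"], row["end"], [row]
            else:
                cur_end = max(cur_end, row["end"])
                cur_members.append(row)
        if cur_members:
            regions.append((chrom, cur_start, cur_end, cur_members))

    out = []
    for chrom, start, end, members in regions:
        best_by_trait: dict[str, float] = {}
        for m in members:
            best_by_trait[m["trait"]] = max(best_by_trait.get(m["trait"], 0.0),
                                            m["best"])
        traits = sorted(best_by_trait)
        rec = {
            "chrom": chrom, "start": int(start), "end": int(end),
            "n_traits": len(traits), "traits": ",".join(traits),
            "best_neglog10p": max(best_by_trait.values()),
        }
        if ratio_traits is not None:
            rec["ratio_only"] = all(t in ratio_traits for t in traits)
        out.append(rec)
    return pd.DataFrame(out)


# -------------------------------------------------------- candidate genes

@dataclass
class CandidateGene:
    gene_id: str
    chrom: str
    start: int
    end: int
    distance_bp: int            # 0 if the lead SNP lies inside the gene
    passes_expression: bool
    fpkm: dict = field(default_factory=dict)


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Gene records (gene_id, chrom, start, end, strand) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("ID", [g.id])[0]
        rows.append({"gene_id": gid, "chrom": g.seqid, "start": g.start,
                     "end": g.end, "strand": g.strand})
    return pd.DataFrame(rows)


def candidate_genes(
    peak: Peak,
    annotation: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    window_bp: int = 500_000,
    fpkm_min: float = 1.0,
) -> list[CandidateGene]:
    """Genes within ``window_bp`` either side of the peak's lead SNP.

    A gene qualifies if its span intersects [lead - window, lead +
    window] (inclusive).  Distance is 0 when the lead SNP falls inside
    the gene span, else base pairs to the nearest gene edge.  A gene
    passes the expression screen when its FPKM reaches ``fpkm_min`` in
    any stage ZM1-ZM6.  Ranked by (passes-expression desc, distance asc).
    """
    genes = annotation[annotation["chrom"] == peak.chrom]
    if genes.empty:
        warnings.warn(f"annotation has no genes on {peak.chrom}")
        return []
    lead = peak.lead_pos
    lo, hi = lead - window_bp, lead + window_bp
    hit = genes[(genes["end"] >= lo) & (genes["start"] <= hi)]

    expr_idx = None
    stage_cols: list[str] = []
    if expression is not None:
        expr_idx = expression.set_index("gene_id")
        stage_cols = [c for c in expr_idx.columns if c.startswith("ZM")]

    out: list[CandidateGene] = []
    for g in hit.itertuples(index=False):
        if g.start <= lead <= g.end:
            dist = 0
        else:
            dist = int(min(abs(lead - g.start), abs(lead - g.end)))
        fpkm: dict = {}
        passes = False
        if expr_idx is not None and g.gene_id in expr_idx.index:
            fpkm = {c: float(expr_idx.loc[g.gene_id, c]) for c in stage_cols}
            passes = any(v >= fpkm_min for v in fpkm.values())
        out.append(CandidateGene(g.gene_id, peak.chrom, int(g.start),
                                 int(g.end), dist, passes, fpkm))
    out.sort(key=lambda c: (not c.passes_expression, c.distance_bp, c.gene_id))
    return out


def candidates_to_frame(cands: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": c.gene_id, "chrom": c.chrom, "start": c.start, "end": c.end,
        "distance_bp": c.distance_bp, "passes_expression": c.passes_expression,
        **c.fpkm,
    } for c in cands])
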