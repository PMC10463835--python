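"""Kinship, PCA, linkage disequilibrium and Tajima's D on dosage matrices.

All pairwise statistics treat missing calls by pairwise-complete
exclusion: a pair of SNPs (or accessions) is compared only over the
entries where both are called.  r-squared is the squared Pearson
correlation of unphased 0/1/2 dosages, matching the genotypic r2 that
Plink and PopLDdecay report on unphased data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


# ----------------------------------------------------------------- kinship

def kinship_simple_matching(gm: GenotypeMatrix) -> pd.DataFrame:
    """Simple-matching-coefficient kinship matrix.

    K[i, j] is the fraction of loci at which accessions i and j carry
    the identical genotype category (0, 1 or 2), over loci where both
    are called.  Symmetric, unit diagonal, entries in [0, 1].
    """
    if gm.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    d = gm.dosages
    called = (d != MISSING).astype(np.float64)
    matches = np.zeros((gm.n_accessions, gm.n_accessions))
    for cat in (0, 1, 2):
        a = (d == cat).astype(np.float64)
        matches += a @ a.T
    joint = called @ called.T
    if (joint == 0).any():
        bad = np.argwhere(joint == 0)[0]
        raise ValueError(
            f"accession pair {gm.accession_ids[bad[0]]}/{gm.accession_ids[bad[1]]} "
            "shares no jointly called locus"
        )
    K = matches / joint
    np.fill_diagonal(K, 1.0)
    return pd.DataFrame(K, index=gm.accession_ids, columns=gm.accession_ids)


def bend_psd(K: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Floor the eigenvalues of a symmetric matrix at ``floor``.

    Simple-matching kinship can be slightly indefinite after pairwise
    missing-data exclusion; mixed-model fitting needs K to be PSD.
    """
    K = np.asarray(K, dtype=float)
    K = (K + K.T) / 2.0
    w, V = np.linalg.eigh(K)
    if w.min() >= floor:
        return K
    w = np.maximum(w, floor)
    return (V * w) @ V.T


# --------------------------------------------------------------------- PCA

def _standardized_dosages(gm: GenotypeMatrix) -> np.ndarray:
    """Mean-impute missing calls, center by 2p and scale by sqrt(2p(1-p))."""
    d = gm.dosages.astype(float)
    called = d != MISSING
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        raise ValueError("SNP with all calls missing; filter first")
    p = np.where(called, d, 0.0).sum(axis=0) / (2.0 * n_called)
    d = np.where(called, d, 2.0 * p)
    denom = np.sqrt(np.maximum(2.0 * p * (1.0 - p), 1e-12))
    return (d - 2.0 * p) / denom


def pca_genotypes(
    gm: GenotypeMatrix,
    n_components: int = 3,
    prune_r2: float | None = 0.2,
    window_bp: int = 50_000,
    step: int = 5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the accession x SNP matrix after LD pruning.

    SNPs are LD-pruned first (``prune_r2=None`` disables), then
    standardized; PCs come from the SVD of the standardized matrix.
    Returns (scores DataFrame indexed by accession with columns
    PC1..PCk, variance fractions for those PCs).
    """
    if gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    if prune_r2 is not None:
        from .gwas import ld_prune_count

        kept_ids, _ = ld_prune_count(gm, window_bp=window_bp, step=step,
                                     r2_max=prune_r2)
        keep = gm.variants["id"].isin(kept_ids).to_numpy()
        gm = gm.take_snps(np.flatnonzero(keep))
    Z = _standardized_dosages(gm)
    Z = Z - Z.mean(axis=0)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    total = float((s ** 2).sum())
    rank = int((s > 1e-9 * s[0]).sum()) if len(s) else 0
    k = min(n_components, rank)
    if k < n_components:
        import warnings

        warnings.warn(f"requested {n_components} PCs but rank is {rank}; truncating")
    scores = U[:, :k] * s[:k]
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=gm.accession_ids, columns=cols), frac


# ---------------------------------------------------------------------- LD

def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared correlation between all dosage columns.

    ``d`` is accessions x SNPs with -1 for missing.  Monomorphic pairs
    yield NaN.
    """
    W = (d != MISSING).astype(np.float64)
    X = np.where(d == MISSING, 0.0, d).astype(np.float64)
    n = W.T @ W
    sx = X.T @ W
    sxy = X.T @ X
    sxx = (X * X).T @ W
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx ** 2 / n
        r2 = cov ** 2 / (varx * varx.T)
    r2[~np.isfinite(r2)] = np.nan
    return r2


def ld_r2(gm: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two SNPs' dosages over jointly
    called accessions.  Raises if either SNP is monomorphic there."""
    xa = gm.dosages[:, gm.snp_index(snp_a)].astype(float)
    xb = gm.dosages[:, gm.snp_index(snp_b)].astype(float)
    joint = (xa != MISSING) & (xb != MISSING)
    xa, xb = xa[joint], xb[joint]
    if len(xa) < 2 or np.var(xa) == 0 or np.var(xb) == 0:
        raise ValueError(f"monomorphic SNP among jointly called accessions: "
                         f"{snp_a}/{snp_b}")
    r = np.corrcoef(xa, xb)[0, 1]
    return float(r * r)


def ld_matrix(gm: GenotypeMatrix, snp_ids: list[str] | None = None) -> pd.DataFrame:
    """Full pairwise r2 matrix (pairwise-complete) for the given SNPs."""
    if snp_ids is None:
        sub = gm
    else:
        idx = [gm.snp_index(s) for s in snp_ids]
        sub = gm.take_snps(np.asarray(idx))
    r2 = _pairwise_r2(sub.dosages)
    ids = list(sub.variants["id"])
    return pd.DataFrame(r2, index=ids, columns=ids)


def ld_decay(
    gm: GenotypeMatrix,
    max_dist_bp: int = 10_000_000,
    bin_width_bp: int = 100_000,
) -> dict:
    """Distance-binned mean r2 and two decay-distance summaries.

    All intra-chromosomal SNP pairs within ``max_dist_bp`` are binned by
    physical distance.  The half-max distance is the midpoint of the
    first bin whose mean r2 drops to at most half the maximum bin mean
    (no interpolation); the r2 = 0.50 distance is found by linear
    interpolation between bin midpoints.  Returns a dict with the decay
    ``curve`` DataFrame and scalar summaries.
    """
    v = gm.variants
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    any_pair = False
    for chrom in pd.unique(v["chrom"]):
        idx = np.flatnonzero((v["chrom"] == chrom).to_numpy())
        if len(idx) < 2:
            continue
        any_pair = True
        sub = gm.take_snps(idx)
        pos = sub.variants["pos"].to_numpy()
        r2 = _pairwise_r2(sub.dosages)
        iu, ju = np.triu_indices(len(idx), k=1)
        dist = np.abs(pos[ju] - pos[iu])
        vals = r2[iu, ju]
        ok = (dist <= max_dist_bp) & np.isfinite(vals)
        b = np.minimum(dist[ok] // bin_width_bp, n_bins - 1).astype(int)
        np.add.at(sums, b, vals[ok])
        np.add.at(counts, b, 1)
    if not any_pair:
        raise ValueError("no chromosome has >= 2 SNPs")

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    starts = np.arange(n_bins) * bin_width_bp
    curve = pd.DataFrame({
        "bin_start": starts,
        "bin_end": starts + bin_width_bp,
        "mid": starts + bin_width_bp / 2.0,
        "mean_r2": mean_r2,
        "n_pairs": counts,
    })
    occupied = curve[curve["n_pairs"] > 0]
    max_r2 = float(occupied["mean_r2"].max())
    half = max_r2 / 2.0
    below = occupied[occupied["mean_r2"] <= half]
    if len(below):
        half_max_dist = float(below["mid"].iloc[0])
    else:
        # flat curve (no decaying LD): decay is complete within the first bin
        half_max_dist = float(occupied["mid"].iloc[0])

    # distance where the curve first crosses r2 = 0.50 (interpolated)
    r50 = np.nan
    occ = occupied.reset_index(drop=True)
    for i in range(1, len(occ)):
        y0, y1 = occ["mean_r2"].iloc[i - 1], occ["mean_r2"].iloc[i]
        if y0 >= 0.5 >= y1 and y0 != y1:
            x0, x1 = occ["mid"].iloc[i - 1], occ["mid"].iloc[i]
            r50 = float(x0 + (y0 - 0.5) * (x1 - x0) / (y0 - y1))
            break
    return {
        "curve": curve,
        "max_r2": max_r2,
        "half_max_distance_bp": half_max_dist,
        "r2_050_distance_bp": r50,
    }


# -------------------------------------------------------------- Tajima's D

def tajimas_d(gm: GenotypeMatrix) -> float:
    """Tajima's D over the SNPs of ``gm`` (typically a gene region).

    Allele counts are taken from diploid genotypes so the sample size is
    n = 2 x accessions chromosomes (the convention VCFtools applies to
    unphased GT calls); per-site pairwise diversity uses each site's own
    called-chromosome count.  Requires >= 4 accessions and at least one
    segregating site.
    """
    if gm.n_accessions < 4:
        raise ValueError("need >= 4 accessions")
    d = gm.dosages
    called = d != MISSING
    n_chrom_site = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    seg = (alt > 0) & (alt < n_chrom_site)
    S = int(seg.sum())
    if S == 0:
        raise ValueError("no segregating sites in region")

    c = alt[seg].astype(float)
    m = n_chrom_site[seg].astype(float)
    # mean pairwise difference per site: 2 c (m - c) / (m (m - 1))
    pi = float(np.sum(2.0 * c * (m - c) / (m * (m - 1.0))))

    n = 2 * gm.n_accessions
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 ** 2)
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        raise ValueError("degenerate variance in Tajima's D")
    return float((pi - S / a1) / np.sqrt(var))
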