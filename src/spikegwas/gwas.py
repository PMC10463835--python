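"""Mixed-linear-model association scan and genome-wide thresholds.

The model is y = X a + S b + u + e with S the fixed covariates
(intercept plus the top principal components), u ~ N(0, sg2 K) a
polygenic effect with simple-matching kinship K, and e ~ N(0, se2 I).
The null model is fitted by single-parameter REML over the variance
ratio lambda = sg2/se2 using the eigendecomposition of K (EMMA); the
scan then either keeps lambda fixed at the null estimate for every SNP
(approx mode, P3D/EMMAX) or re-optimizes it per SNP (exact mode).

Genome-wide significance comes from a Bonferroni correction on an
LD-pruned count of independent markers and from a phenotype-permutation
null of the genome-wide minimum p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import MISSING, GenotypeMatrix
from .popgen import _pairwise_r2, bend_psd


def build_covariates(pcs: pd.DataFrame | np.ndarray, n_pcs: int = 3) -> np.ndarray:
    """Intercept plus the first ``n_pcs`` principal components."""
    P = np.asarray(pcs, dtype=float)[:, :n_pcs]
    return np.column_stack([np.ones(len(P)), P])


@dataclass
class MlmNullFit:
    """REML fit of the covariate-only mixed model."""

    lambda_: float           # sg2 / se2
    loglik: float            # REML log-likelihood at lambda_
    sigma2_e: float
    beta: np.ndarray         # GLS covariate effects
    eigvals: np.ndarray = field(repr=False)
    eigvecs: np.ndarray = field(repr=False)
    yt: np.ndarray = field(repr=False)   # U'y
    Xt: np.ndarray = field(repr=False)   # U'S


def _reml_pieces(lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    w = 1.0 / (lam * d + 1.0)
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    XtWy = XtW.T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yt - Xt @ beta
    rss = float(np.sum(w * resid ** 2))
    return w, XtWX, beta, rss


def _neg_reml_loglik(log_lam: float, d: np.ndarray, yt: np.ndarray,
                     Xt: np.ndarray) -> float:
    n, p = Xt.shape
    lam = float(np.exp(log_lam))
    w, XtWX, _, rss = _reml_pieces(lam, d, yt, Xt)
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * sigma2)
        - np.sum(np.log(w))
        + logdet_XtWX
        + (n - p)
    )
    return -ll


def fit_null_mlm(y: np.ndarray, S: np.ndarray, K: np.ndarray) -> MlmNullFit:
    """REML fit of lambda = sg2/se2 by Brent search on log lambda in
    [-10, 10] over the eigendecomposition of (PSD-bent) K."""
    y = np.asarray(y, dtype=float).ravel()
    S = np.asarray(S, dtype=float)
    K = np.asarray(K, dtype=float)
    n = len(y)
    if S.shape[0] != n or K.shape != (n, n):
        raise ValueError("shape mismatch between y, S and K")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValueError("covariate matrix S is rank deficient")

    Kb = bend_psd(K)
    d, U = np.linalg.eigh(Kb)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Xt = U.T @ S

    res = optimize.minimize_scalar(
        _neg_reml_loglik, bounds=(-10.0, 10.0), method="bounded",
        args=(d, yt, Xt), options={"xatol": 1e-7},
    )
    candidates = [(-10.0, _neg_reml_loglik(-10.0, d, yt, Xt)),
                  (float(res.x), float(res.fun))]
    log_lam, nll = min(candidates, key=lambda t: t[1])
    lam = float(np.exp(log_lam))
    _, _, beta, rss = _reml_pieces(lam, d, yt, Xt)
    sigma2 = rss / (n - S.shape[1])
    return MlmNullFit(lam, -nll, sigma2, beta, d, U, yt, Xt)


def _prepare_dosages(gm: GenotypeMatrix, rows: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed float dosage matrix and a polymorphic-SNP mask."""
    d = gm.dosages if rows is None else gm.dosages[rows, :]
    d = d.astype(float)
    called = d != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mu = np.where(n_called > 0, np.where(called, d, 0.0).sum(axis=0)
                      / np.maximum(n_called, 1), 0.0)
    X = np.where(called, d, mu[None, :])
    poly = X.std(axis=0) > 0
    return X, poly


def _approx_stats(yr: np.ndarray, Xr: np.ndarray, df: int
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP GLS slope, SE, t and p from residualized transformed data."""
    xx = np.einsum("ij,ij->j", Xr, Xr)
    xy = Xr.T @ yr
    yy = float(yr @ yr)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = xy / xx
        rss = yy - beta * xy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / xx)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return beta, se, tstat, p


def loco_kinship(gm: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Per-chromosome leave-one-chromosome-out simple-matching kinships."""
    from .popgen import kinship_simple_matching

    chroms = gm.variants["chrom"].to_numpy()
    uniq = pd.unique(chroms)
    if len(uniq) < 2:
        raise ValueError("LOCO needs >= 2 chromosomes")
    out = {}
    for chrom in uniq:
        rest = np.flatnonzero(chroms != chrom)
        out[chrom] = kinship_simple_matching(gm.take_snps(rest)).to_numpy()
    return out


class _ChromEngine:
    """Transformed-and-residualized scan state for one kinship/SNP subset."""

    def __init__(self, Xall: np.ndarray, poly: np.ndarray, cols: np.ndarray,
                 S: np.ndarray, K: np.ndarray, y: np.ndarray):
        self.cols = cols
        self.null = fit_null_mlm(y, S, K)
        d, U, lam = self.null.eigvals, self.null.eigvecs, self.null.lambda_
        self._w_sqrt = 1.0 / np.sqrt(lam * d + 1.0)
        self._U = U
        self.poly = poly[cols]
        Xs = (U.T @ Xall[:, cols]) * self._w_sqrt[:, None]
        Ss = (U.T @ S) * self._w_sqrt[:, None]
        self._Ss = Ss
        self._SsInv = np.linalg.inv(Ss.T @ Ss)
        self._Xr = Xs - Ss @ (self._SsInv @ (Ss.T @ Xs))
        self._df = len(y) - S.shape[1] - 1

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        ys = (self._U.T @ np.asarray(y, dtype=float)) * self._w_sqrt
        return ys - self._Ss @ (self._SsInv @ (self._Ss.T @ ys))

    def scan(self, y: np.ndarray) -> tuple[np.ndarray, ...]:
        yr = self.transform_y(y)
        beta, se, tstat, p = _approx_stats(yr, self._Xr, self._df)
        beta = np.where(self.poly, beta, np.nan)
        p = np.where(self.poly, p, np.nan)
        return beta, se, tstat, p


class ScanEngine:
    """Reusable approx-mode (P3D) scan state for one (gm, S, K, y).

    With ``loco=True`` each chromosome is tested against a kinship
    matrix built from the other chromosomes (leave-one-chromosome-out),
    which keeps the tested SNP's own LD block out of the polygenic
    covariance; with ``loco=False`` the supplied all-SNP K is used for
    every SNP.  Cheap to rerun for permuted phenotypes.
    """

    def __init__(self, gm: GenotypeMatrix, S: np.ndarray,
                 K: np.ndarray | dict | None, y: np.ndarray,
                 loco: bool = False):
        from .popgen import kinship_simple_matching

        self.gm = gm
        S = np.asarray(S, dtype=float)
        Xall, poly = _prepare_dosages(gm)
        self._engines: list[_ChromEngine] = []
        if loco:
            kin = K if isinstance(K, dict) else loco_kinship(gm)
            chroms = gm.variants["chrom"].to_numpy()
            for chrom in pd.unique(chroms):
                cols = np.flatnonzero(chroms == chrom)
                self._engines.append(
                    _ChromEngine(Xall, poly, cols, S, kin[chrom], y))
        else:
            if K is None:
                K = kinship_simple_matching(gm).to_numpy()
            cols = np.arange(gm.n_snps)
            self._engines.append(
                _ChromEngine(Xall, poly, cols, S, np.asarray(K, float), y))

    @property
    def lambdas(self) -> list[float]:
        return [e.null.lambda_ for e in self._engines]

    @property
    def null(self) -> MlmNullFit:
        return self._engines[0].null

    def scan(self, y: np.ndarray) -> tuple[np.ndarray, ...]:
        m = self.gm.n_snps
        out = [np.full(m, np.nan) for _ in range(4)]
        for e in self._engines:
            for arr, vals in zip(out, e.scan(y)):
                arr[e.cols] = vals
        return tuple(out)

    def min_p(self, y: np.ndarray) -> float:
        return float(np.nanmin(self.scan(y)[3]))


def association_scan(
    gm: GenotypeMatrix,
    y: np.ndarray,
    S: np.ndarray,
    K: np.ndarray | None = None,
    mode: str = "approx",
    trait: str = "trait",
    loco: bool = False,
) -> pd.DataFrame:
    """Per-SNP mixed-model association tests.

    approx mode fixes lambda at the null REML estimate for every SNP;
    exact mode re-optimizes lambda per SNP with the SNP in the fixed
    effects.  ``loco=True`` rebuilds the kinship without the tested
    SNP's chromosome (approx mode only).  Missing dosages are
    mean-imputed inside the test only.  Monomorphic SNPs get NaN
    statistics and are counted in ``result.attrs["n_skipped"]``.
    """
    if mode not in ("approx", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact" and loco:
        raise ValueError("exact mode does not support loco")
    y = np.asarray(y, dtype=float).ravel()
    engine = ScanEngine(gm, S, K, y, loco=loco)
    if mode == "approx":
        beta, se, tstat, p = engine.scan(y)
    else:
        Xall, poly = _prepare_dosages(gm)
        n, pcov = len(y), np.asarray(S).shape[1]
        df = n - pcov - 1
        d, U = engine.null.eigvals, engine.null.eigvecs
        yt = U.T @ y
        St = U.T @ np.asarray(S, dtype=float)
        beta = np.full(gm.n_snps, np.nan)
        se = np.full(gm.n_snps, np.nan)
        tstat = np.full(gm.n_snps, np.nan)
        p = np.full(gm.n_snps, np.nan)
        for j in range(gm.n_snps):
            if not poly[j]:
                continue
            Xt = np.column_stack([St, U.T @ Xall[:, j]])
            res = optimize.minimize_scalar(
                _neg_reml_loglik, bounds=(-10.0, 10.0), method="bounded",
                args=(d, yt, Xt), options={"xatol": 1e-6},
            )
            lam = float(np.exp(res.x))
            w, XtWX, bfull, rss = _reml_pieces(lam, d, yt, Xt)
            sigma2 = rss / df
            cov = sigma2 * np.linalg.inv(XtWX)
            beta[j] = bfull[-1]
            se[j] = np.sqrt(cov[-1, -1])
            tstat[j] = beta[j] / se[j]
            p[j] = 2.0 * stats.t.sf(abs(tstat[j]), df)

    out = gm.variants[["id", "chrom", "pos"]].copy()
    out = out.rename(columns={"id": "snp"})
    out["beta"] = beta
    out["se"] = se
    out["wald"] = tstat
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["neglog10p"] = -np.log10(out["p"])
    out["trait"] = trait
    out.attrs["n_skipped"] = int(np.isnan(p).sum())
    out.attrs["lambda"] = float(np.mean(engine.lambdas))
    return out


# ----------------------------------------------------------------- pruning

def ld_prune_count(
    gm: GenotypeMatrix,
    window_bp: int = 50_000,
    step: int = 5,
    r2_max: float = 0.2,
) -> tuple[list[str], int]:
    """Sliding-window greedy LD prune; returns (surviving ids, count).

    Within each window (SNPs spanning ``window_bp`` from the window's
    first kept SNP) the later-positioned SNP of any pair with
    r2 > ``r2_max`` is dropped; windows advance by ``step`` SNPs and
    passes repeat until no further SNP is removed.
    """
    kept_ids: list[str] = []
    v = gm.variants
    for chrom in pd.unique(v["chrom"]):
        idx = np.flatnonzero((v["chrom"] == chrom).to_numpy())
        sub = gm.take_snps(idx)
        pos = sub.variants["pos"].to_numpy()
        m = len(idx)
        keep = np.ones(m, dtype=bool)

        def sweep(anchors: np.ndarray) -> bool:
            dropped = False
            for s in anchors:
                if not keep[s]:
                    continue
                in_win = np.flatnonzero(
                    keep & (np.arange(m) >= s) & (pos < pos[s] + window_bp)
                )
                if len(in_win) > 1:
                    r2 = _pairwise_r2(sub.dosages[:, in_win])
                    for a in range(len(in_win)):
                        if not keep[in_win[a]]:
                            continue
                        for b in range(a + 1, len(in_win)):
                            if keep[in_win[b]] and r2[a, b] > r2_max:
                                keep[in_win[b]] = False
                                dropped = True
            return dropped

        # stepped passes (plink-style), then full-anchor passes so that no
        # surviving pair within window_bp exceeds r2_max
        for _ in range(50):
            if not sweep(np.arange(0, m, step)):
                break
        for _ in range(50):
            if not sweep(np.arange(m)):
                break
        kept_ids.extend(sub.variants["id"].iloc[np.flatnonzero(keep)])
    return kept_ids, len(kept_ids)


# -------------------------------------------------------------- thresholds

def bonferroni_threshold(n_independent: int, alpha: float = 0.05) -> dict:
    """p = alpha / n plus its -log10 (display-rounded to 2 decimals)."""
    if n_independent < 1:
        raise ValueError("n_independent must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = alpha / n_independent
    return {
        "p": p,
        "neglog10p": -np.log10(p),
        "neglog10p_display": round(-np.log10(p), 2),
        "n_independent": int(n_independent),
        "alpha": alpha,
    }


def permutation_threshold(
    gm: GenotypeMatrix,
    y: np.ndarray,
    S: np.ndarray,
    K: np.ndarray | None = None,
    n_perm: int = 100,
    quantile: float = 0.05,
    seed: int = 0,
    engine: ScanEngine | None = None,
    loco: bool = False,
) -> dict:
    """Permutation-based genome-wide p-value threshold.

    The phenotype is shuffled across accessions ``n_perm`` times (S and
    K stay fixed, preserving the structure correction); each permuted
    scan's genome-wide minimum p is recorded and the threshold is the
    empirical ``quantile`` of those minima.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives an unstable quantile")
    y = np.asarray(y, dtype=float).ravel()
    engine = engine if engine is not None else ScanEngine(gm, S, K, y, loco=loco)
    rng = np.random.default_rng(seed)
    minima = np.empty(n_perm)
    for b in range(n_perm):
        minima[b] = engine.min_p(rng.permutation(y))
    thr = float(np.quantile(minima, quantile))
    return {
        "p": thr,
        "neglog10p": float(-np.log10(thr)),
        "n_perm": n_perm,
        "quantile": quantile,
        "minima": minima,
    }


def genomic_control_lambda(p_values: np.ndarray) -> float:
    """Median-based genomic inflation factor of a vector of p-values."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
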