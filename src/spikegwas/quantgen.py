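"""Trait dissection, variance components, heritability, BLUEs and LSD.

The phenotype panel consists of 12 measured spike-component traits
(lengths, weights and counts per spike and per central spikelet) and 15
assimilate-partitioning traits derived from them as ratios, e.g.
thousand-kernel weight (grain weight / grain number x 1000) and spikelet
density (spikelet number / spike length).  Ratios are always computed at
the replicate level, before any averaging, because averaging and ratio
formation do not commute.

Phenotype observations travel as long-format DataFrames with columns
``accession, trait, year, rep, value``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

PHENO_COLUMNS = ["accession", "trait", "year", "rep", "value"]

#: The 12 measured spike morphology traits (per spike unless noted).
MEASURED_TRAITS: list[str] = [
    "spike_length",            # cm, awns excluded
    "spike_weight",            # g, spike dry weight
    "grain_weight",            # g per spike
    "awn_weight",              # g per spike
    "chaff_weight",            # g per spike (glume + lemma + palea + awn)
    "rachis_weight",           # g per spike
    "grain_number",            # count per spike
    "spikelet_number",         # count per spike
    "spikelet_weight",         # g, central spikelet
    "grain_number_spikelet",   # count, central spikelet
    "chaff_weight_spikelet",   # g, central spikelet
    "grain_weight_spikelet",   # g, central spikelet
]

COUNT_TRAITS: set[str] = {"grain_number", "spikelet_number", "grain_number_spikelet"}


@dataclass(frozen=True)
class TraitDefinition:
    """A measured trait or a ratio of two measured traits."""

    name: str
    kind: str = "measured"  # "measured" | "ratio"
    numerator: str | None = None
    denominator: str | None = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("measured", "ratio"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "ratio":
            if self.numerator is None or self.denominator is None:
                raise ValueError("ratio trait needs numerator and denominator")
            if self.numerator == self.denominator:
                raise ValueError("numerator and denominator must differ")


def _ratio(name: str, num: str, den: str, scale: float = 1.0) -> TraitDefinition:
    return TraitDefinition(name, "ratio", num, den, scale)


#: The 15 derived assimilate-partitioning traits: ten on the entire
#: spike and five on the central spikelet.
RATIO_TRAITS: list[TraitDefinition] = [
    _ratio("thousand_kernel_weight", "grain_weight", "grain_number", 1000.0),
    _ratio("grain_number_per_chaff_weight", "grain_number", "chaff_weight"),
    _ratio("grain_weight_per_chaff_weight", "grain_weight", "chaff_weight"),
    _ratio("grain_weight_per_spike_weight", "grain_weight", "spike_weight"),
    _ratio("grain_weight_per_rachis_weight", "grain_weight", "rachis_weight"),
    _ratio("spikelet_density", "spikelet_number", "spike_length"),
    _ratio("chaff_weight_per_spike_weight", "chaff_weight", "spike_weight"),
    _ratio("awn_weight_per_spike_weight", "awn_weight", "spike_weight"),
    _ratio("awn_weight_per_grain_weight", "awn_weight", "grain_weight"),
    _ratio("awn_weight_per_chaff_weight", "awn_weight", "chaff_weight"),
    _ratio("grain_weight_per_chaff_weight_spikelet",
           "grain_weight_spikelet", "chaff_weight_spikelet"),
    _ratio("thousand_kernel_weight_spikelet",
           "grain_weight_spikelet", "grain_number_spikelet", 1000.0),
    _ratio("grain_number_per_chaff_weight_spikelet",
           "grain_number_spikelet", "chaff_weight_spikelet"),
    _ratio("grain_weight_per_spikelet_weight",
           "grain_weight_spikelet", "spikelet_weight"),
    _ratio("chaff_weight_per_spikelet_weight",
           "chaff_weight_spikelet", "spikelet_weight"),
]

ALL_TRAIT_DEFINITIONS: list[TraitDefinition] = [
    TraitDefinition(t) for t in MEASURED_TRAITS
] + RATIO_TRAITS

RATIO_TRAIT_NAMES: list[str] = [d.name for d in RATIO_TRAITS]


def derive_traits(
    obs: pd.DataFrame, defs: list[TraitDefinition] | None = None
) -> pd.DataFrame:
    """Add derived ratio traits to a long-format phenotype table.

    Every ratio is computed per (accession, year, rep) record before any
    averaging.  Records whose denominator is missing, zero or negative
    are dropped (and counted in the returned frame's ``attrs``), never
    imputed.
    """
    defs = RATIO_TRAITS if defs is None else [d for d in defs if d.kind == "ratio"]
    missing_cols = set(PHENO_COLUMNS) - set(obs.columns)
    if missing_cols:
        raise ValueError(f"phenotype table lacks columns {sorted(missing_cols)}")

    wide = obs.pivot_table(
        index=["accession", "year", "rep"], columns="trait", values="value",
        aggfunc="first",
    )
    derived = {}
    n_dropped = 0
    for d in defs:
        if d.numerator not in wide.columns or d.denominator not in wide.columns:
            raise ValueError(f"ratio {d.name} references unmeasured traits")
        num = wide[d.numerator]
        den = wide[d.denominator]
        valid = num.notna() & den.notna() & (den > 0)
        n_dropped += int((num.notna() & den.notna() & (den <= 0)).sum())
        derived[d.name] = (num / den * d.scale).where(valid)
    ratio_long = (
        pd.DataFrame(derived, index=wide.index)
        .stack()
        .rename("value")
        .reset_index()
        .rename(columns={"level_3": "trait"})
    )[PHENO_COLUMNS]
    out = pd.concat([obs[PHENO_COLUMNS], ratio_long], ignore_index=True)
    out.attrs["n_dropped_ratio_records"] = n_dropped
    return out


@dataclass
class VarianceComponents:
    """Method-of-moments variance components from a two-way ANOVA."""

    var_G: float
    var_GxE: float
    var_e: float
    mean_squares: dict = field(default_factory=dict)
    df: dict = field(default_factory=dict)
    f_stats: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    clamped: bool = False
    n_years: int = 0
    n_reps: float = 0.0


def anova_components(obs: pd.DataFrame) -> VarianceComponents:
    """Two-way genotype x year ANOVA with replicates, solved for variance
    components by expected mean squares.

    For a (near-)balanced design with g genotypes, y years and r reps:
    ``var_e = MS_error``, ``var_GxE = (MS_GxY - MS_error)/r`` and
    ``var_G = (MS_G - MS_GxY)/(r*y)``; negative estimates are clamped to
    zero and flagged.  F tests use MS_GxY as the denominator for the
    genotype and year strata (year and interaction random).
    """
    df_ = obs.dropna(subset=["value"])
    g = df_["accession"].nunique()
    y = df_["year"].nunique()
    if g < 2 or y < 2:
        raise ValueError("need >= 2 genotypes and >= 2 years")
    cell = df_.groupby(["accession", "year"], observed=True)["value"]
    cell_n = cell.size()
    if (cell_n < 2).all():
        raise ValueError("need >= 2 replicates to separate error from interaction")
    r = float(cell_n.mean())

    grand = df_["value"].mean()
    cell_mean = cell.mean()
    geno_mean = df_.groupby("accession", observed=True)["value"].mean()
    year_mean = df_.groupby("year", observed=True)["value"].mean()

    n = len(df_)
    ss_total = float(((df_["value"] - grand) ** 2).sum())
    ss_g = float(r * y * ((geno_mean - grand) ** 2).sum())
    ss_y = float(r * g * ((year_mean - grand) ** 2).sum())
    inter = (
        cell_mean
        - geno_mean.reindex(cell_mean.index.get_level_values(0)).to_numpy()
        - year_mean.reindex(cell_mean.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_gy = float(r * (inter ** 2).sum())
    merged = df_.merge(
        cell_mean.rename("cell_mean"), left_on=["accession", "year"], right_index=True
    )
    ss_e = float(((merged["value"] - merged["cell_mean"]) ** 2).sum())

    dfd = {
        "genotype": g - 1,
        "year": y - 1,
        "gxy": (g - 1) * (y - 1),
        "error": max(n - g * y, 1),
    }
    ms = {
        "genotype": ss_g / dfd["genotype"],
        "year": ss_y / dfd["year"],
        "gxy": ss_gy / dfd["gxy"],
        "error": ss_e / dfd["error"],
        "ss_total": ss_total,
    }
    var_e = ms["error"]
    var_gxe = (ms["gxy"] - ms["error"]) / r
    var_g = (ms["genotype"] - ms["gxy"]) / (r * y)
    clamped = var_gxe < 0 or var_g < 0

    def _f(num: str, den: str) -> tuple[float, float]:
        if ms[den] <= 0:
            return np.nan, np.nan
        f = ms[num] / ms[den]
        return f, float(stats.f.sf(f, dfd[num], dfd[den]))

    f_stats, p_values = {}, {}
    for stratum, den in (("genotype", "gxy"), ("year", "gxy"), ("gxy", "error")):
        f_stats[stratum], p_values[stratum] = _f(stratum, den)

    return VarianceComponents(
        var_G=max(var_g, 0.0),
        var_GxE=max(var_gxe, 0.0),
        var_e=max(var_e, 0.0),
        mean_squares=ms,
        df=dfd,
        f_stats=f_stats,
        p_values=p_values,
        clamped=bool(clamped),
        n_years=y,
        n_reps=r,
    )


def heritability(vc: VarianceComponents, n_years: int | None = None,
                 n_reps: float | None = None) -> float:
    """Broad-sense heritability on an entry-mean basis.

    H2 = var_G / (var_G + var_GxE / y + var_e / (y * r)) with y years
    and r replicates per year; the two-year, five-replicate case reduces
    to var_G / (var_G + var_GxE/2 + var_e/10).
    """
    y = n_years if n_years is not None else vc.n_years
    r = n_reps if n_reps is not None else vc.n_reps
    if y < 1 or r < 1:
        raise ValueError("need at least one year and one replicate")
    denom = vc.var_G + vc.var_GxE / y + vc.var_e / (y * r)
    if denom <= 0:
        raise ValueError("all variance components are zero; H2 undefined")
    return vc.var_G / denom


def _reml_blues_unbalanced(df_: pd.DataFrame) -> pd.Series:
    """REML mixed model: genotype fixed, year and genotype x year random.

    Direct covariance-matrix REML, intended for modestly sized
    unbalanced designs; balanced designs take the closed-form path in
    :func:`compute_blues`.
    """
    from scipy.optimize import minimize

    genos = sorted(df_["accession"].unique())
    years = sorted(df_["year"].unique())
    gi = df_["accession"].map({g: i for i, g in enumerate(genos)}).to_numpy()
    yi = df_["year"].map({yr: i for i, yr in enumerate(years)}).to_numpy()
    yv = df_["value"].to_numpy(float)
    n = len(yv)

    X = np.zeros((n, len(genos)))
    X[np.arange(n), gi] = 1.0
    Zy = np.zeros((n, len(years)))
    Zy[np.arange(n), yi] = 1.0
    cells, cell_idx = np.unique(np.stack([gi, yi]), axis=1, return_inverse=True)
    Zgy = np.zeros((n, cells.shape[1]))
    Zgy[np.arange(n), cell_idx] = 1.0

    base = max(np.var(yv), 1e-12)

    def neg_reml(theta: np.ndarray) -> float:
        vy, vgy, ve = np.exp(theta) * base
        V = vy * (Zy @ Zy.T) + vgy * (Zgy @ Zgy.T) + ve * np.eye(n)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        Vi_y = np.linalg.solve(V, yv)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        resid = yv - X @ beta
        logdet_V = 2.0 * np.log(np.diag(L)).sum()
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e12
        quad = resid @ np.linalg.solve(V, resid)
        return 0.5 * (logdet_V + logdet_XtViX + quad)

    best = None
    for start in ([-1.0, -1.0, 0.0], [-3.0, -3.0, 0.0]):
        res = minimize(neg_reml, np.array(start), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    vy, vgy, ve = np.exp(best.x) * base
    V = vy * (Zy @ Zy.T) + vgy * (Zgy @ Zgy.T) + ve * np.eye(n)
    beta = np.linalg.solve(X.T @ np.linalg.solve(V, X), X.T @ np.linalg.solve(V, yv))
    return pd.Series(beta, index=genos)


def compute_blues(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype BLUEs for one trait across years and replicates.

    Genotype enters as a fixed effect; year and genotype x year are
    random.  For a fully balanced complete design the GLS solution
    collapses to the raw genotype mean, which is used directly; an
    unbalanced design is fitted by covariance-matrix REML.  Genotypes
    with no observations are excluded.

    Returns a DataFrame indexed by accession with a ``blue`` column.
    """
    df_ = obs.dropna(subset=["value"])
    if df_.empty:
        raise ValueError("no observations")
    counts = df_.groupby(["accession", "year"], observed=True).size().unstack()
    balanced = counts.notna().all().all() and counts.nunique().nunique() == 1 \
        and counts.iloc[0].nunique() == 1
    if balanced:
        blues = df_.groupby("accession", observed=True)["value"].mean()
        method = "balanced-mean"
    else:
        blues = _reml_blues_unbalanced(df_)
        method = "reml-gls"
    out = blues.rename("blue").to_frame()
    out.attrs["method"] = method
    return out


def blue_table(obs: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """BLUEs for every trait: accessions x traits wide table."""
    traits = traits if traits is not None else sorted(obs["trait"].unique())
    cols = {}
    for t in traits:
        sub = obs[obs["trait"] == t]
        if sub.empty:
            continue
        cols[t] = compute_blues(sub)["blue"]
    return pd.DataFrame(cols)


def lsd_groups(values: pd.Series, groups: pd.Series, alpha: float = 0.05
               ) -> pd.DataFrame:
    """One-way ANOVA followed by Fisher's LSD with a compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    Groups with fewer than two observations are excluded with a warning.

    Returns a DataFrame (index = group) with ``mean, n, letters``.
    """
    df_ = pd.DataFrame({"value": values, "group": groups}).dropna()
    sizes = df_.groupby("group", observed=True).size()
    small = sizes[sizes < 2].index
    if len(small):
        warnings.warn(f"excluding groups with <2 observations: {list(small)}")
        df_ = df_[~df_["group"].isin(small)]
    levels = sorted(df_["group"].unique(), key=lambda g: -df_[df_["group"] == g]["value"].mean())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")

    means = df_.groupby("group", observed=True)["value"].mean()
    ns = df_.groupby("group", observed=True).size()
    n_total = len(df_)
    k = len(levels)
    ss_within = float(
        df_.groupby("group", observed=True)["value"]
        .apply(lambda v: ((v - v.mean()) ** 2).sum())
        .sum()
    )
    df_e = n_total - k
    mse = ss_within / df_e
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df_e)

    def differ(a: str, b: str) -> bool:
        if mse == 0:
            return means[a] != means[b]
        lsd = tcrit * np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
        return abs(means[a] - means[b]) > lsd

    # maximal runs of mutually non-significant groups (means sorted desc)
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not any(
            differ(levels[a], levels[b])
            for a, b in combinations(range(i, j + 2), 2)
        ):
            j += 1
        runs.append((i, j))
    runs = [r for r in runs if not any(
        (o[0] <= r[0] and r[1] <= o[1] and o != r) for o in runs)]
    # preserve first-appearance order, drop duplicates
    seen: list[tuple[int, int]] = []
    for r in runs:
        if r not in seen:
            seen.append(r)
    letters = {lvl: "" for lvl in levels}
    for li, (a, b) in enumerate(seen):
        ch = chr(ord("a") + li)
        for idx in range(a, b + 1):
            letters[levels[idx]] += ch
    return pd.DataFrame(
        {"mean": means[levels], "n": ns[levels],
         "letters": [letters[lvl] for lvl in levels]},
        index=pd.Index(levels, name="group"),
    )
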