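"""Synthetic genotype/phenotype/metadata generator with known ground truth.

The generator emulates the statistical structure a worldwide cereal
diversity panel presents to a GWAS pipeline: ~300 accessions drawn from
~10 diverged subpopulations, block-structured linkage disequilibrium,
0/1/2 dosage genotypes with missing calls, 12 positive component traits
driven by pleiotropic QTLs plus polygenic background, year, genotype x
year and residual effects, and accession metadata (geographic region,
release year) correlated with population structure.

LD within a block comes from a founder-copying scheme: every block has a
biallelic founder state per haplotype copy; each SNP copies its
haplotype's founder allele and flips it with a probability tuned so
that the expected pairwise dosage r-squared within the block equals
``within_block_r2``.  Blocks are independent, so between-block LD is
limited to what population structure induces.

Component traits are generated on the log scale and exponentiated
(ratios need strictly positive denominators); counts are rounded to
integers afterwards.  A latent per-accession "spike size" factor is
shared across the weight and count traits, so a QTL with antagonistic
effects on a ratio's numerator and denominator is far better powered on
the ratio than on either component — the mechanism the trait-dissection
analysis exploits.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, VARIANT_COLUMNS
from .quantgen import MEASURED_TRAITS, COUNT_TRAITS, PHENO_COLUMNS

#: Geographic region labels carried by accession metadata.
REGIONS: list[str] = ["AF", "AS", "EU", "MEA", "NA", "OA", "SA"]

#: Spike developmental stages used by the expression table.
STAGES: list[str] = ["ZM1", "ZM2", "ZM3", "ZM4", "ZM5", "ZM6"]

#: Baseline trait means on the natural scale (field-realistic magnitudes).
TRAIT_BASELINES: dict[str, float] = {
    "spike_length": 10.0,
    "spike_weight": 3.0,
    "grain_weight": 1.8,
    "awn_weight": 0.15,
    "chaff_weight": 1.0,
    "rachis_weight": 0.2,
    "grain_number": 45.0,
    "spikelet_number": 20.0,
    "spikelet_weight": 0.15,
    "grain_number_spikelet": 2.5,
    "chaff_weight_spikelet": 0.05,
    "grain_weight_spikelet": 0.09,
}

#: Loading of each trait on the latent spike-size factor.
SIZE_LOADINGS: dict[str, float] = {t: 1.0 for t in MEASURED_TRAITS}
SIZE_LOADINGS["spike_length"] = 0.5
SIZE_LOADINGS["spikelet_number"] = 0.5


@dataclass
class SimConfig:
    """Study-design and variance parameters for the generator.

    Variance components ``var_G``, ``var_GxE`` and ``var_e`` apply on
    the log scale of the component traits; ``shared_size_var`` is the
    variance of the latent spike-size factor shared across traits.
    The default design mirrors a two-year field trial with five
    replicate main shoots per accession and year.
    """

    n_accessions: int = 306
    n_subpops: int = 10
    n_chroms: int = 3
    snps_per_chrom: int = 500
    chrom_length_bp: int = 50_000_000
    ld_block_size_bp: int = 2_000_000
    within_block_r2: float = 0.8
    missing_rate: float = 0.02
    n_qtl: int = 5
    qtl_h2: float = 0.05
    n_years: int = 2
    n_reps: int = 5
    var_G: float = 0.005
    var_GxE: float = 0.010
    var_e: float = 0.080
    var_year: float = 0.005
    shared_size_var: float = 0.040
    var_struct: float = 0.005
    subpop_divergence: float = 0.08
    region_coupling: float = 0.9
    n_background_snps: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_accessions": self.n_accessions, "n_subpops": self.n_subpops,
            "n_chroms": self.n_chroms, "snps_per_chrom": self.snps_per_chrom,
            "chrom_length_bp": self.chrom_length_bp,
            "ld_block_size_bp": self.ld_block_size_bp,
            "n_years": self.n_years, "n_reps": self.n_reps,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be >= 0")
        for name, v in (("within_block_r2", self.within_block_r2),
                        ("missing_rate", self.missing_rate),
                        ("region_coupling", self.region_coupling)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, v in (("var_G", self.var_G), ("var_GxE", self.var_GxE),
                        ("var_e", self.var_e), ("var_year", self.var_year),
                        ("shared_size_var", self.shared_size_var),
                        ("var_struct", self.var_struct),
                        ("qtl_h2", self.qtl_h2)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_qtl * self.qtl_h2 >= 1.0:
            raise ValueError("total QTL variance fraction must be < 1")
        if not 0.0 < self.subpop_divergence < 1.0:
            raise ValueError("subpop_divergence must be in (0, 1)")


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Named, seed-derived substream (stable across runs/platforms)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


def assign_subpops(cfg: SimConfig) -> np.ndarray:
    """Deterministic near-equal subpopulation assignment per accession."""
    return np.arange(cfg.n_accessions) % cfg.n_subpops


def _flip_prob(rho: float, p: float) -> float:
    """Per-SNP founder-flip probability giving within-block dosage r2 ~ rho.

    Two block SNPs with flip probabilities eps_s, eps_t have haploid
    allele correlation gamma_s * gamma_t with
    gamma = (1 - 2 eps) sqrt(p(1-p) / (q(1-q))), q = p + eps(1 - 2p);
    setting gamma = rho**(1/4) per SNP yields r2 = rho.  Solved by a
    short fixed-point iteration.
    """
    if rho >= 1.0:
        return 0.0
    target = rho ** 0.25
    eps = (1.0 - target) / 2.0
    for _ in range(8):
        q = p + eps * (1.0 - 2.0 * p)
        ratio = np.sqrt(max(q * (1.0 - q), 1e-9) / max(p * (1.0 - p), 1e-9))
        eps = (1.0 - target * ratio) / 2.0
        eps = min(max(eps, 0.0), 0.5)
    return eps


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Generate a block-LD, structured, partially missing dosage matrix."""
    rng = _rng(cfg.seed, "genotypes")
    subpops = assign_subpops(cfg)
    n = cfg.n_accessions
    F = cfg.subpop_divergence

    all_dosages: list[np.ndarray] = []
    records: list[tuple] = []
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        m = cfg.snps_per_chrom
        pos = np.array([], dtype=np.int64)
        while len(pos) < m:
            extra = rng.integers(1, cfg.chrom_length_bp + 1,
                                 size=2 * (m - len(pos)) + 8)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=m, replace=False))
        block_ids = pos // cfg.ld_block_size_bp

        chrom_dos = np.empty((n, m), dtype=np.int8)
        for b in np.unique(block_ids):
            cols = np.flatnonzero(block_ids == b)
            k = len(cols)
            p_anc = rng.uniform(0.1, 0.9)
            a = p_anc * (1.0 - F) / F
            bpar = (1.0 - p_anc) * (1.0 - F) / F
            p_sp = np.clip(rng.beta(a, bpar, size=cfg.n_subpops), 0.02, 0.98)
            p_acc = p_sp[subpops]
            founder1 = rng.random(n) < p_acc
            founder2 = rng.random(n) < p_acc
            eps = _flip_prob(cfg.within_block_r2, p_anc)
            flips1 = rng.random((n, k)) < eps
            flips2 = rng.random((n, k)) < eps
            h1 = founder1[:, None] ^ flips1
            h2 = founder2[:, None] ^ flips2
            chrom_dos[:, cols] = (h1.astype(np.int8) + h2.astype(np.int8))
        all_dosages.append(chrom_dos)
        for p in pos:
            records.append((f"{chrom}_{p}", chrom, int(p), "A", "T"))

    dosages = np.concatenate(all_dosages, axis=1)
    if cfg.missing_rate > 0:
        mask = _rng(cfg.seed, "missing").random(dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(dosages, [f"acc{i:04d}" for i in range(n)], variants)


@dataclass
class TruthRecord:
    """Ground truth behind a simulated dataset.

    ``qtl_effects`` maps trait name -> {snp_id: log-scale additive
    effect per alt allele}; ``subpops`` is the per-accession
    subpopulation index.
    """

    qtl_snp_ids: list[str]
    qtl_effects: dict[str, dict[str, float]]
    subpops: np.ndarray

    def validate_against(self, gm: GenotypeMatrix) -> None:
        known = set(gm.variants["id"])
        for sid in self.qtl_snp_ids:
            if sid not in known:
                raise ValueError(f"QTL SNP {sid} absent from genotype matrix")
        for trait, eff in self.qtl_effects.items():
            for sid in eff:
                if sid not in known:
                    raise ValueError(f"QTL SNP {sid} absent from genotype matrix")


def _dosage_var(gm: GenotypeMatrix, sid: str) -> float:
    x = gm.dosages[:, gm.snp_index(sid)].astype(float)
    x = x[x != MISSING]
    return float(np.var(x)) if len(x) else 0.0


def make_truth(gm: GenotypeMatrix, cfg: SimConfig,
               traits_per_qtl: tuple[int, int] = (2, 4)) -> TruthRecord:
    """Pick QTL SNPs and assign signed pleiotropic effects to component traits.

    QTLs are drawn from reasonably common SNPs (MAF >= 0.15), at most
    one per LD block, and each one receives effects on a random 2-4
    measured traits sized so that it explains about ``cfg.qtl_h2`` of
    that trait's log-scale variance.
    """
    rng = _rng(cfg.seed, "truth")
    from .genotype_io import allele_stats

    stats = allele_stats(gm)
    block = stats["pos"].to_numpy() // cfg.ld_block_size_bp
    block_key = stats["chrom"].astype(str) + ":" + pd.Series(block).astype(str)
    ok = np.flatnonzero((stats["maf"] >= 0.15).to_numpy())
    rng.shuffle(ok)
    chosen: list[int] = []
    used_blocks: set[str] = set()
    for idx in ok:
        if block_key.iloc[idx] in used_blocks:
            continue
        chosen.append(int(idx))
        used_blocks.add(block_key.iloc[idx])
        if len(chosen) == cfg.n_qtl:
            break
    if len(chosen) < cfg.n_qtl:
        raise ValueError("not enough common SNPs in distinct blocks for QTLs")
    qtl_ids = [stats["id"].iloc[i] for i in chosen]

    base_var = (cfg.shared_size_var + cfg.var_struct + cfg.var_G
                + cfg.var_GxE + cfg.var_e)
    effects: dict[str, dict[str, float]] = {t: {} for t in MEASURED_TRAITS}
    for sid in qtl_ids:
        vx = _dosage_var(gm, sid)
        if vx <= 0:
            continue
        n_traits = int(rng.integers(traits_per_qtl[0], traits_per_qtl[1] + 1))
        picked = rng.choice(MEASURED_TRAITS, size=n_traits, replace=False)
        beta = np.sqrt(cfg.qtl_h2 * base_var / (1.0 - cfg.n_qtl * cfg.qtl_h2) / vx)
        for t in picked:
            effects[t][sid] = float(beta * rng.choice([-1.0, 1.0]))
    return TruthRecord(qtl_ids, {t: e for t, e in effects.items() if e},
                       assign_subpops(cfg))


def make_antagonistic_truth(gm: GenotypeMatrix, cfg: SimConfig, snp_id: str,
                            numerator: str, denominator: str,
                            h2_component: float) -> TruthRecord:
    """One QTL raising ``numerator`` and lowering ``denominator`` equally,
    sized to explain ``h2_component`` of each component's log variance."""
    vx = _dosage_var(gm, snp_id)
    if vx <= 0:
        raise ValueError(f"{snp_id} is monomorphic")
    base_var = (cfg.shared_size_var + cfg.var_struct + cfg.var_G
                + cfg.var_GxE + cfg.var_e)
    beta = np.sqrt(h2_component * base_var / (1.0 - h2_component) / vx)
    return TruthRecord(
        [snp_id],
        {numerator: {snp_id: float(beta)}, denominator: {snp_id: float(-beta)}},
        assign_subpops(cfg),
    )


def _qtl_block_mask(gm: GenotypeMatrix, cfg: SimConfig,
                    truth: "TruthRecord") -> np.ndarray:
    """True for SNPs sharing an LD block with any QTL SNP."""
    v = gm.variants
    block = v["pos"].to_numpy() // cfg.ld_block_size_bp
    chrom = v["chrom"].to_numpy()
    mask = np.zeros(gm.n_snps, dtype=bool)
    for sid in truth.qtl_snp_ids:
        j = gm.snp_index(sid)
        mask |= (chrom == chrom[j]) & (block == block[j])
    return mask


def _background_scores(gm: GenotypeMatrix, cfg: SimConfig,
                       exclude: np.ndarray | None = None) -> np.ndarray:
    """Standardized dosages of a random SNP subset for polygenic backgrounds.

    ``exclude`` masks out SNPs (the planted QTL blocks) so the
    background is genuinely distinct from the focal loci.
    """
    rng = _rng(cfg.seed, "background")
    pool = np.arange(gm.n_snps)
    if exclude is not None and exclude.any():
        pool = pool[~exclude]
    k = min(cfg.n_background_snps, len(pool))
    cols = rng.choice(pool, size=k, replace=False)
    d = gm.dosages[:, cols].astype(float)
    called = d != MISSING
    mu = np.where(called, d, 0.0).sum(axis=0) / np.maximum(called.sum(axis=0), 1)
    d = np.where(called, d, mu[None, :])
    sd = d.std(axis=0)
    keep = sd > 0
    return (d[:, keep] - d[:, keep].mean(axis=0)) / sd[keep]


def _polygenic(Z: np.ndarray, target_var: float,
               rng: np.random.Generator) -> np.ndarray:
    """Sum of small random SNP effects, rescaled to target variance."""
    if target_var == 0 or Z.shape[1] == 0:
        return np.zeros(Z.shape[0])
    g = Z @ rng.normal(0.0, 1.0, Z.shape[1])
    sd = g.std()
    return g * (np.sqrt(target_var) / sd) if sd > 0 else g


def simulate_phenotypes(gm: GenotypeMatrix, truth: TruthRecord,
                        cfg: SimConfig) -> pd.DataFrame:
    """Simulate the 12 component traits per accession x year x replicate.

    log(value) = baseline + polygenic size-factor + QTL dosage effects +
    per-trait polygenic background (var_G) + per-subpopulation trait
    effect (var_struct, the geography-correlated variance worldwide
    panels show) + year (var_year) + genotype x year (var_GxE) +
    residual (var_e); values are exponentiated and count traits rounded
    to integers (min 1).  The size factor and
    backgrounds are sums of many small SNP effects
    (``n_background_snps``), so a kinship-based mixed model can absorb
    them the way it does real polygenic variance.  Deterministic under
    cfg.seed.
    """
    truth.validate_against(gm)
    rng = _rng(cfg.seed, "phenotypes")
    n = gm.n_accessions
    Zbg = _background_scores(gm, cfg, exclude=_qtl_block_mask(gm, cfg, truth))
    # stable accession-level vigor: shared across traits but not tracked by
    # genome-wide kinship (seed quality, micro-environment of the plot)
    size_factor = _rng(cfg.seed, "size").normal(
        0.0, np.sqrt(cfg.shared_size_var), n)

    # centered, mean-imputed dosage per QTL SNP
    dos_cache: dict[str, np.ndarray] = {}
    for sid in {s for eff in truth.qtl_effects.values() for s in eff}:
        x = gm.dosages[:, gm.snp_index(sid)].astype(float)
        called = x != MISSING
        mu = x[called].mean() if called.any() else 0.0
        x = np.where(called, x, mu) - mu
        dos_cache[sid] = x

    rows = []
    subpops = assign_subpops(cfg)
    for trait in MEASURED_TRAITS:
        mu_t = np.log(TRAIT_BASELINES[trait])
        genetic = size_factor * SIZE_LOADINGS[trait]
        genetic = genetic + _polygenic(Zbg, cfg.var_G, rng)
        if cfg.var_struct > 0:
            sub_eff = rng.normal(0.0, np.sqrt(cfg.var_struct), cfg.n_subpops)
            genetic = genetic + sub_eff[subpops]
        for sid, beta in truth.qtl_effects.get(trait, {}).items():
            genetic = genetic + beta * dos_cache[sid]
        for j in range(cfg.n_years):
            year_eff = rng.normal(0.0, np.sqrt(cfg.var_year))
            gxe = rng.normal(0.0, np.sqrt(cfg.var_GxE), n)
            for r in range(cfg.n_reps):
                e = rng.normal(0.0, np.sqrt(cfg.var_e), n)
                logv = mu_t + genetic + year_eff + gxe + e
                vals = np.exp(logv)
                if trait in COUNT_TRAITS:
                    vals = np.maximum(np.rint(vals), 1.0)
                rows.append(pd.DataFrame({
                    "accession": gm.accession_ids,
                    "trait": trait,
                    "year": 2000 + j,
                    "rep": r + 1,
                    "value": vals,
                }))
    return pd.concat(rows, ignore_index=True)[PHENO_COLUMNS]


def simulate_anova_observations(n_genotypes: int, n_years: int, n_reps: int,
                                var_G: float, var_GxE: float, var_e: float,
                                mean: float = 50.0, seed: int = 0
                                ) -> pd.DataFrame:
    """Plain linear-scale two-way design: y_ijk = mu + g_i + y_j + (gy)_ij
    + e_ijk with the stated variance components; year effects have unit
    variance (their scale does not enter G/GxE/e recovery).  Used to
    verify variance-component estimation."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, np.sqrt(var_G), n_genotypes)
    yr = rng.normal(0.0, 1.0, n_years)
    gxe = rng.normal(0.0, np.sqrt(var_GxE), (n_genotypes, n_years))
    rows = []
    for j in range(n_years):
        for r in range(n_reps):
            e = rng.normal(0.0, np.sqrt(var_e), n_genotypes)
            rows.append(pd.DataFrame({
                "accession": [f"g{i:04d}" for i in range(n_genotypes)],
                "trait": "trait",
                "year": 2000 + j,
                "rep": r + 1,
                "value": mean + g + yr[j] + gxe[:, j] + e,
            }))
    return pd.concat(rows, ignore_index=True)[PHENO_COLUMNS]


def simulate_metadata(cfg: SimConfig) -> pd.DataFrame:
    """Per-accession geographic region and release year.

    Each subpopulation has a home region (the 7 labels cycled over the
    subpopulations); an accession inherits it with probability
    ``region_coupling`` and draws a uniform region otherwise, so
    geography correlates with — and at coupling 1.0 is a deterministic
    function of — population structure.
    """
    rng = _rng(cfg.seed, "metadata")
    subpops = assign_subpops(cfg)
    home = np.array([REGIONS[s % len(REGIONS)] for s in range(cfg.n_subpops)])
    region = home[subpops].copy()
    flip = rng.random(cfg.n_accessions) >= cfg.region_coupling
    region[flip] = rng.choice(REGIONS, size=int(flip.sum()))
    release_year = rng.integers(1900, 2021, size=cfg.n_accessions)
    return pd.DataFrame({
        "accession": [f"acc{i:04d}" for i in range(cfg.n_accessions)],
        "region": region,
        "release_year": release_year,
        "subpop": subpops,
    })


def simulate_annotation(cfg: SimConfig, genes_per_chrom: int = 20,
                        gene_length_bp: int = 5_000) -> pd.DataFrame:
    """Evenly spaced gene models (1-based inclusive spans) per chromosome."""
    rng = _rng(cfg.seed, "annotation")
    rows = []
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        starts = np.linspace(1, cfg.chrom_length_bp - gene_length_bp,
                             genes_per_chrom).astype(int)
        starts = starts + rng.integers(0, gene_length_bp, size=genes_per_chrom)
        for i, s in enumerate(starts):
            rows.append({
                "gene_id": f"gene_{chrom}_{i:03d}",
                "chrom": chrom,
                "start": int(s),
                "end": int(s + gene_length_bp - 1),
                "strand": "+" if rng.random() < 0.5 else "-",
            })
    return pd.DataFrame(rows)


def simulate_expression(gene_ids: list[str], seed: int = 0,
                        frac_expressed: float = 0.5) -> pd.DataFrame:
    """FPKM per gene across the six spike developmental stages ZM1-ZM6.

    A ``frac_expressed`` share of genes is expressed (lognormal FPKM,
    well above 1); the rest are near-silent (FPKM << 1) during spike
    development.
    """
    rng = _rng(seed, "expression")
    rows = []
    for gid in gene_ids:
        expressed = rng.random() < frac_expressed
        if expressed:
            fpkm = rng.lognormal(2.5, 0.6, size=len(STAGES))
        else:
            fpkm = rng.uniform(0.0, 0.2, size=len(STAGES))
        rows.append({"gene_id": gid, **{s: fpkm[i] for i, s in enumerate(STAGES)}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- writers

def write_gff3(genes: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.gene_id}\n"
            )


def write_truth_json(truth: TruthRecord, path: str) -> None:
    payload = {
        "qtl_snp_ids": truth.qtl_snp_ids,
        "qtl_effects": truth.qtl_effects,
        "subpops": [int(s) for s in truth.subpops],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth_json(path: str) -> TruthRecord:
    with open(path) as fh:
        payload = json.load(fh)
    return TruthRecord(payload["qtl_snp_ids"], payload["qtl_effects"],
                       np.asarray(payload["subpops"]))
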