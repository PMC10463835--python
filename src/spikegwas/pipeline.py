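"""End-to-end pipeline: simulate/read -> filter -> traits -> H2/BLUEs ->
kinship/PCA -> MLM scans -> thresholds -> peaks -> candidates -> haplotypes.

Every stage writes plain TSV/JSON/VCF files into the run directory so
each step is independently inspectable, and a manifest records the
configuration hash, seed and per-stage row counts.  All randomness
derives from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import genotype_io, gwas, haplotypes, peaks as peaks_mod, popgen, quantgen
from .simulate import (SimConfig, make_truth, simulate_annotation,
                       simulate_expression, simulate_genotypes,
                       simulate_metadata, simulate_phenotypes, write_gff3,
                       write_truth_json)

log = logging.getLogger("spikegwas")


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``simulate`` or the input
    paths (vcf + phenotypes) must be given."""

    out_dir: str = "run"
    simulate: SimConfig | None = None
    vcf: str | None = None
    phenotypes: str | None = None
    metadata: str | None = None
    gff3: str | None = None
    expression: str | None = None

    maf_min: float = 0.05
    max_missing: float = 0.2
    n_pcs: int = 3
    threshold_neglog10: float = 5.00
    clump_r2: float = 0.1
    merge_gap_bp: int = 5_000_000
    min_peak_snps: int = 10
    gene_window_bp: int = 500_000
    fpkm_min: float = 1.0
    hap_min_freq: float = 0.05
    n_perm: int = 0
    traits_to_scan: list[str] | None = None
    hap_region: tuple[str, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        sim_mode = self.simulate is not None
        file_mode = self.vcf is not None and self.phenotypes is not None
        if sim_mode == file_mode:
            raise ValueError("config must give exactly one of a simulate "
                             "block or input paths (vcf + phenotypes)")
        for name, v, lo, hi in (
            ("maf_min", self.maf_min, 0, 1), ("max_missing", self.max_missing, 0, 1),
            ("clump_r2", self.clump_r2, 0, 1), ("hap_min_freq", self.hap_min_freq, 0, 1),
        ):
            if not lo <= v <= hi:
                raise ValueError(f"{name} out of range: {v}")
        if self.threshold_neglog10 <= 0 or self.n_pcs < 1:
            raise ValueError("invalid threshold or n_pcs")


def load_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "simulate" in raw and raw["simulate"] is not None:
        raw["simulate"] = SimConfig(**raw["simulate"])
    if "hap_region" in raw and raw["hap_region"] is not None:
        raw["hap_region"] = tuple(raw["hap_region"])
    return RunConfig(**raw)


def _config_hash(cfg: RunConfig) -> str:
    payload = asdict(cfg)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Any stage failure aborts with the stage name in the raised error;
    files written by earlier stages are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }
    stage = "init"
    try:
        # ---------------------------------------------- inputs
        stage = "inputs"
        truth = None
        metadata = annotation = expression = None
        if cfg.simulate is not None:
            sim = cfg.simulate
            gm = simulate_genotypes(sim)
            truth = make_truth(gm, sim)
            pheno = simulate_phenotypes(gm, truth, sim)
            metadata = simulate_metadata(sim)
            annotation = simulate_annotation(sim)
            expression = simulate_expression(list(annotation["gene_id"]),
                                             seed=sim.seed)
            genotype_io.write_vcf(gm, out / "genotypes.vcf")
            pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
            metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
            write_gff3(annotation, out / "annotation.gff3")
            expression.to_csv(out / "expression.tsv", sep="\t", index=False)
            write_truth_json(truth, out / "truth.json")
        else:
            gm = genotype_io.read_vcf(cfg.vcf)
            pheno = pd.read_csv(cfg.phenotypes, sep="\t")
            if cfg.metadata:
                metadata = pd.read_csv(cfg.metadata, sep="\t")
            if cfg.gff3:
                annotation = peaks_mod.read_gff3_genes(cfg.gff3)
            if cfg.expression:
                expression = pd.read_csv(cfg.expression, sep="\t")
        manifest["stages"]["inputs"] = {
            "n_accessions": gm.n_accessions, "n_snps": gm.n_snps,
            "n_phenotype_records": len(pheno),
        }
        log.info("[inputs] %d accessions x %d SNPs", gm.n_accessions, gm.n_snps)

        # ---------------------------------------------- filter
        stage = "filter"
        genotype_io.write_variant_report(gm, out / "variant_report.tsv",
                                         cfg.maf_min, cfg.max_missing)
        gm, counts = genotype_io.filter_variants(gm, cfg.maf_min, cfg.max_missing)
        manifest["stages"]["filter"] = counts
        log.info("[filter] kept %d dropped %d", counts["kept"], counts["dropped"])

        # ---------------------------------------------- traits
        stage = "traits"
        pheno27 = quantgen.derive_traits(pheno)
        pheno27.to_csv(out / "phenotypes_27.tsv", sep="\t", index=False)
        all_traits = sorted(pheno27["trait"].unique())
        manifest["stages"]["traits"] = {"n_traits": len(all_traits)}

        # ---------------------------------------------- H2 + BLUEs
        stage = "heritability"
        h2_rows = []
        for t in all_traits:
            sub = pheno27[pheno27["trait"] == t].dropna(subset=["value"])
            try:
                vc = quantgen.anova_components(sub)
                h2 = quantgen.heritability(vc)
                h2_rows.append({
                    "trait": t, "var_G": vc.var_G, "var_GxE": vc.var_GxE,
                    "var_e": vc.var_e, "H2": h2,
                    "F_genotype": vc.f_stats.get("genotype", np.nan),
                    "p_genotype": vc.p_values.get("genotype", np.nan),
                })
            except ValueError as exc:
                log.warning("[heritability] %s: %s", t, exc)
        h2_table = pd.DataFrame(h2_rows)
        h2_table.to_csv(out / "heritability.tsv", sep="\t", index=False)

        stage = "blues"
        blues = quantgen.blue_table(pheno27, all_traits)
        blues.to_csv(out / "blues.tsv", sep="\t")
        manifest["stages"]["blues"] = {"n_accessions": len(blues),
                                       "n_traits": blues.shape[1]}

        # ---------------------------------------------- kinship + PCA
        stage = "kinship"
        K = popgen.kinship_simple_matching(gm)
        K.to_csv(out / "kinship.tsv", sep="\t")
        stage = "pca"
        pcs, frac = popgen.pca_genotypes(gm, n_components=max(cfg.n_pcs, 3),
                                         prune_r2=cfg.clump_r2 * 2)
        pcs.assign(**{f"varfrac_PC{i+1}": f for i, f in enumerate(frac)}) \
           .to_csv(out / "pca.tsv", sep="\t")
        manifest["stages"]["pca"] = {"var_fractions": [float(f) for f in frac]}

        # ---------------------------------------------- scans
        stage = "scan"
        scan_traits = cfg.traits_to_scan or all_traits
        order = [a for a in gm.accession_ids if a in blues.index]
        Kmat = K.loc[order, order].to_numpy()
        S = gwas.build_covariates(pcs.loc[order], cfg.n_pcs)
        results: dict[str, pd.DataFrame] = {}
        gm_scan = gm.take_accessions(
            np.asarray([gm.accession_ids.index(a) for a in order]))
        # LOCO kinship keeps the tested chromosome out of the polygenic
        # covariance; fall back to the all-SNP K on single-chromosome input
        use_loco = gm_scan.variants["chrom"].nunique() >= 2
        kin_loco = gwas.loco_kinship(gm_scan) if use_loco else None
        for t in scan_traits:
            if t not in blues.columns:
                continue
            y = blues.loc[order, t].to_numpy(float)
            if np.isnan(y).any():
                keep = ~np.isnan(y)
                gm_t = gm_scan.take_accessions(np.flatnonzero(keep))
                res = gwas.association_scan(
                    gm_t, y[keep], S[keep],
                    gwas.loco_kinship(gm_t) if use_loco
                    else Kmat[np.ix_(keep, keep)],
                    trait=t, loco=use_loco)
            else:
                res = gwas.association_scan(
                    gm_scan, y, S, kin_loco if use_loco else Kmat,
                    trait=t, loco=use_loco)
            res.to_csv(out / f"assoc_{t}.tsv", sep="\t", index=False)
            results[t] = res
        manifest["stages"]["scan"] = {"n_traits_scanned": len(results)}

        # ---------------------------------------------- thresholds
        stage = "thresholds"
        _, n_indep = gwas.ld_prune_count(gm, r2_max=0.2)
        bonf = gwas.bonferroni_threshold(n_indep)
        thresholds = {
            "bonferroni": {k: v for k, v in bonf.items()},
            "working_neglog10p": cfg.threshold_neglog10,
            "n_independent": n_indep,
        }
        if cfg.n_perm >= 20 and results:
            t0 = scan_traits[0]
            y0 = blues.loc[order, t0].to_numpy(float)
            perm = gwas.permutation_threshold(
                gm_scan, y0, S, kin_loco if use_loco else Kmat,
                n_perm=cfg.n_perm, seed=cfg.seed, loco=use_loco)
            thresholds["permutation"] = {
                "p": perm["p"], "neglog10p": perm["neglog10p"], "trait": t0,
            }
        with open(out / "thresholds.json", "w") as fh:
            json.dump(thresholds, fh, indent=1)
        manifest["stages"]["thresholds"] = {"n_independent": n_indep}

        # ---------------------------------------------- peaks
        stage = "peaks"
        peaks_by_trait: dict[str, list] = {}
        all_peaks = []
        for t, res in results.items():
            sig = res[res["neglog10p"] > cfg.threshold_neglog10]
            ivs = peaks_mod.delineate_intervals(sig, gm_scan, cfg.clump_r2)
            pk = peaks_mod.merge_and_call_peaks(ivs, sig, cfg.merge_gap_bp,
                                                cfg.min_peak_snps)
            peaks_by_trait[t] = pk
            all_peaks.extend(pk)
        pd.concat(
            [peaks_mod.peaks_to_frame(p).assign(trait=t)
             for t, p in peaks_by_trait.items() if p],
            ignore_index=True,
        ).to_csv(out / "peaks.tsv", sep="\t", index=False) if all_peaks else \
            pd.DataFrame().to_csv(out / "peaks.tsv", sep="\t", index=False)
        ratio_set = set(quantgen.RATIO_TRAIT_NAMES)
        regions = peaks_mod.cross_trait_summary(peaks_by_trait, ratio_set)
        regions.to_csv(out / "regions.tsv", sep="\t", index=False)
        manifest["stages"]["peaks"] = {
            "n_intervals": len(all_peaks),
            "n_peaks": sum(p.is_peak for p in all_peaks),
            "n_regions": len(regions),
        }

        # ---------------------------------------------- candidate genes
        stage = "candidates"
        best_peak = None
        scored = [p for p in all_peaks if p.is_peak] or all_peaks
        if scored:
            best_peak = max(scored, key=lambda p: p.best_neglog10p)
        cands = []
        if best_peak is not None and annotation is not None:
            cands = peaks_mod.candidate_genes(best_peak, annotation, expression,
                                              cfg.gene_window_bp, cfg.fpkm_min)
            peaks_mod.candidates_to_frame(cands).to_csv(
                out / "candidates.tsv", sep="\t", index=False)
        manifest["stages"]["candidates"] = {"n_candidates": len(cands)}

        # ---------------------------------------------- haplotypes
        stage = "haplotypes"
        region = cfg.hap_region
        if region is None and cands:
            top = cands[0]
            region = (top.chrom, top.start, top.end)
        elif region is None and best_peak is not None:
            # no annotated gene in the window: fall back to the lead
            # SNP's immediate neighborhood
            region = (best_peak.chrom, max(best_peak.lead_pos - 100_000, 1),
                      best_peak.lead_pos + 100_000)
        hap_summary = {}
        if region is not None:
            chrom, start, end = region
            gm_reg = gm_scan.region(chrom, int(start), int(end))
            try:
                assign = haplotypes.assign_haplotypes(gm_reg, cfg.hap_min_freq)
                assign.labels.rename_axis("accession").to_frame().to_csv(
                    out / "haplotype_assignment.tsv", sep="\t")
                try:
                    eff = haplotypes.haplotype_trait_effects(assign, blues)
                    eff.to_csv(out / "haplotype_effects.tsv", sep="\t",
                               index=False)
                except ValueError as exc:
                    log.warning("[haplotypes] effects: %s", exc)
                if metadata is not None:
                    for gb in ("region", "decade"):
                        freq = haplotypes.haplotype_frequencies(assign, metadata,
                                                                gb)
                        freq.to_csv(out / f"haplotype_freq_{gb}.tsv", sep="\t",
                                    index=False)
                try:
                    tajd = popgen.tajimas_d(gm_reg)
                except ValueError:
                    tajd = None
                hap_summary = {
                    "region": list(region),
                    "n_major": len(assign.patterns),
                    "coverage": assign.coverage,
                    "tajimas_d": tajd,
                }
            except ValueError as exc:
                log.warning("[haplotypes] %s", exc)
        manifest["stages"]["haplotypes"] = hap_summary

    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
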