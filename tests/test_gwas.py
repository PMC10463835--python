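import numpy as np
import pytest
import statsmodels.api as sm

from spikegwas import gwas, popgen
from spikegwas.gwas import (ScanEngine, association_scan, bonferroni_threshold,
                            fit_null_mlm, genomic_control_lambda,
                            ld_prune_count, permutation_threshold)
from spikegwas.popgen import bend_psd, kinship_simple_matching
from spikegwas.simulate import SimConfig, simulate_genotypes

from conftest import make_gm


def structured_K(n, seed=0):
    cfg = SimConfig(n_accessions=n, n_chroms=2, snps_per_chrom=150,
                    missing_rate=0.0, seed=seed)
    gm = simulate_genotypes(cfg)
    return gm, kinship_simple_matching(gm).to_numpy()


class TestNullFit:
    def test_iid_phenotype_gives_near_zero_lambda(self):
        """Without polygenic signal the REML variance ratio collapses to
        the boundary; single-draw estimates are half-normal above zero,
        so the median over seeds is the stable summary."""
        gm, K = structured_K(120, seed=1)
        S = np.ones((120, 1))
        lams = []
        for seed in range(11):
            y = np.random.default_rng(seed).normal(size=120)
            lams.append(fit_null_mlm(y, S, K).lambda_)
        assert np.median(lams) < 1e-3

    def test_reml_loglik_is_maximal_at_estimate(self):
        gm, K = structured_K(100, seed=2)
        rng = np.random.default_rng(1)
        L = np.linalg.cholesky(bend_psd(K))
        y = L @ rng.normal(size=100) + rng.normal(size=100)
        S = np.ones((100, 1))
        fit = fit_null_mlm(y, S, K)
        lam = max(fit.lambda_, 1e-6)
        ll_hat = -gwas._neg_reml_loglik(np.log(lam), fit.eigvals, fit.yt, fit.Xt)
        for factor in (1.5, 1 / 1.5):
            ll = -gwas._neg_reml_loglik(np.log(lam * factor), fit.eigvals,
                                        fit.yt, fit.Xt)
            assert ll_hat >= ll - 1e-8

    def test_lambda_recovery_within_twofold_median(self):
        """Generating sg2/se2 = 1 on the panel's own kinship; the median
        REML estimate over 50 seeds stays within two-fold."""
        gm, K = structured_K(150, seed=3)
        Kb = bend_psd(K)
        L = np.linalg.cholesky(Kb)
        S = np.ones((150, 1))
        est = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = L @ rng.normal(size=150) + rng.normal(size=150)
            est.append(fit_null_mlm(y, S, K).lambda_)
        med = np.median(est)
        assert 0.5 <= med <= 2.0

    def test_rank_deficient_covariates_rejected(self):
        gm, K = structured_K(50, seed=4)
        S = np.ones((50, 2))  # duplicated intercept
        with pytest.raises(ValueError, match="rank"):
            fit_null_mlm(np.random.default_rng(0).normal(size=50), S, K)


class TestAssociationScan:
    def test_identity_kinship_equals_ols(self):
        """With K = I the GLS collapses to OLS: per-SNP t statistics and
        p-values must agree with statsmodels to 1e-8."""
        cfg = SimConfig(n_accessions=100, n_chroms=1, snps_per_chrom=60,
                        missing_rate=0.0, seed=5)
        gm = simulate_genotypes(cfg)
        rng = np.random.default_rng(2)
        y = rng.normal(size=100)
        S = np.column_stack([np.ones(100), rng.normal(size=(100, 2))])
        res = association_scan(gm, y, S, np.eye(100))
        X, poly = gwas._prepare_dosages(gm)
        for j in range(gm.n_snps):
            if not poly[j]:
                continue
            fit = sm.OLS(y, np.column_stack([S, X[:, j]])).fit()
            assert res["wald"].iloc[j] == pytest.approx(fit.tvalues[-1],
                                                        abs=1e-8)
            assert res["p"].iloc[j] == pytest.approx(fit.pvalues[-1], abs=1e-8)

    def test_null_calibration_fraction(self):
        gm, K = structured_K(150, seed=6)
        rng = np.random.default_rng(3)
        L = np.linalg.cholesky(bend_psd(K))
        y = L @ rng.normal(size=150) + rng.normal(size=150)
        pcs, _ = popgen.pca_genotypes(gm, 3, prune_r2=None)
        S = gwas.build_covariates(pcs.to_numpy(), 3)
        res = association_scan(gm, y, S, K)
        frac = (res["p"] < 0.05).mean()
        sd = np.sqrt(0.05 * 0.95 / res["p"].notna().sum())
        assert abs(frac - 0.05) < 4 * sd + 0.01

    def test_affine_phenotype_invariance(self):
        gm, K = structured_K(80, seed=7)
        rng = np.random.default_rng(4)
        y = rng.normal(size=80)
        S = np.ones((80, 1))
        p1 = association_scan(gm, y, S, K)["p"]
        p2 = association_scan(gm, 3.0 - 2.5 * y, S, K)["p"]
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_exact_mode_close_to_approx(self):
        """P3D (lambda fixed at the null fit) and per-SNP REML re-fitting
        agree closely in the bulk; only the very strongest signals move
        the variance ratio enough to shift log10 p visibly."""
        cfg = SimConfig(n_accessions=200, n_chroms=2, snps_per_chrom=100,
                        missing_rate=0.0, seed=8)
        gm = simulate_genotypes(cfg)
        K = kinship_simple_matching(gm).to_numpy()
        rng = np.random.default_rng(5)
        L = np.linalg.cholesky(bend_psd(K))
        y = 0.7 * (L @ rng.normal(size=200)) + rng.normal(size=200)
        S = np.ones((200, 1))
        approx = association_scan(gm, y, S, K, mode="approx")
        exact = association_scan(gm, y, S, K, mode="exact")
        ok = approx["p"].notna() & exact["p"].notna()
        delta = np.abs(np.log10(approx["p"][ok]) - np.log10(exact["p"][ok]))
        assert np.quantile(delta, 0.99) < 0.2
        assert delta.max() < 0.5

    def test_injected_qtl_attains_minimum_p(self):
        """A SNP explaining 10% of variance is the scan's top hit in at
        least 90% of 50 seeds (n = 300, independent markers)."""
        cfg = SimConfig(n_accessions=300, n_chroms=2, snps_per_chrom=250,
                        ld_block_size_bp=1, missing_rate=0.0, seed=9)
        gm = simulate_genotypes(cfg)
        K = kinship_simple_matching(gm).to_numpy()
        pcs, _ = popgen.pca_genotypes(gm, 3, prune_r2=None)
        S = gwas.build_covariates(pcs.to_numpy(), 3)
        from spikegwas.genotype_io import allele_stats
        st = allele_stats(gm)
        target = st.loc[(st["maf"] - 0.4).abs().idxmin(), "id"]
        j = gm.snp_index(target)
        x = gm.dosages[:, j].astype(float)
        x = (x - x.mean()) / x.std()
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            y = x * np.sqrt(0.1) + rng.normal(0, np.sqrt(0.9), 300)
            res = association_scan(gm, y, S, K)
            hits += res.loc[res["p"].idxmin(), "snp"] == target
        assert hits >= 45

    def test_structure_correction_improves_genomic_control(self):
        """Lambda_GC of a structure-confounded null is closer to 1 with
        PC + kinship correction than without (median over 20 seeds)."""
        cfg = SimConfig(n_accessions=120, n_chroms=2, snps_per_chrom=150,
                        subpop_divergence=0.15, missing_rate=0.0, seed=10)
        gm = simulate_genotypes(cfg)
        K = kinship_simple_matching(gm).to_numpy()
        pcs, _ = popgen.pca_genotypes(gm, 3, prune_r2=None)
        S = gwas.build_covariates(pcs.to_numpy(), 3)
        subpop = np.arange(120) % cfg.n_subpops
        gaps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=cfg.n_subpops)[subpop] + rng.normal(
                0, 0.7, 120)
            corrected = association_scan(gm, y, S, K)["p"]
            naive = association_scan(gm, y, np.ones((120, 1)), np.eye(120))["p"]
            gaps.append(abs(genomic_control_lambda(corrected) - 1)
                        - abs(genomic_control_lambda(naive) - 1))
        assert np.median(gaps) < 0


class TestLdPrune:
    def test_independent_snps_all_survive(self):
        cfg = SimConfig(n_accessions=150, n_chroms=1, snps_per_chrom=100,
                        ld_block_size_bp=1, missing_rate=0.0, seed=11)
        gm = simulate_genotypes(cfg)
        kept, n = ld_prune_count(gm, window_bp=10_000_000, step=5, r2_max=0.2)
        assert n >= 0.95 * gm.n_snps

    def test_perfect_blocks_collapse_to_one_survivor(self):
        col = np.random.default_rng(12).integers(0, 3, 40)
        d = np.column_stack([col] * 5)
        gm = make_gm(d, positions=[1000, 2000, 3000, 4000, 5000])
        kept, n = ld_prune_count(gm, window_bp=100_000, step=1, r2_max=0.2)
        assert n == 1

    def test_no_surviving_pair_exceeds_threshold(self):
        """Post-hoc verification: after pruning, no pair of surviving SNPs
        within any window has r2 above the limit."""
        cfg = SimConfig(n_accessions=100, n_chroms=1, snps_per_chrom=200,
                        missing_rate=0.0, seed=13)
        gm = simulate_genotypes(cfg)
        window = 3_000_000
        kept, _ = ld_prune_count(gm, window_bp=window, step=5, r2_max=0.2)
        sub = gm.take_snps(np.flatnonzero(gm.variants["id"].isin(kept)))
        pos = sub.variants["pos"].to_numpy()
        r2 = popgen._pairwise_r2(sub.dosages)
        iu, ju = np.triu_indices(sub.n_snps, 1)
        close = np.abs(pos[ju] - pos[iu]) < window
        vals = r2[iu, ju][close]
        assert np.nanmax(vals) <= 0.2 + 1e-12


class TestThresholds:
    def test_bonferroni_printed_case(self):
        out = bonferroni_threshold(2_756_291, 0.05)
        assert out["neglog10p_display"] == 7.74
        assert out["p"] == pytest.approx(0.05 / 2_756_291)

    def test_bonferroni_identity_and_arithmetic(self):
        assert bonferroni_threshold(1, 0.05)["p"] == 0.05
        out = bonferroni_threshold(1000, 0.05)
        assert out["p"] == pytest.approx(5e-5)
        assert out["neglog10p_display"] == 4.30

    def test_permutation_quantile_one_is_max_and_below_alpha(self):
        gm, K = structured_K(60, seed=14)
        rng = np.random.default_rng(6)
        y = rng.normal(size=60)
        S = np.ones((60, 1))
        engine = ScanEngine(gm, S, K, y)
        full = permutation_threshold(gm, y, S, K, n_perm=25, quantile=1.0,
                                     seed=1, engine=engine)
        assert full["p"] == pytest.approx(full["minima"].max())
        thr = permutation_threshold(gm, y, S, K, n_perm=25, quantile=0.05,
                                    seed=1, engine=engine)
        assert thr["p"] <= 0.05

    def test_too_few_permutations_rejected(self):
        gm, K = structured_K(40, seed=15)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_threshold(gm, np.zeros(40), np.ones((40, 1)), K,
                                  n_perm=10)


class TestLoco:
    def test_loco_matches_single_k_structure(self):
        """LOCO scan returns a statistic for every polymorphic SNP and its
        per-chromosome kinships exclude the focal chromosome."""
        cfg = SimConfig(n_accessions=80, n_chroms=3, snps_per_chrom=60,
                        missing_rate=0.0, seed=16)
        gm = simulate_genotypes(cfg)
        kin = gwas.loco_kinship(gm)
        assert set(kin) == {"chr1", "chr2", "chr3"}
        manual = kinship_simple_matching(
            gm.take_snps(np.flatnonzero(gm.variants["chrom"] != "chr2"))
        ).to_numpy()
        np.testing.assert_allclose(kin["chr2"], manual)
        rng = np.random.default_rng(7)
        y = rng.normal(size=80)
        pcs, _ = popgen.pca_genotypes(gm, 3, prune_r2=None)
        S = gwas.build_covariates(pcs.to_numpy(), 3)
        res = association_scan(gm, y, S, kin, loco=True)
        assert res["p"].notna().sum() == gm.n_snps - res.attrs["n_skipped"]

    def test_single_chromosome_loco_rejected(self):
        cfg = SimConfig(n_accessions=30, n_chroms=1, snps_per_chrom=20, seed=17)
        gm = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="chromosome"):
            gwas.loco_kinship(gm)
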