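import subprocess

import numpy as np
import pandas as pd
import pytest

from spikegwas import quantgen
from spikegwas.quantgen import (PHENO_COLUMNS, RATIO_TRAITS, VarianceComponents,
                                anova_components, compute_blues, derive_traits,
                                heritability, lsd_groups)
from spikegwas.simulate import simulate_anova_observations


def long_row(values: dict, accession="a1", year=2000, rep=1) -> pd.DataFrame:
    return pd.DataFrame([
        {"accession": accession, "trait": t, "year": year, "rep": rep, "value": v}
        for t, v in values.items()
    ])


FULL_ROW = {
    "spike_length": 10.0, "spike_weight": 3.0, "grain_weight": 1.8,
    "awn_weight": 0.15, "chaff_weight": 1.0, "rachis_weight": 0.2,
    "grain_number": 60.0, "spikelet_number": 20.0, "spikelet_weight": 0.15,
    "grain_number_spikelet": 2.5, "chaff_weight_spikelet": 0.05,
    "grain_weight_spikelet": 0.09,
}


class TestDeriveTraits:
    def test_thousand_kernel_weight_formula(self):
        obs = long_row({**FULL_ROW, "grain_weight": 3.0, "grain_number": 60.0})
        out = derive_traits(obs)
        tkw = out[out["trait"] == "thousand_kernel_weight"]["value"].iloc[0]
        assert tkw == pytest.approx(50.0)  # (3 g / 60) * 1000

    def test_spikelet_density_formula(self):
        out = derive_traits(long_row(FULL_ROW))
        sd = out[out["trait"] == "spikelet_density"]["value"].iloc[0]
        assert sd == pytest.approx(2.0)  # 20 spikelets / 10 cm

    def test_full_row_matches_independent_hand_computation(self):
        out = derive_traits(long_row(FULL_ROW)).set_index("trait")["value"]
        v = FULL_ROW
        expected = {
            "thousand_kernel_weight": v["grain_weight"] / v["grain_number"] * 1000,
            "grain_number_per_chaff_weight": v["grain_number"] / v["chaff_weight"],
            "grain_weight_per_chaff_weight": v["grain_weight"] / v["chaff_weight"],
            "grain_weight_per_spike_weight": v["grain_weight"] / v["spike_weight"],
            "grain_weight_per_rachis_weight": v["grain_weight"] / v["rachis_weight"],
            "spikelet_density": v["spikelet_number"] / v["spike_length"],
            "chaff_weight_per_spike_weight": v["chaff_weight"] / v["spike_weight"],
            "awn_weight_per_spike_weight": v["awn_weight"] / v["spike_weight"],
            "awn_weight_per_grain_weight": v["awn_weight"] / v["grain_weight"],
            "awn_weight_per_chaff_weight": v["awn_weight"] / v["chaff_weight"],
            "grain_weight_per_chaff_weight_spikelet":
                v["grain_weight_spikelet"] / v["chaff_weight_spikelet"],
            "thousand_kernel_weight_spikelet":
                v["grain_weight_spikelet"] / v["grain_number_spikelet"] * 1000,
            "grain_number_per_chaff_weight_spikelet":
                v["grain_number_spikelet"] / v["chaff_weight_spikelet"],
            "grain_weight_per_spikelet_weight":
                v["grain_weight_spikelet"] / v["spikelet_weight"],
            "chaff_weight_per_spikelet_weight":
                v["chaff_weight_spikelet"] / v["spikelet_weight"],
        }
        assert len(expected) == 15
        for name, val in expected.items():
            assert out[name] == pytest.approx(val), name

    def test_panel_has_27_traits(self):
        out = derive_traits(long_row(FULL_ROW))
        assert out["trait"].nunique() == 27

    def test_zero_denominator_record_dropped_and_counted(self):
        obs = long_row({**FULL_ROW, "chaff_weight": 0.0})
        out = derive_traits(obs)
        assert "grain_weight_per_chaff_weight" not in set(out["trait"])
        assert out.attrs["n_dropped_ratio_records"] > 0

    def test_derivation_precedes_averaging(self):
        """Deriving per replicate then averaging differs from deriving on
        replicate means; the pipeline must do the former."""
        rows = pd.concat([
            long_row({**FULL_ROW, "grain_weight": 1.0, "grain_number": 20.0}, rep=1),
            long_row({**FULL_ROW, "grain_weight": 3.0, "grain_number": 100.0}, rep=2),
        ])
        out = derive_traits(rows)
        tkw = out[out["trait"] == "thousand_kernel_weight"]["value"]
        per_rep_mean = tkw.mean()                      # (50 + 30) / 2 = 40
        ratio_of_means = (1.0 + 3.0) / (20.0 + 100.0) * 1000 / 1  # 33.3
        assert per_rep_mean == pytest.approx(40.0)
        assert abs(per_rep_mean - ratio_of_means) > 1


class TestAnovaComponents:
    def test_constant_data_yields_zero_components(self):
        obs = simulate_anova_observations(5, 2, 3, 0, 0, 0, seed=0)
        obs["value"] = 7.0
        vc = anova_components(obs)
        assert vc.var_G == vc.var_GxE == vc.var_e == 0.0

    def test_noise_free_genotype_effects(self):
        obs = simulate_anova_observations(40, 2, 3, 3.0, 0.0, 0.0, seed=1)
        vc = anova_components(obs)
        geno_means = obs.groupby("accession")["value"].mean()
        assert vc.var_e == pytest.approx(0.0, abs=1e-20)
        assert vc.var_G == pytest.approx(geno_means.var(ddof=1), rel=1e-6)

    def test_sum_of_squares_conservation_balanced(self):
        obs = simulate_anova_observations(10, 2, 4, 2, 1, 3, seed=2)
        vc = anova_components(obs)
        ms, dfd = vc.mean_squares, vc.df
        parts = sum(ms[k] * dfd[k] for k in ("genotype", "year", "gxy", "error"))
        assert parts == pytest.approx(ms["ss_total"], rel=1e-9)

    def test_single_year_design_rejected(self):
        obs = simulate_anova_observations(5, 1, 3, 1, 1, 1, seed=3)
        with pytest.raises(ValueError):
            anova_components(obs)


class TestHeritability:
    def test_printed_formula_case(self):
        vc = VarianceComponents(var_G=4.0, var_GxE=2.0, var_e=5.0)
        assert heritability(vc, n_years=2, n_reps=5) == pytest.approx(
            0.7273, abs=5e-5)  # 4 / (4 + 2/2 + 5/10)

    def test_noise_free_limit_is_one(self):
        vc = VarianceComponents(var_G=3.0, var_GxE=0.0, var_e=0.0)
        assert heritability(vc, 2, 5) == 1.0

    def test_no_genetics_limit_is_zero(self):
        vc = VarianceComponents(var_G=0.0, var_GxE=1.0, var_e=1.0)
        assert heritability(vc, 2, 5) == 0.0

    @pytest.mark.parametrize("scale", [0.01, 3.7, 1200.0])
    def test_scale_invariance(self, scale):
        obs = simulate_anova_observations(20, 2, 3, 2, 1, 3, seed=4)
        h = heritability(anova_components(obs))
        obs2 = obs.assign(value=obs["value"] * scale)
        h2 = heritability(anova_components(obs2))
        assert h2 == pytest.approx(h, rel=1e-9)

    def test_all_zero_components_rejected(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents(0.0, 0.0, 0.0), 2, 5)


class TestComputeBlues:
    def test_balanced_design_blue_equals_genotype_mean(self):
        obs = simulate_anova_observations(12, 2, 3, 2, 0.5, 1, seed=5)
        blues = compute_blues(obs)
        means = obs.groupby("accession")["value"].mean()
        np.testing.assert_allclose(blues["blue"], means[blues.index])
        assert blues.attrs["method"] == "balanced-mean"

    def test_translation_equivariance_unbalanced(self):
        obs = simulate_anova_observations(8, 2, 3, 2, 0.5, 1, seed=6)
        obs = obs[~((obs["accession"] == "g0002") & (obs["year"] == 2001))]
        b1 = compute_blues(obs)["blue"]
        b2 = compute_blues(obs.assign(value=obs["value"] + 13.5))["blue"]
        np.testing.assert_allclose(b2 - b1, 13.5, rtol=1e-6)

    def test_unbalanced_blues_match_lme4_oracle(self, tmp_path):
        """Genotype-fixed, year and genotype:year random REML against an
        independent lme4 fit of the same model."""
        obs = simulate_anova_observations(8, 2, 3, 2.0, 0.5, 1.0, seed=5)
        obs = obs[~((obs["accession"] == "g0003") & (obs["year"] == 2001))]
        ours = compute_blues(obs)["blue"]
        tsv = tmp_path / "obs.tsv"
        obs.to_csv(tsv, sep="\t", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.delim("{tsv}")
d$accession <- factor(d$accession); d$year <- factor(d$year)
m <- lmer(value ~ 0 + accession + (1|year) + (1|accession:year), data=d,
          control=lmerControl(check.conv.singular="ignore"))
fe <- fixef(m)
write.csv(data.frame(acc=sub("accession", "", names(fe)), blue=fe),
          "{tmp_path}/lme4.csv", row.names=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "lme4.csv").set_index("acc")["blue"]
        np.testing.assert_allclose(ours, ref[ours.index], atol=0.05)

    def test_unbalanced_solution_is_gls_at_fitted_components(self):
        """The unbalanced fit must satisfy the explicit GLS normal
        equations beta = (X'V^-1 X)^-1 X'V^-1 y for some nonnegative
        variance components (verified by matching against a direct
        matrix-inversion GLS profiled over a component grid)."""
        obs = simulate_anova_observations(6, 2, 3, 2, 0.5, 1, seed=7)
        obs = obs[~((obs["accession"] == "g0001") & (obs["year"] == 2000))]
        ours = compute_blues(obs)["blue"]

        genos = sorted(obs["accession"].unique())
        years = sorted(obs["year"].unique())
        gi = obs["accession"].map({g: i for i, g in enumerate(genos)}).to_numpy()
        yi = obs["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
        yv = obs["value"].to_numpy(float)
        n = len(yv)
        X = np.zeros((n, len(genos)))
        X[np.arange(n), gi] = 1
        Zy = np.zeros((n, len(years)))
        Zy[np.arange(n), yi] = 1
        _, cell = np.unique(np.stack([gi, yi]), axis=1, return_inverse=True)
        Zgy = np.zeros((n, cell.max() + 1))
        Zgy[np.arange(n), cell] = 1

        def gls(vy, vgy, ve):
            V = vy * Zy @ Zy.T + vgy * Zgy @ Zgy.T + ve * np.eye(n)
            Vi = np.linalg.inv(V)
            return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ yv)

        best = np.inf
        for vy in (0.01, 0.1, 0.5, 1, 3):
            for vgy in (0.01, 0.1, 0.5, 1, 3):
                for ve in (0.1, 0.5, 1, 2):
                    dev = np.abs(gls(vy, vgy, ve) - ours.to_numpy()).max()
                    best = min(best, dev)
        assert best < 0.1


class TestLsdGroups:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 10)
        vals = pd.Series(np.concatenate([base, base]))
        grps = pd.Series(["A"] * 10 + ["B"] * 10)
        tab = lsd_groups(vals, grps)
        assert set(tab.loc["A", "letters"]) & set(tab.loc["B", "letters"])

    def test_extreme_separation_gets_distinct_letters(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(np.concatenate([rng.normal(0, 1, 10),
                                         rng.normal(100, 1, 10)]))
        grps = pd.Series(["lo"] * 10 + ["hi"] * 10)
        tab = lsd_groups(vals, grps)
        assert not (set(tab.loc["lo", "letters"]) & set(tab.loc["hi", "letters"]))

    def test_letters_match_all_pairs_t_comparisons(self):
        """Compact letters agree with exhaustive pairwise LSD decisions."""
        rng = np.random.default_rng(2)
        means = {"g1": 0.0, "g2": 0.4, "g3": 6.0}
        vals, grps = [], []
        for g, m in means.items():
            vals.extend(rng.normal(m, 1, 12))
            grps.extend([g] * 12)
        vals, grps = pd.Series(vals), pd.Series(grps)
        tab = lsd_groups(vals, grps, alpha=0.05)

        from itertools import combinations
        from scipy import stats as sps
        df = pd.DataFrame({"v": vals, "g": grps})
        k, n = 3, len(df)
        mse = df.groupby("g")["v"].apply(
            lambda v: ((v - v.mean()) ** 2).sum()).sum() / (n - k)
        tcrit = sps.t.ppf(0.975, n - k)
        for a, b in combinations(means, 2):
            va, vb = df[df.g == a]["v"], df[df.g == b]["v"]
            lsd = tcrit * np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
            significant = abs(va.mean() - vb.mean()) > lsd
            shared = bool(set(tab.loc[a, "letters"]) & set(tab.loc[b, "letters"]))
            assert shared == (not significant), (a, b)

    def test_small_group_excluded_with_warning(self):
        vals = pd.Series([1.0, 1.1, 5.0, 5.2, 9.0])
        grps = pd.Series(["A", "A", "B", "B", "C"])
        with pytest.warns(UserWarning, match="excluding"):
            tab = lsd_groups(vals, grps)
        assert "C" not in tab.index
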