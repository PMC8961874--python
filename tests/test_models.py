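"""Mixed models: REML oracles, LSMeans, Tukey letters, BIC, term retention."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gdmr import models, pheno_sim
from gdmr.models import (
    MODEL_SPECS,
    BICComparisonError,
    ModelSpec,
    ModelSpecError,
    RankDeficiencyError,
    compact_letters,
    compare_bic,
    fit_mixed,
    lsmeans,
    retain_effects,
    tukey,
    tukey_letters,
)


def _balanced_between_animal_table(rng, n_per_group=12, n_dates=2, sd=1.0):
    """Balanced one-factor design; the factor is constant within animal."""
    rows = []
    means = {"X": 10.0, "Y": 12.0, "Z": 15.0}
    for g, mu in means.items():
        for i in range(n_per_group):
            for d in range(n_dates):
                rows.append(
                    {
                        "animal": f"{g}{i}",
                        "group": g,
                        "date": f"d{d}",
                        "y": mu + sd * rng.normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestFitMixed:
    def test_balanced_cluster_constant_design_equals_ols(self, rng):
        """With the factor constant within animal and a balanced design, GLS
        and OLS coincide exactly, whatever the variance estimates."""
        table = _balanced_between_animal_table(rng)
        spec = ModelSpec("y", ("group",))
        fit = fit_mixed(table, spec)
        X = pd.get_dummies(table["group"], drop_first=True, dtype=float)
        X.insert(0, "const", 1.0)
        ols = sm.OLS(table["y"], X).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-8)

    def test_reml_matches_balanced_anova_closed_form(self, rng):
        """Balanced one-way random-effects layout: REML variance components
        have the closed form sigma_e^2 = MSW, sigma_a^2 = (MSB - MSW)/k."""
        n_animals, k = 40, 4
        sigma_a, sigma_e = 1.5, 1.0
        a = rng.normal(0, sigma_a, n_animals)
        y = a[:, None] + rng.normal(0, sigma_e, (n_animals, k)) + 50.0
        table = pd.DataFrame(
            {
                "animal": np.repeat([f"a{i}" for i in range(n_animals)], k),
                "y": y.ravel(),
            }
        )
        spec = ModelSpec("y", ())
        fit = fit_mixed(table, spec)
        group_means = y.mean(axis=1)
        msb = k * group_means.var(ddof=1)
        msw = y.var(axis=1, ddof=1).mean()
        assert fit.sigma_e2 == pytest.approx(msw, rel=1e-4)
        assert fit.sigma_a2 == pytest.approx((msb - msw) / k, rel=1e-4)

    def test_permutation_invariance(self, longitudinal_design, blood_effects, rng):
        panel = pheno_sim.simulate_blood_panel(longitudinal_design, blood_effects, 10)
        shuffled = panel.sample(frac=1.0, random_state=4).reset_index(drop=True)
        f1 = fit_mixed(panel, MODEL_SPECS["blood"])
        f2 = fit_mixed(shuffled, MODEL_SPECS["blood"])
        np.testing.assert_allclose(f1.params.to_numpy(), f2.params.to_numpy(), atol=1e-8)
        assert f1.sigma_a2 == pytest.approx(f2.sigma_a2, abs=1e-10)

    def test_rank_deficient_design_names_aliased_columns(self, longitudinal_design, blood_effects):
        panel = pheno_sim.simulate_blood_panel(longitudinal_design, blood_effects, 1)
        panel["breed2"] = panel["breed"]  # perfectly aliased factor
        spec = ModelSpec("gdmr", ("breed", "breed2"))
        with pytest.raises(RankDeficiencyError, match="breed2"):
            fit_mixed(panel, spec)

    def test_single_observation_per_subject_rejected(self):
        table = pd.DataFrame(
            {"animal": ["a", "b", "c"], "g": ["x", "y", "x"], "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ModelSpecError, match="random intercept"):
            fit_mixed(table, ModelSpec("y", ("g",)))

    def test_non_numeric_response_rejected(self):
        table = pd.DataFrame({"animal": ["a", "a"], "y": ["hi", "lo"]})
        with pytest.raises(ModelSpecError, match="numeric"):
            fit_mixed(table, ModelSpec("y", ()))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_fit_agrees_with_lme4_and_emmeans(tmp_path, longitudinal_design, blood_effects):
    """Independent oracle: lme4 REML fit + emmeans on the same panel."""
    panel = pheno_sim.simulate_blood_panel(longitudinal_design, blood_effects, 7)
    csv = tmp_path / "panel.csv"
    panel.to_csv(csv, index=False)
    script = textwrap.dedent(
        f"""
        suppressMessages({{library(lme4); library(emmeans)}})
        d <- read.csv('{csv}')
        m <- lmer(gdmr ~ date + breed + sex + (1|animal), data=d, REML=TRUE)
        em <- as.data.frame(emmeans(m, 'breed'))
        vc <- as.data.frame(VarCorr(m))
        cat(em$emmean, em$SE, vc$vcov, sep='\\n')
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    vals = [float(x) for x in out.stdout.strip().splitlines()]
    r_means, r_se, r_vc = vals[:3], vals[3:6], vals[6:8]
    fit = fit_mixed(panel, MODEL_SPECS["blood"])
    ls = lsmeans(fit, "breed").sort_values("level")  # emmeans orders levels alphabetically
    np.testing.assert_allclose(ls["lsmean"].to_numpy(), r_means, atol=1e-4)
    np.testing.assert_allclose(ls["se"].to_numpy(), r_se, atol=1e-4)
    assert fit.sigma_a2 == pytest.approx(r_vc[0], abs=1e-4)
    assert fit.sigma_e2 == pytest.approx(r_vc[1], abs=1e-4)


class TestLSMeans:
    def test_balanced_design_equals_cell_mean_average(self, rng):
        table = _balanced_between_animal_table(rng)
        fit = fit_mixed(table, ModelSpec("y", ("group", "date")))
        ls = lsmeans(fit, "group").set_index("level")
        raw = table.groupby("group")["y"].mean()
        for g in raw.index:
            assert ls.loc[g, "lsmean"] == pytest.approx(raw[g], abs=1e-8)

    def test_unbalanced_design_recovers_generator_means(self):
        """Unbalanced two-factor layout at zero noise: LSMeans recover the
        generator's level means exactly while raw means are biased."""
        rows = []
        cell = {("X", "m"): 10.0, ("X", "f"): 14.0, ("Y", "m"): 12.0, ("Y", "f"): 16.0}
        counts = {("X", "m"): 8, ("X", "f"): 2, ("Y", "m"): 2, ("Y", "f"): 8}
        for (g, s), n in counts.items():
            for i in range(n):
                aid = f"{g}{s}{i}"
                for d in range(2):
                    rows.append({"animal": aid, "group": g, "sex": s, "y": cell[(g, s)]})
        table = pd.DataFrame(rows)
        fit = fit_mixed(table, ModelSpec("y", ("group", "sex")))
        ls = lsmeans(fit, "group").set_index("level")
        assert ls.loc["X", "lsmean"] == pytest.approx(12.0, abs=1e-6)  # (10+14)/2
        assert ls.loc["Y", "lsmean"] == pytest.approx(14.0, abs=1e-6)
        raw = table.groupby("group")["y"].mean()
        assert abs(raw["X"] - 12.0) > 0.5 and abs(raw["Y"] - 14.0) > 0.5

    def test_lsmean_is_contrast_dot_coefficients(self, longitudinal_design, blood_effects):
        panel = pheno_sim.simulate_blood_panel(longitudinal_design, blood_effects, 2)
        fit = fit_mixed(panel, MODEL_SPECS["blood"])
        levels, C = models._lsmean_contrasts(fit, "sex")
        ls = lsmeans(fit, "sex")
        np.testing.assert_allclose(ls["lsmean"].to_numpy(), C @ fit.params.to_numpy())

    def test_covariate_held_at_sample_mean(self, rng):
        rows = []
        for i in range(30):
            x = rng.normal(5.0, 1.0)
            for d in range(2):
                rows.append(
                    {
                        "animal": f"a{i}",
                        "g": "A" if i % 2 else "B",
                        "x": x,
                        "y": 1.0 + 2.0 * x + (0.5 if i % 2 else -0.5) + rng.normal(0, 0.1),
                    }
                )
        table = pd.DataFrame(rows)
        fit = fit_mixed(table, ModelSpec("y", ("g",), covariates=("x",)))
        ls = lsmeans(fit, "g").set_index("level")
        beta = fit.params
        xbar = table["x"].mean()
        predicted_A = beta["Intercept"] + beta["x"] * xbar  # reference level A... or B
        # the two LSMeans must straddle the overall prediction at xbar
        overall = (ls["lsmean"].sum()) / 2
        assert overall == pytest.approx(
            beta["Intercept"] + beta.get("C(g)[T.B]", 0.0) / 2 + beta["x"] * xbar, abs=1e-8
        )
        assert fit.covariate_means["x"] == pytest.approx(xbar)
        assert predicted_A == pytest.approx(ls.loc["A", "lsmean"], abs=1e-8)


class TestTukey:
    def test_identical_levels_share_one_letter(self):
        """Zero-noise equal means: no pair significant, single shared letter."""
        rows = []
        for g in ("X", "Y", "Z"):
            for i in range(5):
                for d in range(2):
                    rows.append({"animal": f"{g}{i}", "group": g, "y": 7.0})
        fit = fit_mixed(pd.DataFrame(rows), ModelSpec("y", ("group",)))
        ls, pairs = tukey_letters(fit, "group")
        assert set(ls["letters"]) == {"a"}
        assert not pairs["significant"].any()

    def test_well_separated_means_all_distinct(self, rng):
        table = _balanced_between_animal_table(rng, n_per_group=30, sd=0.05)
        fit = fit_mixed(table, ModelSpec("y", ("group",)))
        ls, pairs = tukey_letters(fit, "group")
        assert pairs["significant"].all()
        assert sorted(ls["letters"]) == ["a", "b", "c"]
        # letters ordered by ascending mean
        assert ls.sort_values("lsmean")["letters"].tolist() == ["a", "b", "c"]

    def test_tukey_p_matches_studentized_range_reference(self, rng):
        """Cross-check one pair against scipy's studentized range directly."""
        from scipy import stats

        table = _balanced_between_animal_table(rng)
        fit = fit_mixed(table, ModelSpec("y", ("group",)))
        pairs = tukey(fit, "group")
        row = pairs.iloc[0]
        q = np.sqrt(2.0) * abs(row["diff"]) / row["se"]
        assert row["p_adj"] == pytest.approx(
            min(1.0, stats.studentized_range.sf(q, 3, fit.resid_df)), abs=1e-12
        )

    def test_compact_letter_display_known_pattern(self):
        # means ordered a < b < c; only extremes differ
        letters = compact_letters(
            ["lo", "mid", "hi"],
            {("lo", "mid"): False, ("lo", "hi"): True, ("mid", "hi"): False},
        )
        assert letters == {"lo": "a", "mid": "ab", "hi": "b"}


class TestBIC:
    def test_duplicate_fits_tie(self, longitudinal_design, blood_effects):
        panel = pheno_sim.simulate_blood_panel(longitudinal_design, blood_effects, 3)
        fit = fit_mixed(panel, MODEL_SPECS["blood"])
        ranking = compare_bic([fit, fit])
        assert ranking["bic"].iloc[0] == ranking["bic"].iloc[1]

    def test_single_fit(self, longitudinal_design, blood_effects):
        panel = pheno_sim.simulate_blood_panel(longitudinal_design, blood_effects, 3)
        fit = fit_mixed(panel, MODEL_SPECS["blood"])
        ranking = compare_bic([fit])
        assert len(ranking) == 1 and ranking["rank"].iloc[0] == 1

    def test_sas_convention_penalises_covariance_parameters_only(
        self, longitudinal_design, blood_effects
    ):
        panel = pheno_sim.simulate_blood_panel(longitudinal_design, blood_effects, 3)
        fit = fit_mixed(panel, MODEL_SPECS["blood"])
        assert fit.bic("sas") == pytest.approx(
            -2 * fit.loglik + 2 * np.log(fit.n_subjects)
        )
        assert fit.bic("all") > fit.bic("sas")  # more parameters, larger N

    def test_different_records_rejected(self, longitudinal_design, blood_effects):
        p1 = pheno_sim.simulate_blood_panel(longitudinal_design, blood_effects, 3)
        p2 = pheno_sim.simulate_blood_panel(longitudinal_design, blood_effects, 4)
        f1 = fit_mixed(p1, MODEL_SPECS["blood"])
        f2 = fit_mixed(p2, MODEL_SPECS["blood"])
        with pytest.raises(BICComparisonError):
            compare_bic([f1, f2])

    def test_differing_fixed_effects_flagged(self, longitudinal_design):
        spec = pheno_sim.preset("blood_gdmr")
        panel = pheno_sim.simulate_blood_panel(
            longitudinal_design, spec, 3, cbc_spec=pheno_sim.preset("cbc_counts")
        )
        f1 = fit_mixed(panel, MODEL_SPECS["blood"])
        f2 = fit_mixed(panel, MODEL_SPECS["blood_cbc"])
        ranking = compare_bic([f1, f2])
        assert (ranking["caveat"] == "REML-comparison").all()


class TestRetainEffects:
    def test_empty_candidates_gives_intercept_only(self, longitudinal_design, blood_effects):
        panel = pheno_sim.simulate_blood_panel(longitudinal_design, blood_effects, 0)
        spec = retain_effects(panel, "gdmr")
        assert spec.terms == ()

    def test_null_covariate_dropped_strong_factors_kept(self, longitudinal_design, rng):
        spec = pheno_sim.preset("blood_gdmr")
        panel = pheno_sim.simulate_blood_panel(longitudinal_design, spec, 6)
        panel["age"] = rng.normal(size=len(panel))  # pure noise candidate
        retained = retain_effects(
            panel, "gdmr", factors=("date", "breed", "sex"), covariates=("age",)
        )
        assert "age" not in retained.terms
        assert "breed" in retained.terms and "date" in retained.terms

    def test_main_effects_protected_by_interaction(self, slaughter_design):
        som = pheno_sim.preset("somatic_tissue")
        rep = pheno_sim.preset("reproductive_tissue")
        som.sigma_e = 1.0
        panel = pheno_sim.simulate_tissue_panel(slaughter_design, som, rep, 8)
        shared = panel[panel["tissue_class"] == "shared"]
        retained = retain_effects(
            shared,
            "gdmr",
            factors=("tissue", "sex"),
            interactions=("tissue:sex",),
        )
        # the strong cortical-kidney interaction keeps tissue:sex, which
        # protects both main effects even if sex alone is weak
        if "tissue:sex" in retained.terms:
            assert "sex" in retained.terms and "tissue" in retained.terms
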