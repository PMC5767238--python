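"""Random-intercept REML fitting, model selection, ANCOVA, correlations."""

import shutil
import subprocess
import textwrap
import warnings

import numpy as np
import pandas as pd
import pytest

from langsample import (
    ModelSpec,
    adjusted_group_means,
    correlation_matrix,
    fit_random_intercept_lmm,
    prepare_records,
    select_final_model,
    simulate_cohort_scores,
)
from langsample.simulate import SimCohortConfig, REFERENCE_BETAS


def small_cohort(seed=0, **overrides):
    cfg = SimCohortConfig(seed=seed, **overrides)
    return prepare_records(simulate_cohort_scores(cfg))


FLUENCY_SPEC = ModelSpec(
    outcome="fluency",
    fixed_terms=("intercept", "age_centered", "sex", "literacy", "dx",
                 "age_centered:dx"),
)


class TestReml:
    def test_reduces_to_ols_without_subject_variance(self):
        """With one observation per subject the intercept variance is not
        identifiable and the fit must land on the OLS solution."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 150
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "age_centered": rng.normal(0, 5, n),
            "sex_male": rng.binomial(1, 0.4, n).astype(float),
            "literacy_z": rng.normal(0, 1, n),
            "dx_emci": rng.binomial(1, 0.25, n).astype(float),
        })
        df["y"] = (
            0.2 - 0.03 * df.age_centered + 0.5 * df.sex_male
            - 0.4 * df.literacy_z - 0.3 * df.dx_emci + rng.normal(0, 0.6, n)
        )
        spec = ModelSpec(outcome="y")
        fit = fit_random_intercept_lmm(df, spec)
        X = sm.add_constant(df[["age_centered", "sex_male", "literacy_z", "dx_emci"]])
        ols = sm.OLS(df["y"], X).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-6)
        assert fit.boundary

    def test_perfectly_separated_groups_noise_free(self):
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(20)],
            "dx_emci": [0.0] * 10 + [1.0] * 10,
        })
        df["y"] = df["dx_emci"]
        fit = fit_random_intercept_lmm(
            df, ModelSpec(outcome="y", fixed_terms=("intercept", "dx"))
        )
        assert fit.params["dx"] == pytest.approx(1.0, abs=1e-9)
        assert fit.sigma2 < 1e-9

    def test_matches_statsmodels_mixedlm(self):
        """Independent cross-check of the profiled-REML solver against a
        general-purpose mixed-model optimizer."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        for seed in (10, 11, 12):
            rec = small_cohort(seed=seed)
            fit = fit_random_intercept_lmm(rec, FLUENCY_SPEC)
            from langsample.models import _build_design

            X = _build_design(rec, FLUENCY_SPEC.all_terms)
            groups = rec["subject_id"].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm_fit = MixedLM(rec["fluency"].to_numpy(), X, groups=groups).fit(
                    reml=True
                )
            assert np.allclose(fit.params.to_numpy(), sm_fit.fe_params, atol=1e-5)
            assert np.allclose(fit.se.to_numpy(), sm_fit.bse_fe, atol=1e-4)
            assert fit.tau2 == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]), abs=1e-3)
            assert fit.sigma2 == pytest.approx(float(sm_fit.scale), abs=1e-3)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_lme4(self, tmp_path):
        """Second independent oracle: lme4's REML on a small cohort."""
        rec = small_cohort(seed=21, n_ch=40, n_emci=20)
        csv = tmp_path / "rec.csv"
        rec.to_csv(csv, index=False)
        rcode = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(fluency ~ age_centered + sex_male + literacy_z + dx_emci +
                      age_centered:dx_emci + (1|subject_id), data = d, REML = TRUE)
            cat(fixef(m), sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        lme4 = np.array([float(v) for v in out.stdout.split()])
        fit = fit_random_intercept_lmm(rec, FLUENCY_SPEC)
        assert np.allclose(fit.params.to_numpy(), lme4, atol=1e-4)

    def test_rank_deficient_design_names_terms(self):
        df = pd.DataFrame({
            "subject_id": list("aabbccdd"),
            "age_centered": [0.0] * 8,
            "sex_male": [0, 0, 1, 1, 0, 0, 1, 1],
            "literacy_z": [0.1, 0.1, -0.2, -0.2, 0.3, 0.3, -0.1, -0.1],
            "dx_emci": [0, 0, 0, 0, 1, 1, 1, 1],
            "y": np.arange(8.0),
        })
        with pytest.raises(ValueError, match="age_centered"):
            fit_random_intercept_lmm(df, ModelSpec(outcome="y"))

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main effects"):
            ModelSpec(outcome="y", fixed_terms=("intercept", "age_centered:dx"))

    def test_ci_brackets_estimate(self):
        rec = small_cohort(seed=30)
        fit = fit_random_intercept_lmm(rec, FLUENCY_SPEC)
        assert (fit.ci_low <= fit.params).all()
        assert (fit.params <= fit.ci_high).all()
        assert fit.tau2 >= 0 and fit.sigma2 > 0
        assert fit.n_subjects == 264 and fit.n_obs == 528


class TestSelection:
    def test_strong_interaction_retained(self):
        betas = {f: dict(REFERENCE_BETAS[f]) for f in REFERENCE_BETAS}
        betas["fluency"]["age_centered:dx"] = -0.2  # far above detection limit
        rec = small_cohort(seed=40, betas=betas)
        sel = select_final_model(rec, "fluency", include_secondary=False)
        assert "age_centered:dx" in sel.retained_interactions
        assert "age_centered:dx" in sel.final_fit.terms

    def test_secondary_covariates_reported(self):
        rec = small_cohort(seed=41)
        sel = select_final_model(rec, "syntax")
        assert set(sel.secondary_significant) == {"cesd", "anxiety", "sleep"}
        for t in ("cesd", "anxiety", "sleep"):
            assert t in sel.secondary_fit.terms

    def test_single_visit_data_still_fits(self):
        rec = small_cohort(seed=42, visits=1)
        sel = select_final_model(rec, "lexical", include_secondary=False)
        assert sel.final_fit.boundary


class TestAdjustedMeans:
    def test_orthogonal_design_equals_raw_means(self):
        rng = np.random.default_rng(50)
        half = 60
        df = pd.DataFrame({
            "dx_emci": [0.0] * half + [1.0] * half,
            "age_centered": np.tile(rng.normal(0, 5, half), 2),
            "sex_male": np.tile(rng.binomial(1, 0.5, half).astype(float), 2),
            "literacy_z": np.tile(rng.normal(0, 1, half), 2),
        })
        df["y"] = 0.5 * df.dx_emci + rng.normal(0, 0.1, 2 * half)
        out = adjusted_group_means(df, "y")
        raw = df.groupby("dx_emci")["y"].mean()
        assert out.loc[out.group == "CH", "mean"].iloc[0] == pytest.approx(
            raw[0.0], abs=1e-6
        )
        assert out.loc[out.group == "eMCI", "mean"].iloc[0] == pytest.approx(
            raw[1.0], abs=1e-6
        )

    def test_age_confounding_removed(self):
        """An older impaired group with a purely age-driven outcome shows a
        raw difference but no adjusted difference."""
        rng = np.random.default_rng(51)
        n = 400
        dx = rng.binomial(1, 0.3, n).astype(float)
        age = rng.normal(0, 4, n) + 6 * dx
        df = pd.DataFrame({
            "dx_emci": dx, "age_centered": age,
            "sex_male": rng.binomial(1, 0.5, n).astype(float),
            "literacy_z": rng.normal(0, 1, n),
        })
        df["y"] = -0.1 * age + rng.normal(0, 0.05, n)
        raw_diff = df[df.dx_emci == 1].y.mean() - df[df.dx_emci == 0].y.mean()
        out = adjusted_group_means(df, "y")
        adj_diff = out["mean"].iloc[1] - out["mean"].iloc[0]
        assert abs(raw_diff) > 0.3
        assert abs(adj_diff) < 0.02

    def test_single_group_rejected(self):
        df = pd.DataFrame({
            "dx_emci": [0.0] * 10,
            "age_centered": np.arange(10.0),
            "sex_male": [0, 1] * 5,
            "literacy_z": np.linspace(-1, 1, 10),
            "y": np.arange(10.0),
        })
        with pytest.raises(ValueError, match="both diagnosis groups"):
            adjusted_group_means(df, "y")


class TestCorrelations:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(60)
        df = pd.DataFrame({"x": rng.normal(size=50), "y": rng.normal(size=50)})
        base = correlation_matrix(df, ["x", "y"])
        df2 = pd.DataFrame({"x": np.exp(df.x), "y": df.y**3})
        assert correlation_matrix(df2, ["x", "y"]).loc["x", "y"] == pytest.approx(
            base.loc["x", "y"]
        )

    def test_reversal(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = -df.x
        assert correlation_matrix(df, ["x", "y"]).loc["x", "y"] == pytest.approx(-1.0)

    def test_six_point_rank_formula(self):
        x = [1.0, 2, 3, 4, 5, 6]
        y = [3.0, 1, 4, 6, 5, 2]
        d = np.array([1, 2, 3, 4, 5, 6]) - np.array([3, 1, 4, 6, 5, 2])
        expected = 1 - 6 * (d**2).sum() / (6 * 35)
        df = pd.DataFrame({"x": x, "y": y})
        assert correlation_matrix(df, ["x", "y"]).loc["x", "y"] == pytest.approx(expected)

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"x": np.arange(6.0), "c": np.ones(6)})
        corr = correlation_matrix(df, ["x", "c"])
        assert np.isnan(corr.loc["x", "c"])
        assert corr.attrs["constant_variables"] == ["c"]
        assert corr.loc["x", "x"] == 1.0
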