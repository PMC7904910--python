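"""Criterion-validity modelling: correlations, stratified split,
elastic net and the adjusted-biomarker rearrangement."""

import numpy as np
import pandas as pd
import pytest

from digibench.model import (AdjustedBiomarker, PUBLISHED_ADJUSTMENT,
                             SplitSpec, correlation_matrix,
                             fit_biomarker_model, split_cohort,
                             to_adjusted_biomarker, validate_model)
from digibench.simulate import CohortParams, generate_cross_sectional


@pytest.fixture(scope="module")
def noise_free_cohort():
    return generate_cross_sectional(
        CohortParams(n_ms=2000, n_hv=0, residual_sd=0.0, seed=5))


class TestCorrelationMatrix:
    def test_diagonal_is_one(self, cross_sectional_default):
        rho, _, _ = correlation_matrix(cross_sectional_default,
                                       ["app_sdmt", "bpfr", "age"])
        assert np.allclose(np.diag(rho), 1.0)

    def test_independent_features_near_zero(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (200, 6)),
                          columns=list("abcdef"))
        rho, _, _ = correlation_matrix(df, list("abcdef"))
        off = rho.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.mean(np.abs(off) < 0.2) >= 0.95

    def test_biomarker_sign_pattern(self, cross_sectional_default):
        """App score correlates positively with brain parenchymal
        fraction and negatively with lesion load."""
        rho, p, stars = correlation_matrix(
            cross_sectional_default, ["app_sdmt", "bpfr", "t2ll"])
        assert rho.loc["app_sdmt", "bpfr"] > 0.2
        assert rho.loc["app_sdmt", "t2ll"] < -0.2
        assert stars.loc["app_sdmt", "bpfr"] != ""

    def test_all_missing_feature_flagged(self, cross_sectional_default):
        df = cross_sectional_default.copy()
        df["ghost"] = np.nan
        rho, p, _ = correlation_matrix(df, ["app_sdmt", "ghost"])
        assert np.isnan(rho.loc["app_sdmt", "ghost"])


class TestSplitCohort:
    def test_sizes_for_112(self, rng):
        df = pd.DataFrame({"age": rng.normal(55, 10, 112),
                           "app_sdmt": rng.normal(40, 12, 112)})
        train, val = split_cohort(df, SplitSpec(seed=0))
        assert len(train) + len(val) == 112
        assert 70 <= len(train) <= 78

    def test_deterministic_and_disjoint(self, cross_sectional_default):
        df = cross_sectional_default
        t1, v1 = split_cohort(df, SplitSpec(seed=3))
        t2, v2 = split_cohort(df, SplitSpec(seed=3))
        assert list(t1["subject_id"]) == list(t2["subject_id"])
        assert not set(t1["subject_id"]) & set(v1["subject_id"])
        assert len(t1) + len(v1) == len(df)

    def test_stratification_balances_age_and_score(self,
                                                   cross_sectional_default):
        df = cross_sectional_default
        gaps_age, gaps_sdmt = [], []
        for seed in range(10):
            t, v = split_cohort(df, SplitSpec(seed=seed))
            gaps_age.append(abs(t["age"].mean() - v["age"].mean())
                            / df["age"].std())
            gaps_sdmt.append(abs(t["app_sdmt"].mean() - v["app_sdmt"].mean())
                             / df["app_sdmt"].std())
        assert np.mean(gaps_age) < 0.25
        assert np.mean(gaps_sdmt) < 0.25

    def test_small_cohort_rejected(self):
        df = pd.DataFrame({"age": range(5), "app_sdmt": range(5)})
        with pytest.raises(ValueError):
            split_cohort(df, SplitSpec())


class TestFitBiomarkerModel:
    def test_noise_free_recovery_near_zero_penalty(self, noise_free_cohort):
        m = fit_biomarker_model(noise_free_cohort, alpha=1e-8)
        assert m.coefficients["bpfr"] == pytest.approx(55.5, rel=0.01)
        assert m.coefficients["t2ll"] == pytest.approx(-306.5, rel=0.01)
        assert m.coefficients["dh_taps"] == pytest.approx(0.24, rel=0.01)
        assert m.coefficients["age"] == pytest.approx(-0.16, rel=0.01)

    def test_permuted_outcome_has_no_validity(self, rng):
        df = generate_cross_sectional(CohortParams(seed=13))
        df = df.copy()
        df["app_sdmt"] = rng.permutation(df["app_sdmt"].to_numpy())
        train, val = split_cohort(df, SplitSpec(seed=1))
        m = fit_biomarker_model(train, seed=1)
        metrics = validate_model(m, val)
        assert metrics["r2"] <= 0.05

    def test_removing_taps_reduces_concordance(self,
                                               cross_sectional_default):
        train, val = split_cohort(cross_sectional_default, SplitSpec(seed=2))
        full = fit_biomarker_model(train, covariates=("dh_taps", "age"),
                                   seed=2)
        reduced = fit_biomarker_model(train, covariates=("age",), seed=2)
        ccc_full = validate_model(full, val)["ccc"]
        ccc_reduced = validate_model(reduced, val)["ccc"]
        assert ccc_reduced < ccc_full

    def test_constant_predictor_dropped(self, noise_free_cohort):
        df = noise_free_cohort.copy()
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            m = fit_biomarker_model(df, covariates=("dh_taps", "age",
                                                    "flat"), alpha=1e-8)
        assert "flat" not in m.coefficients
        assert m.dropped == ("flat",)

    def test_shrinkage_monotone_in_penalty(self, rng):
        """Single-predictor elastic net: |coefficient| non-increasing
        along increasing penalty strength."""
        df = pd.DataFrame({"bpfr": rng.uniform(0.75, 0.95, 300)})
        df["app_sdmt"] = 55.5 * df["bpfr"] + rng.normal(0, 2, 300)
        mags = []
        for a in (1e-6, 1e-3, 1e-2, 0.1, 1.0):
            m = fit_biomarker_model(df, predictors=("bpfr",), covariates=(),
                                    alpha=a)
            mags.append(abs(m.coefficients["bpfr"]))
        assert all(m2 <= m1 + 1e-9 for m1, m2 in zip(mags, mags[1:]))


class TestValidateModel:
    def test_perfect_prediction(self, noise_free_cohort):
        m = fit_biomarker_model(noise_free_cohort, alpha=1e-10)
        metrics = validate_model(m, noise_free_cohort.head(100))
        assert metrics["r2"] == pytest.approx(1.0, abs=1e-5)
        # near-identical scores can swap ranks at machine precision
        assert metrics["rho"] == pytest.approx(1.0, abs=1e-3)
        assert metrics["ccc"] == pytest.approx(1.0, abs=1e-5)

    def test_constant_prediction(self, noise_free_cohort):
        m = fit_biomarker_model(noise_free_cohort, alpha=1e-8)
        m.coefficients = {k: 0.0 for k in m.coefficients}
        metrics = validate_model(m, noise_free_cohort.head(50))
        assert metrics["r2"] <= 0.0
        assert metrics["ccc"] == pytest.approx(0.0)

    def test_metrics_match_recompute_oracle(self, cross_sectional_default):
        train, val = split_cohort(cross_sectional_default, SplitSpec(seed=4))
        m = fit_biomarker_model(train, seed=4)
        metrics = validate_model(m, val)
        sub = val[list(m.coefficients) + [m.outcome]].dropna()
        pred = m.predict(sub)
        actual = sub[m.outcome].to_numpy()
        r2 = 1 - np.sum((actual - pred) ** 2) / np.sum(
            (actual - actual.mean()) ** 2)
        assert metrics["r2"] == pytest.approx(r2, abs=1e-12)
        assert metrics["n"] == len(sub)

    def test_tiny_validation_withheld(self, noise_free_cohort):
        m = fit_biomarker_model(noise_free_cohort, alpha=1e-8)
        with pytest.raises(ValueError, match="withheld"):
            validate_model(m, noise_free_cohort.head(3))

    def test_validation_rows_never_in_training(self,
                                               cross_sectional_default):
        train, val = split_cohort(cross_sectional_default, SplitSpec(seed=7))
        assert not set(train["subject_id"]) & set(val["subject_id"])


class TestAdjustedBiomarker:
    def test_published_coefficients_example(self):
        assert PUBLISHED_ADJUSTMENT(45, 100, 50) == pytest.approx(34.9)

    def test_zero_covariates(self):
        adj = AdjustedBiomarker(taps_coef=0.0, age_coef=0.0, intercept=-5.9)
        assert adj(45, 100, 50) == pytest.approx(45 + 5.9)

    def test_model_formula_roundtrip(self, noise_free_cohort):
        """The rearranged formula reproduces the model's MRI-side
        prediction to 1e-10 (algebraic identity)."""
        m = fit_biomarker_model(noise_free_cohort, alpha=1e-8)
        adj = to_adjusted_biomarker(m)
        df = noise_free_cohort.head(200)
        via_formula = adj(m.predict(df), df["dh_taps"], df["age"])
        mri_side = (m.coefficients["bpfr"] * df["bpfr"]
                    + m.coefficients["t2ll"] * df["t2ll"])
        np.testing.assert_allclose(via_formula, mri_side, atol=1e-10)

    def test_missing_covariate_rejected(self, noise_free_cohort):
        m = fit_biomarker_model(noise_free_cohort, covariates=("age",),
                                alpha=1e-8)
        with pytest.raises(ValueError, match="covariate"):
            to_adjusted_biomarker(m)
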