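"""Scoring, covariate binning and the UTD logistic regression."""

import numpy as np
import pandas as pd
import pytest

from vaxcov.determinants import (
    REFERENCE_LEVELS,
    SeparationError,
    attitude_band,
    bin_covariates,
    caregiver_age_band,
    child_age_band,
    fit_utd_logistic,
    income_band,
    knowledge_band,
    score_attitude,
    score_knowledge,
)
from vaxcov.synthetic import GeneratorConfig, generate_utd_outcomes

from conftest import make_covariates


class TestScoring:
    @pytest.mark.parametrize("n_correct", [0, 12, 34])
    def test_knowledge_is_count_of_correct(self, n_correct):
        items = [True] * n_correct + [False] * (34 - n_correct)
        assert score_knowledge(items) == n_correct

    def test_too_many_items_rejected(self):
        with pytest.raises(ValueError):
            score_knowledge([True] * 35)

    def test_attitude_is_point_total(self):
        assert score_attitude([3, 2, 0, 5]) == 10

    def test_attitude_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_attitude([10, 10])


class TestBinning:
    @pytest.mark.parametrize(
        "score, band", [(0, "<9"), (9, "<9"), (10, "10-19"), (12, "10-19"), (20, "20-34"), (34, "20-34")]
    )
    def test_knowledge_bands(self, score, band):
        assert knowledge_band(score) == band

    @pytest.mark.parametrize("score, band", [(0, "0-7"), (7, "0-7"), (8, "8-13"), (13, "8-13")])
    def test_attitude_bands(self, score, band):
        assert attitude_band(score) == band

    @pytest.mark.parametrize(
        "yuan, band",
        [(2999, "<3000"), (3000, "3000-5000"), (5000, "3000-5000"), (5001, ">5000")],
    )
    def test_income_bands_include_lower_bound(self, yuan, band):
        assert income_band(yuan) == band

    @pytest.mark.parametrize("years, band", [(24, "<25"), (25, "25-34"), (34, "25-34"), (35, ">34")])
    def test_caregiver_age_bands(self, years, band):
        assert caregiver_age_band(years) == band

    @pytest.mark.parametrize("months, band", [(12, "12-35"), (35, "12-35"), (36, "36-59"), (59, "36-59")])
    def test_child_age_bands(self, months, band):
        assert child_age_band(months) == band

    def test_out_of_range_names_variable(self):
        with pytest.raises(ValueError, match="child_age_months"):
            child_age_band(60)
        with pytest.raises(ValueError, match="knowledge"):
            knowledge_band(40)

    def test_bin_covariates_assembles_covariate_set(self):
        cov = bin_covariates(
            caregiver_relation="mother",
            caregiver_age_years=28,
            caregiver_gender="female",
            caregiver_occupation="housewife",
            caregiver_education="middle_school",
            knowledge_score=12,
            attitude_score=8,
            family_income=3000,
            child_age_months=20,
            child_sex="male",
            hukou="guangdong",
            residence="renting_house",
            birth_place="home",
        )
        assert cov.caregiver_age_band == "25-34"
        assert cov.family_income_band == "3000-5000"
        assert cov.child_age_band == "12-35"


def _random_covariates(rng, **fixed):
    drawn = dict(
        caregiver_relation=rng.choice(["mother", "father", "other"]),
        caregiver_age_band=rng.choice(["<25", "25-34", ">34"]),
        caregiver_gender=rng.choice(["male", "female"]),
        caregiver_occupation=rng.choice(
            ["worker", "commercial_staff", "professional", "private_owner", "housewife"]
        ),
        caregiver_education=rng.choice(
            ["primary_or_below", "middle_school", "high_school_or_above"]
        ),
        knowledge_score=int(rng.integers(0, 35)),
        attitude_score=int(rng.integers(0, 14)),
        family_income_band=rng.choice(["<3000", "3000-5000", ">5000"]),
        child_age_band=rng.choice(["12-35", "36-59"]),
        child_sex=rng.choice(["male", "female"]),
        hukou=rng.choice(["guangdong", "outside"]),
        residence=rng.choice(["purchased_house", "renting_house"]),
        birth_place=rng.choice(
            ["county_hospital_or_above", "town_clinic", "village_clinic", "home"]
        ),
    )
    drawn.update(fixed)
    return make_covariates(**drawn)


def _two_by_two_frame():
    # exposed: 40 UTD / 10 not; unexposed: 20 UTD / 30 not -> OR = 6.0
    rows = (
        [{"exposed": "yes", "utd": True}] * 40
        + [{"exposed": "yes", "utd": False}] * 10
        + [{"exposed": "no", "utd": True}] * 20
        + [{"exposed": "no", "utd": False}] * 30
    )
    return pd.DataFrame(rows)


class TestLogisticFit:
    def test_single_binary_predictor_matches_cross_product_ratio(self):
        result = fit_utd_logistic(_two_by_two_frame())
        row = result.level("exposed", "yes")
        assert row["odds_ratio"] == pytest.approx(6.0, rel=1e-6)
        # Wald CI equals exp(beta +/- 1.96*se) with se from cell counts
        se = np.sqrt(1 / 40 + 1 / 10 + 1 / 20 + 1 / 30)
        assert row["ci_low"] == pytest.approx(6.0 * np.exp(-1.959963985 * se), rel=1e-4)
        assert row["ci_high"] == pytest.approx(6.0 * np.exp(1.959963985 * se), rel=1e-4)

    def test_reference_rows_are_exactly_one_with_no_ci(self):
        result = fit_utd_logistic(_two_by_two_frame())
        ref = result.level("exposed", "no")
        assert ref["reference"]
        assert ref["odds_ratio"] == 1.0
        assert pd.isna(ref["ci_low"]) and pd.isna(ref["p_value"])

    def test_per_level_n_sums_to_cohort_size(self):
        result = fit_utd_logistic(_two_by_two_frame())
        assert result.table.groupby("variable")["n"].sum().eq(100).all()

    def test_single_outcome_class_rejected(self):
        df = _two_by_two_frame()
        df["utd"] = True
        with pytest.raises(SeparationError, match="single class"):
            fit_utd_logistic(df)

    def test_complete_separation_rejected(self):
        df = pd.DataFrame(
            {"exposed": ["yes"] * 30 + ["no"] * 30, "utd": [True] * 30 + [False] * 30}
        )
        with pytest.raises(SeparationError):
            fit_utd_logistic(df)

    def test_unobserved_declared_level_named(self):
        rng = np.random.default_rng(3)
        pairs = [
            (_random_covariates(rng, caregiver_occupation="worker"), bool(rng.random() < 0.6))
            for _ in range(200)
        ]
        with pytest.raises(SeparationError, match="caregiver_occupation"):
            fit_utd_logistic(pairs)

    def test_covariate_set_pairs_use_table_reference_levels(self):
        rng = np.random.default_rng(7)
        pairs = [
            (_random_covariates(rng), bool(rng.random() < 0.6)) for _ in range(300)
        ]
        result = fit_utd_logistic(pairs)
        for variable, ref_level in REFERENCE_LEVELS.items():
            ref = result.level(variable, ref_level)
            assert ref["reference"] and ref["odds_ratio"] == 1.0
        assert result.table.groupby("variable")["n"].sum().eq(300).all()

    def test_recovers_configured_true_odds_ratio(self):
        config = GeneratorConfig(
            seed=11,
            covariate_marginals={"hukou": {"guangdong": 0.4, "outside": 0.6}},
            true_or={"hukou": {"guangdong": 2.0}},
            baseline_utd_probability=0.5,
        )
        df = generate_utd_outcomes(config, n=20_000)
        result = fit_utd_logistic(df[["hukou", "utd"]])
        row = result.level("hukou", "guangdong")
        assert row["odds_ratio"] == pytest.approx(2.0, rel=0.10)
        assert row["ci_low"] < 2.0 < row["ci_high"]

    def test_display_rounding_of_p_values(self, tmp_path):
        result = fit_utd_logistic(_two_by_two_frame())
        out = tmp_path / "table.csv"
        result.to_csv(out)
        row = pd.read_csv(out, dtype=str).set_index("level").loc["yes"]
        assert row["p_value"] == "0.000"  # p < 0.0005 renders as 0.000
        assert row["odds_ratio"] == "6.00"
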