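"""Dose/series timeliness classification and the coverage decomposition."""

import datetime as dt

import pytest

from vaxcov.records import DoseEvent, reconcile
from vaxcov.schedule import default_schedule
from vaxcov.timeliness import (
    COMPOSITE_LABEL,
    CoverageTable,
    Dose,
    SeriesTimeliness,
    classify_composite,
    classify_dose,
    classify_series,
    coverage_table,
    dose_coverage_gap,
)

from conftest import APPROPRIATE_AGES, BIRTH, make_child, split_label


def _event(label, age_days):
    antigen, number = split_label(label)
    date = BIRTH + dt.timedelta(days=age_days) if age_days is not None else None
    return DoseEvent(antigen, number, date)


def _classify(label, age_days, prev_age_days=None, schedule=None):
    schedule = schedule or default_schedule()
    antigen, number = split_label(label)
    rule = schedule.get(antigen).rule(number)
    prev = None
    if number > 1:
        prev = _event(f"{antigen}{number - 1}", prev_age_days)
    return classify_dose(_event(label, age_days), prev, rule, BIRTH)


class TestClassifyDose:
    @pytest.mark.parametrize(
        "age, expected",
        [
            (100, Dose.AGE_APPROPRIATE),
            (89, Dose.AGE_APPROPRIATE),  # inclusive lower bound
            (122, Dose.AGE_APPROPRIATE),  # inclusive upper bound
            (88, Dose.AGE_INVALID),
            (123, Dose.AGE_DELAYED),
        ],
    )
    def test_dpt1_age_window(self, age, expected):
        assert _classify("DPT1", age) is expected

    @pytest.mark.parametrize(
        "gap, expected",
        [
            (27, Dose.INTERVAL_INVALID),
            (28, Dose.INTERVAL_APPROPRIATE),
            (61, Dose.INTERVAL_APPROPRIATE),
            (62, Dose.INTERVAL_DELAYED),
        ],
    )
    def test_hepb2_interval_window(self, gap, expected):
        assert _classify("HepB2", 0 + gap, prev_age_days=0) is expected

    def test_missing_event_not_received(self):
        assert _classify("MCV1", None) is Dose.NOT_RECEIVED

    def test_negative_interval_is_invalid(self):
        assert _classify("OPV2", 60, prev_age_days=90) is Dose.INTERVAL_INVALID

    def test_orphan_later_dose_is_interval_invalid(self):
        assert _classify("OPV3", 120, prev_age_days=None) is Dose.INTERVAL_INVALID

    def test_antigen_mismatch_raises(self, schedule):
        rule = schedule.get("DPT").rule(1)
        with pytest.raises(ValueError, match="DPT"):
            classify_dose(_event("OPV1", 60), None, rule, BIRTH)

    def test_oracle_equivalence_all_rules(self, schedule):
        """Exhaustive agreement with a direct window-lookup oracle.

        Every age 0-600 days for first doses and every gap 0-400 days for
        later doses, across all 11 dose rules; also checks that exactly one
        category applies to every received dose.
        """
        for series in schedule.series:
            for rule in series.rules:
                low, high = rule.window_low_days, rule.window_high_days
                if rule.dose_number == 1:
                    for age in range(601):
                        expected = (
                            Dose.AGE_INVALID
                            if age < low
                            else Dose.AGE_APPROPRIATE
                            if age <= high
                            else Dose.AGE_DELAYED
                        )
                        got = _classify(rule.label, age, schedule=schedule)
                        assert got is expected, (rule.label, age)
                        assert got.invalid + got.appropriate + got.delayed == 1
                else:
                    for gap in range(401):
                        expected = (
                            Dose.INTERVAL_INVALID
                            if gap < low
                            else Dose.INTERVAL_APPROPRIATE
                            if gap <= high
                            else Dose.INTERVAL_DELAYED
                        )
                        got = _classify(
                            rule.label, 100 + gap, prev_age_days=100, schedule=schedule
                        )
                        assert got is expected, (rule.label, gap)
                        assert got.invalid + got.appropriate + got.delayed == 1


def _series_cls(ages, antigen, schedule):
    child = make_child(ages=ages)
    return classify_series(reconcile(child), schedule.get(antigen), BIRTH)


class TestClassifySeries:
    def test_bcg_at_birth_age_appropriate(self, schedule):
        out = _series_cls({"BCG1": 0}, "BCG", schedule)
        assert out.utd and out.timeliness is SeriesTimeliness.AGE_APPROPRIATE

    def test_opv_all_windows_satisfied(self, schedule):
        out = _series_cls({"OPV1": 70, "OPV2": 100, "OPV3": 130}, "OPV", schedule)
        assert out.timeliness is SeriesTimeliness.AGE_APPROPRIATE

    def test_late_first_dose_makes_series_delayed(self, schedule):
        out = _series_cls({"DPT1": 150, "DPT2": 180, "DPT3": 210}, "DPT", schedule)
        assert out.utd and out.timeliness is SeriesTimeliness.DELAYED

    def test_invalid_dose_beats_delay(self, schedule):
        # dose 2 too early (invalid), dose 3 late (delayed): invalid wins
        out = _series_cls({"DPT1": 150, "DPT2": 160, "DPT3": 260}, "DPT", schedule)
        assert out.timeliness is SeriesTimeliness.INVALID

    def test_missing_dose_incomplete(self, schedule):
        out = _series_cls({"DPT1": 90, "DPT2": 120}, "DPT", schedule)
        assert not out.utd and out.timeliness is SeriesTimeliness.INCOMPLETE


class TestClassifyComposite:
    def test_all_series_appropriate(self, schedule):
        child = make_child()
        out = classify_composite(reconcile(child), schedule, BIRTH)
        assert out.utd and out.timeliness is SeriesTimeliness.AGE_APPROPRIATE

    def test_one_delayed_series_makes_composite_delayed(self, schedule):
        ages = dict(APPROPRIATE_AGES, MCV1=300)
        out = classify_composite(reconcile(make_child(ages=ages)), schedule, BIRTH)
        assert out.utd and out.timeliness is SeriesTimeliness.DELAYED

    def test_missing_hepb3_incomplete(self, schedule):
        ages = {k: v for k, v in APPROPRIATE_AGES.items() if k != "HepB3"}
        out = classify_composite(reconcile(make_child(ages=ages)), schedule, BIRTH)
        assert not out.utd and out.timeliness is SeriesTimeliness.INCOMPLETE


class TestCoverageTable:
    def test_hand_enumerated_four_child_cohort(self, schedule):
        children = [
            make_child("a"),
            make_child("b"),
            make_child("c", ages=dict(APPROPRIATE_AGES, MCV1=300)),  # delayed-complete
            make_child("d", certificate=False, card=False),  # recordless
        ]
        table = coverage_table(children, schedule)
        row = table.row(COMPOSITE_LABEL)
        assert row["coverage"] == 75.0
        assert row["age_appropriate"] == 50.0
        assert row["delayed"] == 25.0
        assert row["invalid"] == 0.0

    def test_fully_appropriate_cohort_is_100_everywhere(self, schedule):
        table = coverage_table([make_child(str(i)) for i in range(5)], schedule)
        frame = table.to_frame(None)
        assert (frame["coverage"] == 100.0).all()
        assert (frame["age_appropriate"] == 100.0).all()

    def test_recordless_child_counts_in_denominator(self, schedule):
        table = coverage_table(
            [make_child("a"), make_child("b", certificate=False, card=False)], schedule
        )
        assert table.denominator == 2
        assert (table.to_frame(None)["coverage"] == 50.0).all()

    def test_additivity_exact_before_rounding(self, schedule):
        children = [
            make_child("a"),
            make_child("b", ages={"BCG1": 5, "OPV1": 60, "OPV2": 70, "MCV1": 250}),
            make_child("c", ages=dict(APPROPRIATE_AGES, DPT3=400)),
            make_child("d", certificate=False, card=False),
        ]
        frame = coverage_table(children, schedule).to_frame(None)
        residual = frame["coverage"] - (
            frame["invalid"] + frame["age_appropriate"] + frame["delayed"]
        )
        assert residual.abs().max() == 0.0

    def test_empty_cohort_rejected(self, schedule):
        with pytest.raises(ValueError):
            coverage_table([], schedule)

    def test_rounding_is_half_up_to_one_decimal(self, schedule):
        # 7 of 8 children covered -> 87.5 exactly at one decimal
        children = [make_child(str(i)) for i in range(7)] + [
            make_child("x", certificate=False, card=False)
        ]
        frame = coverage_table(children, schedule).to_frame()
        assert frame.loc["BCG1", "coverage"] == 87.5


class TestCoverageGap:
    def test_gap_from_published_style_rows(self):
        table = CoverageTable.from_percentages(
            {
                "HepB1": {"coverage": 76.7},
                "HepB2": {"coverage": 75.8},
                "HepB3": {"coverage": 71.5},
            },
            1530,
        )
        assert dose_coverage_gap(table, "HepB") == pytest.approx(5.2)

    def test_no_dropout_zero_gap(self, schedule):
        table = coverage_table([make_child()], schedule)
        assert dose_coverage_gap(table, "OPV") == 0.0

    def test_single_dose_antigen_rejected(self, schedule):
        table = coverage_table([make_child()], schedule)
        with pytest.raises(ValueError, match="BCG"):
            dose_coverage_gap(table, "BCG")
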