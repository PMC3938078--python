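"""Timeliness classification of doses and series, and coverage tabulation.

Every *received* dose falls in exactly one of three mutually exclusive
timeliness categories, measured against its schedule window:

* invalid — given before the window minimum (age-invalid for first doses,
  interval-invalid for later doses): not a valid immunization;
* appropriate — given inside the closed window;
* delayed — given after the window maximum.

A series is **UTD** (up-to-date) when every required dose has a date,
regardless of timing. Among UTD series the timeliness is INVALID if any
dose was invalid, AGE_APPROPRIATE if the first dose was age-appropriate and
every later dose interval-appropriate, and DELAYED otherwise. Coverage of a
dose equals the share of surveyed children with a dated record of it, so
per row: coverage = invalid + appropriate + delayed (exactly, pre-rounding).
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._util import round_half_up
from .records import ChildRecord, DoseEvent, ReconciledHistory, reconcile
from .schedule import DoseRule, VaccineSchedule, VaccineSeries

log = logging.getLogger(__name__)

__all__ = [
    "Dose",
    "SeriesTimeliness",
    "SeriesClassification",
    "CoverageTable",
    "COMPOSITE_LABEL",
    "classify_dose",
    "classify_series",
    "classify_composite",
    "classify_cohort",
    "coverage_table",
    "dose_coverage_gap",
]

COMPOSITE_LABEL = "1:3:3:3:1"


class Dose(enum.Enum):
    """Dose-level timeliness category.

    First doses take the AGE_* values, later doses the INTERVAL_* values.
    """

    NOT_RECEIVED = "not_received"
    AGE_INVALID = "age_invalid"
    INTERVAL_INVALID = "interval_invalid"
    AGE_APPROPRIATE = "age_appropriate"
    AGE_DELAYED = "age_delayed"
    INTERVAL_APPROPRIATE = "interval_appropriate"
    INTERVAL_DELAYED = "interval_delayed"

    @property
    def received(self) -> bool:
        return self is not Dose.NOT_RECEIVED

    @property
    def invalid(self) -> bool:
        return self in (Dose.AGE_INVALID, Dose.INTERVAL_INVALID)

    @property
    def appropriate(self) -> bool:
        return self in (Dose.AGE_APPROPRIATE, Dose.INTERVAL_APPROPRIATE)

    @property
    def delayed(self) -> bool:
        return self in (Dose.AGE_DELAYED, Dose.INTERVAL_DELAYED)


class SeriesTimeliness(enum.Enum):
    INCOMPLETE = "incomplete"
    INVALID = "invalid"
    AGE_APPROPRIATE = "age_appropriate"
    DELAYED = "delayed"


@dataclass(frozen=True)
class SeriesClassification:
    """UTD status and exclusive timeliness category of one (or the composite) series."""

    utd: bool
    timeliness: SeriesTimeliness

    def __post_init__(self):
        if self.utd == (self.timeliness is SeriesTimeliness.INCOMPLETE):
            raise ValueError("utd=False iff timeliness=INCOMPLETE")


def classify_dose(
    event: Optional[DoseEvent],
    previous_event: Optional[DoseEvent],
    rule: DoseRule,
    birth_date: dt.date,
) -> Dose:
    """Classify a single dose against its schedule window.

    First doses are measured as age in days (day of birth = day 0); later
    doses as the gap in days from the immediately preceding dose of the same
    antigen. Windows are closed. An undated/absent event is NOT_RECEIVED. A
    dated later dose whose predecessor is unreceived has an undefined
    interval and is classified INTERVAL_INVALID (and logged); a negative
    gap (out-of-order dates) likewise falls below the minimum.
    """
    if event is not None and event.antigen != rule.antigen:
        raise ValueError(
            f"rule is for {rule.antigen} dose {rule.dose_number}, "
            f"event is {event.label}"
        )
    if event is None or event.date is None:
        return Dose.NOT_RECEIVED
    if rule.dose_number == 1:
        age = (event.date - birth_date).days
        if age < rule.window_low_days:
            return Dose.AGE_INVALID
        if age > rule.window_high_days:
            return Dose.AGE_DELAYED
        return Dose.AGE_APPROPRIATE
    if previous_event is None or previous_event.date is None:
        log.warning(
            "%s dated %s without a dated preceding dose: interval undefined, "
            "classified interval-invalid",
            event.label,
            event.date,
        )
        return Dose.INTERVAL_INVALID
    gap = (event.date - previous_event.date).days
    if gap < 0:
        log.warning(
            "%s dated %s before its preceding dose (%s): out-of-order record",
            event.label,
            event.date,
            previous_event.date,
        )
    if gap < rule.window_low_days:
        return Dose.INTERVAL_INVALID
    if gap > rule.window_high_days:
        return Dose.INTERVAL_DELAYED
    return Dose.INTERVAL_APPROPRIATE


def _classify_series_doses(
    history: ReconciledHistory, series: VaccineSeries, birth_date: dt.date
) -> list[Dose]:
    out = []
    previous = None
    for rule in series.rules:
        event = history.dated(series.antigen, rule.dose_number)
        out.append(classify_dose(event, previous, rule, birth_date))
        previous = event
    return out


def _series_outcome(dose_classes: Sequence[Dose]) -> SeriesClassification:
    if any(not c.received for c in dose_classes):
        return SeriesClassification(False, SeriesTimeliness.INCOMPLETE)
    if any(c.invalid for c in dose_classes):
        return SeriesClassification(True, SeriesTimeliness.INVALID)
    if all(c.appropriate for c in dose_classes):
        return SeriesClassification(True, SeriesTimeliness.AGE_APPROPRIATE)
    return SeriesClassification(True, SeriesTimeliness.DELAYED)


def classify_series(
    history: ReconciledHistory, series: VaccineSeries, birth_date: dt.date
) -> SeriesClassification:
    """Classify one antigen series for one child (UTD + timeliness)."""
    return _series_outcome(_classify_series_doses(history, series, birth_date))


def classify_composite(
    history: ReconciledHistory, schedule: VaccineSchedule, birth_date: dt.date
) -> SeriesClassification:
    """Classify the composite (1:3:3:3:1) series.

    UTD requires every constituent series UTD; the composite is INVALID if
    any constituent is INVALID, AGE_APPROPRIATE only if all are, and DELAYED
    otherwise.
    """
    results = []
    for antigen, k in schedule.series_spec.items():
        series = schedule.get(antigen)
        if k < series.n_doses:
            series = VaccineSeries(antigen, series.rules[:k])
        results.append(classify_series(history, series, birth_date))
    if not all(r.utd for r in results):
        return SeriesClassification(False, SeriesTimeliness.INCOMPLETE)
    cats = [r.timeliness for r in results]
    if SeriesTimeliness.INVALID in cats:
        return SeriesClassification(True, SeriesTimeliness.INVALID)
    if all(c is SeriesTimeliness.AGE_APPROPRIATE for c in cats):
        return SeriesClassification(True, SeriesTimeliness.AGE_APPROPRIATE)
    return SeriesClassification(True, SeriesTimeliness.DELAYED)


def classify_cohort(
    children: Iterable[ChildRecord], schedule: VaccineSchedule
) -> pd.DataFrame:
    """Per-child, per-dose (plus composite) classification, long format.

    Columns: child_id, label, category — one row per schedule dose per child
    and one composite row per child; children without any written record
    contribute NOT_RECEIVED / INCOMPLETE rows.
    """
    rows = []
    for rec in children:
        history = reconcile(rec)
        for series in schedule.series:
            for rule, cls in zip(
                series.rules, _classify_series_doses(history, series, rec.birth_date)
            ):
                rows.append((rec.child_id, rule.label, cls.value))
        comp = classify_composite(history, schedule, rec.birth_date)
        rows.append((rec.child_id, COMPOSITE_LABEL, comp.timeliness.value))
    return pd.DataFrame(rows, columns=["child_id", "label", "category"])


_TABLE_COLUMNS = (
    "coverage",
    "invalid",
    "age_invalid",
    "interval_invalid",
    "age_appropriate",
    "delayed",
    "age_delayed",
    "interval_delayed",
)


@dataclass(frozen=True)
class CoverageTable:
    """Coverage decomposition per dose and for the composite series.

    ``data`` holds full-precision percentages of the surveyed denominator,
    one row per dose label plus the composite row; per row
    invalid + age_appropriate + delayed = coverage exactly. Display methods
    round to one decimal, half-up.
    """

    data: pd.DataFrame
    denominator: int

    def row(self, label: str) -> pd.Series:
        if label not in self.data.index:
            raise KeyError(f"no coverage row {label!r}")
        return self.data.loc[label]

    @classmethod
    def from_percentages(
        cls, rows: dict[str, dict[str, float]], denominator: int
    ) -> "CoverageTable":
        """Build a table from already-tabulated percentages.

        Each row dict may give any of the sub-kind columns; the aggregate
        ``invalid``/``delayed``/``coverage`` columns are derived when absent
        (coverage = invalid + age_appropriate + delayed).
        """
        df = pd.DataFrame.from_dict(rows, orient="index").reindex(
            columns=list(_TABLE_COLUMNS)
        )
        for agg, parts in (
            ("invalid", ("age_invalid", "interval_invalid")),
            ("delayed", ("age_delayed", "interval_delayed")),
        ):
            derived = df[list(parts)].sum(axis=1, min_count=1)
            df[agg] = df[agg].fillna(derived)
        df["coverage"] = df["coverage"].fillna(
            df[["invalid", "age_appropriate", "delayed"]].sum(axis=1)
        )
        return cls(df.fillna(0.0), denominator)

    def to_frame(self, decimals: int | None = 1) -> pd.DataFrame:
        if decimals is None:
            return self.data.copy()
        return self.data.map(lambda v: round_half_up(v, decimals))

    def to_csv(self, path: str | Path, decimals: int | None = 1) -> None:
        out = self.to_frame(decimals)
        out.index.name = "label"
        out.to_csv(path)


def coverage_table(
    children: Sequence[ChildRecord], schedule: VaccineSchedule
) -> CoverageTable:
    """Tabulate the coverage decomposition for a surveyed cohort.

    The denominator is every surveyed child, including those with no written
    record (regarded as unvaccinated, NOT_RECEIVED throughout). One row per
    schedule dose and one for the composite series; percentages at full
    precision (round on export).
    """
    children = list(children)
    if not children:
        raise ValueError("coverage_table requires a nonempty cohort")
    n = len(children)
    long = classify_cohort(children, schedule)
    counts = (
        long.groupby(["label", "category"]).size().unstack(fill_value=0)
    )

    labels = list(schedule.dose_labels) + [COMPOSITE_LABEL]
    rows = {}
    for label in labels:
        c = counts.loc[label] if label in counts.index else pd.Series(dtype=int)

        def pct(*cats) -> float:
            return 100.0 * sum(int(c.get(k, 0)) for k in cats) / n

        if label == COMPOSITE_LABEL:
            row = {
                "invalid": pct("invalid"),
                "age_invalid": pct("invalid"),
                "interval_invalid": 0.0,
                "age_appropriate": pct("age_appropriate"),
                "delayed": pct("delayed"),
                "age_delayed": pct("delayed"),
                "interval_delayed": 0.0,
            }
        else:
            row = {
                "age_invalid": pct("age_invalid"),
                "interval_invalid": pct("interval_invalid"),
                "invalid": pct("age_invalid", "interval_invalid"),
                "age_appropriate": pct("age_appropriate", "interval_appropriate"),
                "age_delayed": pct("age_delayed"),
                "interval_delayed": pct("interval_delayed"),
                "delayed": pct("age_delayed", "interval_delayed"),
            }
        row["coverage"] = row["invalid"] + row["age_appropriate"] + row["delayed"]
        rows[label] = row
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(_TABLE_COLUMNS)
    )
    return CoverageTable(df, n)


def dose_coverage_gap(table: CoverageTable, antigen: str) -> float:
    """Coverage drop from dose 1 to dose 3 of a multi-dose antigen, in points."""
    first, third = f"{antigen}1", f"{antigen}3"
    if third not in table.data.index:
        raise ValueError(f"{antigen} has fewer than 3 doses in this table")
    return float(table.data.loc[first, "coverage"] - table.data.loc[third, "coverage"])
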