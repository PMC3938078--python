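"""Immunization schedules: acceptable-age and acceptable-interval windows.

A schedule is a set of antigen series. Dose 1 of each series carries an
acceptable *age* window (days since birth, day of birth = day 0); every
later dose carries an acceptable *interval* window measured from the
immediately preceding dose of the same antigen. All windows are closed
intervals, inclusive at both bounds.

The default schedule is the Chinese EPI primary series in force in
Guangdong in 2011: one BCG, three HepB, three OPV, three DPT and one MCV
dose — the "1:3:3:3:1" composite series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "DoseRule",
    "VaccineSeries",
    "VaccineSchedule",
    "ScheduleError",
    "default_schedule",
    "load_schedule",
    "save_schedule",
    "FIRST_DOSE_AGE",
    "INTERDOSE_INTERVAL",
]

FIRST_DOSE_AGE = "first_dose_age"
INTERDOSE_INTERVAL = "interdose_interval"


class ScheduleError(ValueError):
    """A schedule violates its structural invariants."""


@dataclass(frozen=True)
class DoseRule:
    """Acceptable-timing window for one dose of one antigen.

    ``window_low_days``/``window_high_days`` bound either the age at dose 1
    (``window_kind == "first_dose_age"``) or the gap from the previous dose
    (``window_kind == "interdose_interval"``), both inclusive.
    """

    antigen: str
    dose_number: int
    recommended_age_months: float
    window_low_days: int
    window_high_days: int
    window_kind: str = ""

    def __post_init__(self):
        if not self.window_kind:
            object.__setattr__(
                self,
                "window_kind",
                FIRST_DOSE_AGE if self.dose_number == 1 else INTERDOSE_INTERVAL,
            )
        if self.dose_number < 1:
            raise ScheduleError(f"{self.antigen}: dose_number must be >= 1")
        if self.window_low_days < 0 or self.window_high_days < 0:
            raise ScheduleError(
                f"{self.antigen} dose {self.dose_number}: negative window bound"
            )
        if self.window_low_days > self.window_high_days:
            raise ScheduleError(
                f"{self.antigen} dose {self.dose_number}: window low "
                f"{self.window_low_days} > high {self.window_high_days}"
            )
        expected = FIRST_DOSE_AGE if self.dose_number == 1 else INTERDOSE_INTERVAL
        if self.window_kind != expected:
            raise ScheduleError(
                f"{self.antigen} dose {self.dose_number}: window_kind "
                f"{self.window_kind!r}, expected {expected!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.antigen}{self.dose_number}"


@dataclass(frozen=True)
class VaccineSeries:
    """All dose rules for one antigen, ordered by dose number (1..k)."""

    antigen: str
    rules: tuple[DoseRule, ...]

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        numbers = [r.dose_number for r in self.rules]
        if numbers != list(range(1, len(numbers) + 1)):
            if len(set(numbers)) != len(numbers):
                raise ScheduleError(f"{self.antigen}: duplicate dose numbers {numbers}")
            if 1 not in numbers:
                raise ScheduleError(f"{self.antigen}: missing dose 1")
            raise ScheduleError(
                f"{self.antigen}: dose numbers {numbers} are not consecutive from 1"
            )
        for r in self.rules:
            if r.antigen != self.antigen:
                raise ScheduleError(
                    f"series {self.antigen} contains rule for {r.antigen}"
                )

    @property
    def n_doses(self) -> int:
        return len(self.rules)

    def rule(self, dose_number: int) -> DoseRule:
        try:
            return self.rules[dose_number - 1]
        except IndexError:
            raise ScheduleError(
                f"{self.antigen} has no dose {dose_number}"
            ) from None


@dataclass(frozen=True)
class VaccineSchedule:
    """A set of antigen series plus the composite-series dose requirement.

    ``series_spec`` maps antigen -> number of doses required for the
    composite ("1:3:3:3:1") up-to-date definition; by default every listed
    series is required in full.
    """

    series: tuple[VaccineSeries, ...]
    series_spec: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "series", tuple(self.series))
        names = [s.antigen for s in self.series]
        if len(set(names)) != len(names):
            raise ScheduleError(f"duplicate antigen series: {names}")
        if not self.series_spec:
            object.__setattr__(
                self, "series_spec", {s.antigen: s.n_doses for s in self.series}
            )
        spec = dict(self.series_spec)
        for antigen, k in spec.items():
            s = self.get(antigen)
            if k < 1 or k > s.n_doses:
                raise ScheduleError(
                    f"series_spec requires {k} doses of {antigen}, "
                    f"schedule defines {s.n_doses}"
                )
        object.__setattr__(self, "series_spec", spec)

    def get(self, antigen: str) -> VaccineSeries:
        for s in self.series:
            if s.antigen == antigen:
                return s
        raise ScheduleError(f"no series for antigen {antigen!r}")

    @property
    def antigens(self) -> tuple[str, ...]:
        return tuple(s.antigen for s in self.series)

    @property
    def dose_labels(self) -> tuple[str, ...]:
        """All dose labels in schedule order, e.g. BCG1, HepB1, HepB2, ..."""
        return tuple(r.label for s in self.series for r in s.rules)

    @property
    def total_required_doses(self) -> int:
        return sum(self.series_spec.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "antigen": r.antigen,
                "dose_number": r.dose_number,
                "recommended_age_months": r.recommended_age_months,
                "window_low_days": r.window_low_days,
                "window_high_days": r.window_high_days,
            }
            for s in self.series
            for r in s.rules
        ]
        return pd.DataFrame(rows)


# Guangdong 2011 EPI primary schedule. Recommended ages in months; windows in
# days: dose-1 rows are acceptable ages, later rows acceptable gaps from the
# preceding dose.
_DEFAULT_ROWS: Sequence[tuple[str, int, float, int, int]] = (
    ("BCG", 1, 0, 0, 1),
    ("HepB", 1, 0, 0, 1),
    ("HepB", 2, 1, 28, 61),
    ("HepB", 3, 6, 59, 183),
    ("OPV", 1, 2, 59, 91),
    ("OPV", 2, 3, 28, 61),
    ("OPV", 3, 4, 28, 61),
    ("DPT", 1, 3, 89, 122),
    ("DPT", 2, 4, 28, 61),
    ("DPT", 3, 5, 28, 61),
    ("MCV", 1, 8, 242, 274),
)


def default_schedule() -> VaccineSchedule:
    """The 2011 Guangdong EPI schedule (1 BCG, 3 HepB, 3 OPV, 3 DPT, 1 MCV).

    Returns a fresh immutable schedule on every call.
    """
    return _schedule_from_rows(_DEFAULT_ROWS)


def _schedule_from_rows(rows) -> VaccineSchedule:
    by_antigen: dict[str, list[DoseRule]] = {}
    for antigen, dose, rec, low, high in rows:
        by_antigen.setdefault(str(antigen), []).append(
            DoseRule(str(antigen), int(dose), float(rec), int(low), int(high))
        )
    series = tuple(
        VaccineSeries(a, tuple(sorted(rules, key=lambda r: r.dose_number)))
        for a, rules in by_antigen.items()
    )
    return VaccineSchedule(series)


def load_schedule(path: str | Path) -> VaccineSchedule:
    """Load a schedule from a flat CSV or a YAML file.

    Both encodings carry one record per dose rule with fields ``antigen``,
    ``dose_number``, ``recommended_age_months``, ``window_low_days``,
    ``window_high_days``. Unknown antigens are allowed. Structural problems
    (inverted windows, duplicate or missing dose numbers) raise
    :class:`ScheduleError` naming the offending rule.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        rules = data["rules"] if isinstance(data, dict) else data
        df = pd.DataFrame(rules)
    else:
        df = pd.read_csv(path)
    required = {
        "antigen",
        "dose_number",
        "recommended_age_months",
        "window_low_days",
        "window_high_days",
    }
    missing = required - set(df.columns)
    if missing:
        raise ScheduleError(f"schedule file {path} missing columns {sorted(missing)}")
    return _schedule_from_rows(
        df[
            [
                "antigen",
                "dose_number",
                "recommended_age_months",
                "window_low_days",
                "window_high_days",
            ]
        ].itertuples(index=False)
    )


def save_schedule(schedule: VaccineSchedule, path: str | Path) -> None:
    """Write a schedule in the flat format that :func:`load_schedule` reads."""
    path = Path(path)
    df = schedule.to_frame()
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, "w") as fh:
            yaml.safe_dump({"rules": df.to_dict(orient="records")}, fh, sort_keys=False)
    else:
        df.to_csv(path, index=False)
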