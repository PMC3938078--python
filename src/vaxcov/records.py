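"""Surveyed children and reconciliation of their written immunization records.

Each child may hold up to two written histories: the immunization
*certificate* kept by the caregiver and the immunization *card* kept by the
vaccination clinic. Only written history counts as proof of immunization
(caregiver recall is not accepted). Reconciliation prefers the certificate;
the card is used only when no certificate exists; a child with neither
document is regarded as unvaccinated. A dose whose date is missing on the
chosen document is considered unreceived.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "DoseEvent",
    "CovariateSet",
    "ChildRecord",
    "ReconciledHistory",
    "DocumentTally",
    "RecordError",
    "read_children",
    "read_children_long",
    "write_children",
    "reconcile",
    "document_tally",
    "COVARIATE_LEVELS",
    "DOSE_COLUMNS",
]


class RecordError(ValueError):
    """A child record violates its validity constraints."""


# Categorical covariate levels, in display order; the first level of each
# variable is NOT necessarily the regression reference (see determinants).
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "caregiver_relation": ("mother", "father", "other"),
    "caregiver_age_band": ("<25", "25-34", ">34"),
    "caregiver_gender": ("male", "female"),
    "caregiver_occupation": (
        "worker",
        "commercial_staff",
        "professional",
        "private_owner",
        "housewife",
    ),
    "caregiver_education": (
        "primary_or_below",
        "middle_school",
        "high_school_or_above",
    ),
    "family_income_band": ("<3000", "3000-5000", ">5000"),
    "child_age_band": ("12-35", "36-59"),
    "child_sex": ("male", "female"),
    "hukou": ("guangdong", "outside"),
    "residence": ("purchased_house", "renting_house"),
    "birth_place": (
        "county_hospital_or_above",
        "town_clinic",
        "village_clinic",
        "home",
    ),
}

# Default dose columns (wide CSV dialect), matching the default schedule.
DOSE_COLUMNS: tuple[str, ...] = (
    "BCG1",
    "HepB1",
    "HepB2",
    "HepB3",
    "OPV1",
    "OPV2",
    "OPV3",
    "DPT1",
    "DPT2",
    "DPT3",
    "MCV1",
)


@dataclass(frozen=True)
class DoseEvent:
    """One recorded dose; ``date`` is None when the written date is missing."""

    antigen: str
    dose_number: int
    date: Optional[dt.date]

    def __post_init__(self):
        if self.dose_number < 1:
            raise RecordError(f"{self.antigen}: dose_number must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.antigen}{self.dose_number}"


@dataclass(frozen=True)
class CovariateSet:
    """Caregiver and household covariates of one surveyed child.

    Knowledge (0-34, count of correct free-vaccine / disease-prevented
    answers) and attitude (0-13, immunization-safety awareness) are raw
    scores; the remaining variables are categorical with the levels of
    :data:`COVARIATE_LEVELS`.
    """

    caregiver_relation: str
    caregiver_age_band: str
    caregiver_gender: str
    caregiver_occupation: str
    caregiver_education: str
    knowledge_score: int
    attitude_score: int
    family_income_band: str
    child_age_band: str
    child_sex: str
    hukou: str
    residence: str
    birth_place: str

    def __post_init__(self):
        for name, levels in COVARIATE_LEVELS.items():
            value = getattr(self, name)
            if value not in levels:
                raise RecordError(
                    f"covariate {name}: {value!r} not in levels {levels}"
                )
        if not 0 <= self.knowledge_score <= 34:
            raise RecordError(f"knowledge_score {self.knowledge_score} outside 0-34")
        if not 0 <= self.attitude_score <= 13:
            raise RecordError(f"attitude_score {self.attitude_score} outside 0-13")


@dataclass(frozen=True)
class ChildRecord:
    """One surveyed child: identity, covariates and the two written sources.

    ``certificate``/``card`` are None when the document itself is absent,
    otherwise a tuple of :class:`DoseEvent` (possibly with missing dates).
    """

    child_id: str
    birth_date: dt.date
    age_months_at_survey: int
    covariates: Optional[CovariateSet]
    certificate: Optional[tuple[DoseEvent, ...]]
    card: Optional[tuple[DoseEvent, ...]]
    cluster_id: Optional[str] = None

    def __post_init__(self):
        if not 12 <= self.age_months_at_survey <= 59:
            raise RecordError(
                f"child {self.child_id}: age_months_at_survey "
                f"{self.age_months_at_survey} outside 12-59"
            )
        for source_name in ("certificate", "card"):
            events = getattr(self, source_name)
            if events is None:
                continue
            object.__setattr__(self, source_name, tuple(events))
            for ev in events:
                if ev.date is not None and ev.date < self.birth_date:
                    raise RecordError(
                        f"child {self.child_id}: {ev.label} on {source_name} "
                        f"dated {ev.date}, before birth {self.birth_date}"
                    )


@dataclass(frozen=True)
class ReconciledHistory:
    """The single authoritative dose history chosen for one child."""

    child_id: str
    source: str  # "certificate" | "card" | "none"
    doses: tuple[DoseEvent, ...]

    def __post_init__(self):
        object.__setattr__(self, "doses", tuple(self.doses))
        if self.source == "none" and self.doses:
            raise RecordError(
                f"child {self.child_id}: source 'none' with non-empty doses"
            )

    def dated(self, antigen: str, dose_number: int) -> Optional[DoseEvent]:
        """The dated event for one dose, or None if unreceived."""
        for ev in self.doses:
            if ev.antigen == antigen and ev.dose_number == dose_number:
                return ev
        return None


@dataclass(frozen=True)
class DocumentTally:
    """Counts of written-record availability and certificate/card agreement."""

    total: int
    with_certificate: int
    with_card: int
    with_both: int
    with_neither: int
    discordant_pairs: int
    discordant_extra_doses: int  # one document records more doses
    discordant_dates: int  # same doses, differing dates

    @property
    def pct_without_record(self) -> float:
        return 100.0 * self.with_neither / self.total if self.total else float("nan")


def reconcile(record: ChildRecord) -> ReconciledHistory:
    """Choose the authoritative written source for one child.

    The certificate wins whenever present, regardless of what the card says;
    otherwise the card is used; with neither document the child is regarded
    as unvaccinated. Doses with missing dates are dropped (considered
    unreceived). Total: never raises.
    """
    if record.certificate is not None:
        source, events = "certificate", record.certificate
    elif record.card is not None:
        source, events = "card", record.card
    else:
        return ReconciledHistory(record.child_id, "none", ())
    dated = tuple(ev for ev in events if ev.date is not None)
    return ReconciledHistory(record.child_id, source, dated)


def _dose_multiset(events: Sequence[DoseEvent]) -> dict:
    out: dict = {}
    for ev in events:
        if ev.date is not None:
            out[(ev.antigen, ev.dose_number)] = ev.date
    return out


def document_tally(records: Iterable[ChildRecord]) -> DocumentTally:
    """Tally document availability and certificate-vs-card discordance.

    A pair is discordant when the multiset of (antigen, dose, date) dated
    events differs between the two documents; pairs differing in the dose
    set are counted separately from pairs with the same doses but differing
    dates.
    """
    total = with_cert = with_card = with_both = with_neither = 0
    discordant = extra = dates = 0
    for rec in records:
        total += 1
        has_cert = rec.certificate is not None
        has_card = rec.card is not None
        with_cert += has_cert
        with_card += has_card
        if has_cert and has_card:
            with_both += 1
            c = _dose_multiset(rec.certificate)
            k = _dose_multiset(rec.card)
            if c != k:
                discordant += 1
                if set(c) != set(k):
                    extra += 1
                else:
                    dates += 1
        elif not has_cert and not has_card:
            with_neither += 1
    return DocumentTally(
        total, with_cert, with_card, with_both, with_neither, discordant, extra, dates
    )


# ---------------------------------------------------------------------------
# CSV I/O: wide dialect (one row per child, cert_<DOSE>/card_<DOSE> columns,
# ISO-8601 dates, empty cell = missing date) and a long dialect.

_META_COLUMNS = ("child_id", "birth_date", "age_months_at_survey")
_COVARIATE_COLUMNS = tuple(f.name for f in dc_fields(CovariateSet))


def _parse_date(value, *, context: str) -> Optional[dt.date]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError:
        raise RecordError(f"{context}: unparseable date {value!r}") from None


_PRESENCE_FLAG = {"cert": "has_certificate", "card": "has_card"}


def _events_from_row(row, prefix: str, dose_columns, context: str):
    present = row.get(_PRESENCE_FLAG[prefix])
    if pd.isna(present) or not int(present):
        return None
    events = []
    for label in dose_columns:
        col = f"{prefix}_{label}"
        antigen = label.rstrip("0123456789")
        number = int(label[len(antigen):])
        date = _parse_date(row.get(col), context=f"{context} {col}")
        events.append(DoseEvent(antigen, number, date))
    return tuple(events)


def read_children(
    path: str | Path,
    dose_columns: Sequence[str] = DOSE_COLUMNS,
    require_covariates: bool = True,
) -> list[ChildRecord]:
    """Read the wide one-row-per-child CSV dialect.

    Required columns: ``child_id``, ``birth_date``, ``age_months_at_survey``,
    ``has_certificate``, ``has_card`` (0/1), one ``cert_<DOSE>`` and
    ``card_<DOSE>`` column per dose label, and (unless
    ``require_covariates=False``) every :class:`CovariateSet` field. Dates
    are ISO-8601; an empty date cell is a missing (unreceived) dose.
    Validation problems raise :class:`RecordError` naming the row/child.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = set(_META_COLUMNS) | {"has_certificate", "has_card"}
    required |= {f"cert_{c}" for c in dose_columns} | {f"card_{c}" for c in dose_columns}
    if require_covariates:
        required |= set(_COVARIATE_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise RecordError(f"{path}: missing required columns {sorted(missing)}")

    records: list[ChildRecord] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        context = f"row {i + 2} (child {row.get('child_id', '?')})"
        birth = _parse_date(row["birth_date"], context=f"{context} birth_date")
        if birth is None:
            raise RecordError(f"{context}: missing birth_date")
        try:
            covariates = (
                CovariateSet(
                    **{
                        name: (
                            int(row[name])
                            if name in ("knowledge_score", "attitude_score")
                            else row[name]
                        )
                        for name in _COVARIATE_COLUMNS
                    }
                )
                if require_covariates
                else None
            )
            records.append(
                ChildRecord(
                    child_id=str(row["child_id"]),
                    birth_date=birth,
                    age_months_at_survey=int(row["age_months_at_survey"]),
                    covariates=covariates,
                    certificate=_events_from_row(row, "cert", dose_columns, context),
                    card=_events_from_row(row, "card", dose_columns, context),
                    cluster_id=row.get("cluster_id") or None,
                )
            )
        except RecordError as exc:
            raise RecordError(f"{context}: {exc}") from None
    return records


def read_children_long(
    children_path: str | Path, doses_path: str | Path, **kwargs
) -> list[ChildRecord]:
    """Read the long dialect: a child table plus a dose-event table.

    The child table carries the wide dialect's metadata/covariate columns and
    the ``has_certificate``/``has_card`` flags; the dose table has columns
    ``child_id, antigen, dose_number, date, source`` with source in
    {certificate, card} and empty date = missing.
    """
    doses = pd.read_csv(doses_path, dtype=str, keep_default_na=False)
    need = {"child_id", "antigen", "dose_number", "date", "source"}
    if need - set(doses.columns):
        raise RecordError(
            f"{doses_path}: missing columns {sorted(need - set(doses.columns))}"
        )
    children = pd.read_csv(children_path, dtype=str, keep_default_na=False)

    by_child: dict[tuple[str, str], list[DoseEvent]] = {}
    for i, row in enumerate(doses.to_dict(orient="records")):
        src = row["source"]
        if src not in ("certificate", "card"):
            raise RecordError(f"{doses_path} row {i + 2}: unknown source {src!r}")
        date = _parse_date(row["date"], context=f"{doses_path} row {i + 2}")
        by_child.setdefault((str(row["child_id"]), src), []).append(
            DoseEvent(row["antigen"], int(row["dose_number"]), date)
        )

    require_covariates = kwargs.get("require_covariates", True)
    records = []
    for i, row in enumerate(children.to_dict(orient="records")):
        cid = str(row["child_id"])
        context = f"row {i + 2} (child {cid})"
        birth = _parse_date(row["birth_date"], context=f"{context} birth_date")
        if birth is None:
            raise RecordError(f"{context}: missing birth_date")
        try:
            covariates = (
                CovariateSet(
                    **{
                        name: (
                            int(row[name])
                            if name in ("knowledge_score", "attitude_score")
                            else row[name]
                        )
                        for name in _COVARIATE_COLUMNS
                    }
                )
                if require_covariates
                else None
            )
            records.append(
                ChildRecord(
                    child_id=cid,
                    birth_date=birth,
                    age_months_at_survey=int(row["age_months_at_survey"]),
                    covariates=covariates,
                    certificate=(
                        tuple(by_child.get((cid, "certificate"), ()))
                        if int(row["has_certificate"])
                        else None
                    ),
                    card=(
                        tuple(by_child.get((cid, "card"), ()))
                        if int(row["has_card"])
                        else None
                    ),
                    cluster_id=row.get("cluster_id") or None,
                )
            )
        except RecordError as exc:
            raise RecordError(f"{context}: {exc}") from None
    return records


def write_children(
    records: Iterable[ChildRecord],
    path: str | Path,
    dose_columns: Sequence[str] = DOSE_COLUMNS,
) -> None:
    """Write records in the wide CSV dialect read by :func:`read_children`."""
    rows = []
    for rec in records:
        row: dict = {
            "child_id": rec.child_id,
            "birth_date": rec.birth_date.isoformat(),
            "age_months_at_survey": rec.age_months_at_survey,
            "cluster_id": rec.cluster_id or "",
        }
        if rec.covariates is not None:
            for name in _COVARIATE_COLUMNS:
                row[name] = getattr(rec.covariates, name)
        for prefix, events in (("cert", rec.certificate), ("card", rec.card)):
            row[_PRESENCE_FLAG[prefix]] = int(events is not None)
            dated = _dose_multiset(events) if events else {}
            for label in dose_columns:
                antigen = label.rstrip("0123456789")
                number = int(label[len(antigen):])
                date = dated.get((antigen, number))
                row[f"{prefix}_{label}"] = date.isoformat() if date else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
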