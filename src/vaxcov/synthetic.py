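"""Synthetic survey generator with known ground truth.

Emulates a two-district migrant-child population surveyed by a two-stage
EPI cluster design: village clusters, households, children aged 12-59
months with caregiver/household covariates, per-dose vaccination dates
drawn from configurable timing mixtures, and written-record availability
(certificate / clinic card, including rare discordant pairs and children
with no document at all).

Every default is anchored to the 2011 Guangdong migrant-child survey's
published margins: covariate marginals from the determinants table
(n/1530), per-dose timing mixtures from the coverage decomposition table
(conditional on receipt), record-availability probabilities from the
reported document counts (49/1530 with no document, 18/1437 discordant
pairs), and a 64.9% baseline UTD probability. Ground truth (each child's
true UTD status and per-dose timing category) is returned alongside the
records, so classification and model fitting can be checked against what
was generated.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._util import as_rng
from .design import ClusterFrame, DesignParameters, household_walk, plan_clusters, pps_select, required_sample_size
from .records import ChildRecord, CovariateSet, DoseEvent
from .schedule import VaccineSchedule, default_schedule

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SurveyDataset",
    "generate_cohort",
    "generate_utd_outcomes",
    "generate_survey",
    "load_generator_config",
    "save_generator_config",
]

# Covariate marginals: published category counts / 1530.
_MARGINAL_COUNTS: dict[str, dict[str, int]] = {
    "caregiver_relation": {"mother": 1111, "father": 257, "other": 162},
    "caregiver_age_band": {"<25": 176, "25-34": 950, ">34": 404},
    "caregiver_gender": {"male": 302, "female": 1228},
    "caregiver_occupation": {
        "worker": 161,
        "commercial_staff": 313,
        "professional": 54,
        "private_owner": 240,
        "housewife": 762,
    },
    "caregiver_education": {
        "primary_or_below": 539,
        "middle_school": 738,
        "high_school_or_above": 253,
    },
    "knowledge_band": {"<9": 627, "10-19": 647, "20-34": 256},
    "attitude_band": {"0-7": 454, "8-13": 1076},
    "family_income_band": {"<3000": 671, "3000-5000": 544, ">5000": 315},
    "child_age_band": {"12-35": 1180, "36-59": 350},
    "child_sex": {"male": 670, "female": 860},
    "hukou": {"guangdong": 562, "outside": 968},
    "residence": {"purchased_house": 187, "renting_house": 1343},
    "birth_place": {
        "county_hospital_or_above": 780,
        "town_clinic": 644,
        "village_clinic": 40,
        "home": 66,
    },
}

# Published per-dose decomposition (invalid, appropriate, delayed), in
# percent of the surveyed denominator; mixtures below condition on receipt.
_DOSE_DECOMPOSITION: dict[str, tuple[float, float, float]] = {
    "BCG1": (0.0, 47.8, 28.5),
    "HepB1": (0.0, 63.6, 13.1),
    "HepB2": (1.0, 68.8, 5.9),
    "HepB3": (1.2, 55.9, 14.3),
    "OPV1": (1.9, 58.8, 16.9),
    "OPV2": (1.3, 67.3, 8.0),
    "OPV3": (2.0, 64.2, 8.9),
    "DPT1": (1.4, 60.4, 14.8),
    "DPT2": (1.0, 66.7, 7.5),
    "DPT3": (0.8, 60.5, 12.4),
    "MCV1": (1.8, 37.2, 32.8),
}

_SCORE_RANGES = {
    "knowledge_band": {"<9": (0, 9), "10-19": (10, 19), "20-34": (20, 34)},
    "attitude_band": {"0-7": (0, 7), "8-13": (8, 13)},
}

_TRUE_CATEGORIES = ("invalid", "appropriate", "delayed")


def _default_marginals() -> dict[str, dict[str, float]]:
    return {
        var: {level: count / 1530 for level, count in levels.items()}
        for var, levels in _MARGINAL_COUNTS.items()
    }


def _default_mixture() -> dict[str, tuple[float, float, float]]:
    out = {}
    for label, parts in _DOSE_DECOMPOSITION.items():
        total = sum(parts)
        out[label] = tuple(p / total for p in parts)
    return out


def _default_dropout() -> dict[str, float]:
    # Stop probabilities of the series-truncation chain for non-UTD
    # children: most non-UTD children are missing first doses entirely.
    return {
        label: 0.5 if label.endswith("1") and not label.startswith("HepB2") else 0.3
        for label in _DOSE_DECOMPOSITION
    }


def _default_record_model() -> dict[str, float]:
    # no document 49/1530; among the documented, splits approximating the
    # reported certificate/card counts.
    p_none = 49 / 1530
    rest = 1 - p_none
    return {
        "no_document": p_none,
        "certificate_only": rest * 38 / 1481,
        "card_only": rest * 6 / 1481,
        "both": rest * 1437 / 1481,
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-survey generator, with survey-anchored defaults.

    ``true_or`` maps covariate -> level -> odds ratio for UTD relative to
    ``baseline_utd_probability`` (the UTD probability of a child whose every
    covariate carries OR 1); ``timing_mixture`` gives per-dose
    (invalid, appropriate, delayed) probabilities conditional on receipt;
    ``dropout`` is the per-dose probability, for a non-UTD child, that the
    series stops before that dose.
    """

    seed: int = 0
    n_children: int = 1530
    survey_date: dt.date = dt.date(2011, 6, 1)
    covariate_marginals: dict = field(default_factory=_default_marginals)
    true_or: dict = field(default_factory=dict)
    baseline_utd_probability: float = 0.649
    timing_mixture: dict = field(default_factory=_default_mixture)
    delay_mean_days: float = 30.0
    invalid_margin_days: int = 30
    dropout: dict = field(default_factory=_default_dropout)
    record_model: dict = field(default_factory=_default_record_model)
    discordant_given_both: float = 18 / 1437
    date_shift_max_days: int = 14
    household_two_child_prob: float = 0.10
    n_villages: int = 429
    village_size_mean: float = 60.0
    village_size_sigma: float = 0.6
    censor_at_survey: bool = False

    def __post_init__(self):
        if not 0 < self.baseline_utd_probability < 1:
            raise ValueError("baseline_utd_probability must be in (0, 1)")
        for var, levels in self.covariate_marginals.items():
            total = sum(levels.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"marginals for {var} sum to {total}, expected 1")
            if any(p < 0 for p in levels.values()):
                raise ValueError(f"negative marginal probability in {var}")
        for label, mix in self.timing_mixture.items():
            mix = tuple(float(p) for p in mix)
            if len(mix) != 3 or any(p < 0 for p in mix) or abs(sum(mix) - 1) > 1e-9:
                raise ValueError(
                    f"timing mixture for {label} must be 3 non-negative "
                    f"probabilities summing to 1, got {mix}"
                )
            self.timing_mixture[label] = mix
        total = sum(self.record_model.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"record_model probabilities sum to {total}, expected 1")
        for var, levels in self.true_or.items():
            for level, or_ in levels.items():
                if or_ <= 0:
                    raise ValueError(f"true OR for {var}={level} must be > 0")
        if isinstance(self.survey_date, str):
            self.survey_date = dt.date.fromisoformat(self.survey_date)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["survey_date"] = self.survey_date.isoformat()
        d["timing_mixture"] = {k: list(v) for k, v in self.timing_mixture.items()}
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        return cls(**data)


def load_generator_config(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return GeneratorConfig.from_dict(data)


def save_generator_config(config: GeneratorConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew, per child, before record missingness.

    ``frame`` columns: child_id, p_utd, true_utd, document category, and one
    ``true_<DOSE>`` column per dose with values not_received / invalid /
    appropriate / delayed.
    """

    frame: pd.DataFrame
    config: GeneratorConfig

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _draw_levels(rng, marginal: dict[str, float], n: int) -> np.ndarray:
    levels = list(marginal)
    cum = np.cumsum([marginal[l] for l in levels])
    idx = np.searchsorted(cum, rng.random(n) * cum[-1], side="right")
    return np.array(levels, dtype=object)[np.minimum(idx, len(levels) - 1)]


def generate_utd_outcomes(
    config: GeneratorConfig, n: Optional[int] = None, rng=None
) -> pd.DataFrame:
    """Covariate levels and the UTD outcome only (steps 1-2 of generation).

    Columns: every covariate variable (band-level), ``p_utd`` (the logistic
    probability implied by the configured baseline and true ORs) and the
    drawn boolean ``utd``.
    """
    rng = as_rng(config.seed if rng is None else rng)
    n = config.n_children if n is None else n
    data = {
        var: _draw_levels(rng, marginal, n)
        for var, marginal in config.covariate_marginals.items()
    }
    logit = np.full(
        n,
        np.log(config.baseline_utd_probability / (1 - config.baseline_utd_probability)),
    )
    for var, levels in config.true_or.items():
        if var not in data:
            raise ValueError(f"true_or refers to unknown covariate {var!r}")
        for level, or_ in levels.items():
            logit += np.where(data[var] == level, np.log(or_), 0.0)
    p = 1.0 / (1.0 + np.exp(-logit))
    out = pd.DataFrame(data)
    out["p_utd"] = p
    out["utd"] = rng.random(n) < p
    return out


def _timing_draws(rng, config, rule, n):
    """Category codes (0 invalid / 1 appropriate / 2 delayed) and day offsets."""
    label = rule.label
    mix = config.timing_mixture.get(label)
    if mix is None:
        raise ValueError(f"no timing mixture configured for dose {label}")
    low, high = rule.window_low_days, rule.window_high_days
    if mix[0] > 0 and low == 0:
        raise ValueError(
            f"infeasible config: dose {label} has window minimum 0 days, "
            f"an invalid (too-early) dose cannot exist"
        )
    cum = np.cumsum(mix)
    cat = np.searchsorted(cum, rng.random(n) * cum[-1], side="right")
    cat = np.minimum(cat, 2)
    appropriate = rng.integers(low, high + 1, n)
    if low > 0:
        invalid = rng.integers(max(0, low - config.invalid_margin_days), low, n)
    else:
        invalid = np.zeros(n, dtype=int)  # never used (mix[0] == 0)
    delayed = high + rng.geometric(1.0 / config.delay_mean_days, n)
    offsets = np.choose(cat, [invalid, appropriate, delayed])
    return cat, offsets


def generate_cohort(
    config: GeneratorConfig,
    n: Optional[int] = None,
    rng=None,
    schedule: Optional[VaccineSchedule] = None,
    id_prefix: str = "C",
) -> tuple[list[ChildRecord], GroundTruth]:
    """Generate a full synthetic cohort with ground truth.

    Pipeline per child: covariates from marginals; UTD from the logistic
    model; if UTD every dose receives a timing category and a date, else the
    series are truncated by the dropout chain; finally the record model
    decides document availability, discordance perturbations and hence which
    doses are observable. Deterministic given seed/rng.
    """
    rng = as_rng(config.seed if rng is None else rng)
    schedule = schedule or default_schedule()
    n = config.n_children if n is None else n

    out = generate_utd_outcomes(config, n, rng)
    utd = out["utd"].to_numpy()

    # raw scores within the drawn bands
    scores = {}
    for var in ("knowledge_band", "attitude_band"):
        lo = np.array([_SCORE_RANGES[var][b][0] for b in out[var]])
        hi = np.array([_SCORE_RANGES[var][b][1] for b in out[var]])
        scores[var] = rng.integers(lo, hi + 1)

    # survey age: uniform within the drawn age band
    band = out["child_age_band"].to_numpy()
    months = np.where(
        band == "12-35", rng.integers(12, 36, n), rng.integers(36, 60, n)
    )
    extra_days = rng.integers(0, 30, n)
    age_days = np.round(months * 30.4375).astype(int) + extra_days
    birth_dates = [config.survey_date - dt.timedelta(days=int(d)) for d in age_days]

    # per-dose timing categories, receipt masks and cumulative dates
    received: dict[str, np.ndarray] = {}
    category: dict[str, np.ndarray] = {}
    day_offset: dict[str, np.ndarray] = {}
    series_labels: list[list[str]] = []
    for series in schedule.series:
        labels = []
        stopped = np.zeros(n, dtype=bool)
        for rule in series.rules:
            cat, off = _timing_draws(rng, config, rule, n)
            stop = (~utd) & (rng.random(n) < float(config.dropout.get(rule.label, 0.3)))
            stopped |= stop
            received[rule.label] = ~stopped
            category[rule.label] = cat
            day_offset[rule.label] = off
            labels.append(rule.label)
        series_labels.append(labels)

    # a non-UTD child whose dropout chain dropped nothing would contradict
    # its ground truth: drop the final dose of a random series
    all_received = np.logical_and.reduce([received[l] for l in received])
    fix = np.flatnonzero((~utd) & all_received)
    if fix.size:
        which = rng.integers(0, len(series_labels), fix.size)
        for i, s in zip(fix, which):
            received[series_labels[s][-1]][i] = False

    # dates: within a series receipt is a prefix, so date_k = birth + sum of offsets
    dates: dict[str, list[Optional[dt.date]]] = {}
    for labels in series_labels:
        cum = np.zeros(n, dtype=int)
        for label in labels:
            cum = cum + day_offset[label]
            col: list[Optional[dt.date]] = []
            for i in range(n):
                if not received[label][i]:
                    col.append(None)
                    continue
                date = birth_dates[i] + dt.timedelta(days=int(cum[i]))
                if config.censor_at_survey and date > config.survey_date:
                    col.append(None)
                    received[label][i] = False
                else:
                    col.append(date)
            dates[label] = col

    # document availability
    doc_cat = _draw_levels(rng, config.record_model, n)
    discordant = (doc_cat == "both") & (rng.random(n) < config.discordant_given_both)
    discord_kind = rng.random(n) < 0.5  # True: drop a card dose; False: shift a date

    all_labels = [l for labels in series_labels for l in labels]
    records: list[ChildRecord] = []
    truth_rows = []
    for i in range(n):
        events = tuple(
            DoseEvent(lbl.rstrip("0123456789"), int(lbl[len(lbl.rstrip('0123456789')):]), dates[lbl][i])
            for lbl in all_labels
            if received[lbl][i]
        )
        cert = card = None
        if doc_cat[i] == "certificate_only":
            cert = events
        elif doc_cat[i] == "card_only":
            card = events
        elif doc_cat[i] == "both":
            cert, card = events, events
            if discordant[i] and len(events) > 0:
                j = int(rng.integers(len(events)))
                if discord_kind[i]:
                    card = events[:j] + events[j + 1 :]
                else:
                    shift = int(rng.integers(1, config.date_shift_max_days + 1))
                    if rng.random() < 0.5 and (events[j].date - birth_dates[i]).days > shift:
                        shift = -shift
                    ev = events[j]
                    card = (
                        events[:j]
                        + (DoseEvent(ev.antigen, ev.dose_number, ev.date + dt.timedelta(days=shift)),)
                        + events[j + 1 :]
                    )
        covariates = CovariateSet(
            caregiver_relation=out["caregiver_relation"][i],
            caregiver_age_band=out["caregiver_age_band"][i],
            caregiver_gender=out["caregiver_gender"][i],
            caregiver_occupation=out["caregiver_occupation"][i],
            caregiver_education=out["caregiver_education"][i],
            knowledge_score=int(scores["knowledge_band"][i]),
            attitude_score=int(scores["attitude_band"][i]),
            family_income_band=out["family_income_band"][i],
            child_age_band=out["child_age_band"][i],
            child_sex=out["child_sex"][i],
            hukou=out["hukou"][i],
            residence=out["residence"][i],
            birth_place=out["birth_place"][i],
        )
        child_id = f"{id_prefix}{i:06d}"
        records.append(
            ChildRecord(
                child_id=child_id,
                birth_date=birth_dates[i],
                age_months_at_survey=int(months[i]),
                covariates=covariates,
                certificate=cert,
                card=card,
            )
        )
        row = {
            "child_id": child_id,
            "p_utd": float(out["p_utd"][i]),
            "true_utd": bool(utd[i]),
            "document": doc_cat[i],
        }
        for lbl in all_labels:
            row[f"true_{lbl}"] = (
                _TRUE_CATEGORIES[category[lbl][i]] if received[lbl][i] else "not_received"
            )
        truth_rows.append(row)

    return records, GroundTruth(pd.DataFrame(truth_rows), config)


@dataclass(frozen=True)
class SurveyDataset:
    """Output of the simulated two-stage survey."""

    children: list[ChildRecord]
    ground_truth: GroundTruth
    cluster_frame: ClusterFrame
    selected_clusters: list
    shortfall_clusters: list


def generate_survey(
    config: GeneratorConfig, design: DesignParameters, rng=None
) -> SurveyDataset:
    """Simulate the whole two-stage survey.

    Villages are generated with lognormal sizes, ``design.clusters_selected``
    clusters are drawn by systematic PPS, village populations are generated
    only for selected villages, grouped into households (some with two
    eligible children), and the household walk selects the per-cluster quota
    (youngest child per household). Sampled children carry their cluster id.
    """
    rng = as_rng(config.seed if rng is None else rng)
    sizes = np.maximum(
        2,
        np.round(
            rng.lognormal(np.log(config.village_size_mean), config.village_size_sigma, config.n_villages)
        ).astype(int),
    )
    ids = [f"V{i:03d}" for i in range(config.n_villages)]
    frame = ClusterFrame(ids, sizes)

    selected = pps_select(frame, design.clusters_selected, rng)
    quota = design.per_cluster_quota or plan_clusters(
        required_sample_size(design), design.clusters_selected
    ).per_cluster_quota

    multiplicity: dict[str, int] = {}
    for cid in selected:
        multiplicity[cid] = multiplicity.get(cid, 0) + 1

    children: list[ChildRecord] = []
    truth_frames = []
    shortfalls = []
    for cid, mult in multiplicity.items():
        size = frame.sizes[frame.cluster_ids.index(cid)]
        village_children, truth = generate_cohort(
            config, n=int(size), rng=rng, id_prefix=f"{cid}-"
        )
        # group into households (1 eligible child mostly, sometimes 2)
        households: list[list[ChildRecord]] = []
        it = iter(village_children)
        for child in it:
            if households and rng.random() < config.household_two_child_prob and len(households[-1]) == 1:
                households[-1].append(child)
            else:
                households.append([child])
        walk = household_walk(households, quota * mult, rng)
        if walk.shortfall:
            shortfalls.append(cid)
        picked_ids = {c.child_id for c in walk.selected}
        children.extend(
            dataclasses.replace(c, cluster_id=cid) for c in walk.selected
        )
        truth_frames.append(truth.frame[truth.frame["child_id"].isin(picked_ids)])

    truth = GroundTruth(pd.concat(truth_frames, ignore_index=True), config)
    return SurveyDataset(children, truth, frame, selected, shortfalls)
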