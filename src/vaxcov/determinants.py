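"""Determinants of up-to-date immunization: scoring, binning, logistic model.

Caregiver knowledge is scored as the number of correct answers (which
vaccines are free, which diseases they prevent; 0-34). Attitude toward
immunization safety is a graded-points total (0-13). Covariates are binned
into the analysis categories and all enter one multivariable logistic
regression of the child's composite-series UTD status; the model reports
per-level odds ratios with Wald 95% confidence intervals and p-values
against the designated reference level of each variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .records import COVARIATE_LEVELS, CovariateSet

__all__ = [
    "SeparationError",
    "RegressionResult",
    "score_knowledge",
    "score_attitude",
    "knowledge_band",
    "attitude_band",
    "income_band",
    "caregiver_age_band",
    "child_age_band",
    "bin_covariates",
    "fit_utd_logistic",
    "REFERENCE_LEVELS",
]


class SeparationError(ValueError):
    """The logistic fit is degenerate (one outcome class, empty level, separation)."""


def score_knowledge(items: Sequence[bool]) -> int:
    """Knowledge score: count of correct items (at most 34)."""
    items = list(items)
    if len(items) > 34:
        raise ValueError(f"knowledge questionnaire has at most 34 items, got {len(items)}")
    return int(sum(bool(x) for x in items))


def score_attitude(points: Sequence[int]) -> int:
    """Attitude score: total of graded awareness points, range 0-13."""
    total = int(sum(points))
    if not 0 <= total <= 13:
        raise ValueError(f"attitude score {total} outside 0-13")
    return total


# Bin edges are configurable; defaults follow the analysis categories.
# The knowledge categories are printed "<9" then "10-19": score 9 falls in
# the low bin (read as <=9).
KNOWLEDGE_EDGES: tuple[tuple[int, int, str], ...] = (
    (0, 9, "<9"),
    (10, 19, "10-19"),
    (20, 34, "20-34"),
)
ATTITUDE_EDGES: tuple[tuple[int, int, str], ...] = ((0, 7, "0-7"), (8, 13, "8-13"))


def _bin(value: float, edges, variable: str) -> str:
    for low, high, label in edges:
        if low <= value <= high:
            return label
    raise ValueError(f"{variable}: value {value} outside all bins")


def knowledge_band(score: int, edges=KNOWLEDGE_EDGES) -> str:
    return _bin(score, edges, "knowledge_score")


def attitude_band(score: int, edges=ATTITUDE_EDGES) -> str:
    return _bin(score, edges, "attitude_score")


def income_band(yuan_per_person_year: float) -> str:
    """Family income band; both 3000 and 5000 fall in the middle band."""
    if yuan_per_person_year < 0:
        raise ValueError(f"family_income: negative value {yuan_per_person_year}")
    if yuan_per_person_year < 3000:
        return "<3000"
    if yuan_per_person_year <= 5000:
        return "3000-5000"
    return ">5000"


def caregiver_age_band(years: float) -> str:
    if years < 0:
        raise ValueError(f"caregiver_age: negative value {years}")
    if years < 25:
        return "<25"
    if years <= 34:
        return "25-34"
    return ">34"


def child_age_band(months: int) -> str:
    if 12 <= months <= 35:
        return "12-35"
    if 36 <= months <= 59:
        return "36-59"
    raise ValueError(f"child_age_months: {months} outside 12-59")


def bin_covariates(
    *,
    caregiver_relation: str,
    caregiver_age_years: float,
    caregiver_gender: str,
    caregiver_occupation: str,
    caregiver_education: str,
    knowledge_score: int,
    attitude_score: int,
    family_income: float,
    child_age_months: int,
    child_sex: str,
    hukou: str,
    residence: str,
    birth_place: str,
) -> CovariateSet:
    """Assign raw quantities to the analysis categories, deterministically."""
    return CovariateSet(
        caregiver_relation=caregiver_relation,
        caregiver_age_band=caregiver_age_band(caregiver_age_years),
        caregiver_gender=caregiver_gender,
        caregiver_occupation=caregiver_occupation,
        caregiver_education=caregiver_education,
        knowledge_score=int(knowledge_score),
        attitude_score=int(attitude_score),
        family_income_band=income_band(family_income),
        child_age_band=child_age_band(child_age_months),
        child_sex=child_sex,
        hukou=hukou,
        residence=residence,
        birth_place=birth_place,
    )


# Reference level of each model variable (odds ratio fixed at 1.00).
REFERENCE_LEVELS: dict[str, str] = {
    "caregiver_relation": "mother",
    "caregiver_age_band": "<25",
    "caregiver_gender": "male",
    "caregiver_occupation": "worker",
    "caregiver_education": "high_school_or_above",
    "knowledge_band": "<9",
    "attitude_band": "0-7",
    "family_income_band": "<3000",
    "child_age_band": "36-59",
    "child_sex": "male",
    "hukou": "outside",
    "residence": "renting_house",
    "birth_place": "county_hospital_or_above",
}

# Display order of levels within each model variable.
_LEVEL_ORDER: dict[str, tuple[str, ...]] = dict(COVARIATE_LEVELS)
_LEVEL_ORDER["knowledge_band"] = tuple(lbl for *_, lbl in KNOWLEDGE_EDGES)
_LEVEL_ORDER["attitude_band"] = tuple(lbl for *_, lbl in ATTITUDE_EDGES)


@dataclass(frozen=True)
class RegressionResult:
    """Per-level odds ratios of the UTD logistic model.

    ``table`` columns: variable, level, n, odds_ratio, ci_low, ci_high,
    p_value, reference. Reference rows carry odds_ratio 1.0 and no CI or
    p-value.
    """

    table: pd.DataFrame
    n_observations: int
    converged: bool

    def level(self, variable: str, level: str) -> pd.Series:
        t = self.table
        hit = t[(t["variable"] == variable) & (t["level"] == level)]
        if hit.empty:
            raise KeyError(f"no fitted level {variable}={level}")
        return hit.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        """Write the result table with the conventional display rounding.

        ORs and CI bounds to two decimals; p-values to three decimals, with
        values below 0.0005 shown as "0.000".
        """
        out = self.table.copy()
        for col in ("odds_ratio", "ci_low", "ci_high"):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
        out["p_value"] = out["p_value"].map(
            lambda v: "" if pd.isna(v) else f"{v:.3f}"
        )
        out.to_csv(path, index=False)


def _as_model_frame(children) -> pd.DataFrame:
    if isinstance(children, pd.DataFrame):
        if "utd" not in children.columns:
            raise ValueError("model frame must contain a boolean 'utd' column")
        return children.copy()
    rows = []
    for cov, utd in children:
        if not isinstance(cov, CovariateSet):
            raise TypeError("expected (CovariateSet, bool) pairs")
        rows.append(
            {
                "caregiver_relation": cov.caregiver_relation,
                "caregiver_age_band": cov.caregiver_age_band,
                "caregiver_gender": cov.caregiver_gender,
                "caregiver_occupation": cov.caregiver_occupation,
                "caregiver_education": cov.caregiver_education,
                "knowledge_band": knowledge_band(cov.knowledge_score),
                "attitude_band": attitude_band(cov.attitude_score),
                "family_income_band": cov.family_income_band,
                "child_age_band": cov.child_age_band,
                "child_sex": cov.child_sex,
                "hukou": cov.hukou,
                "residence": cov.residence,
                "birth_place": cov.birth_place,
                "utd": bool(utd),
            }
        )
    return pd.DataFrame(rows)


def fit_utd_logistic(
    children,
    covariates: Sequence[str] | None = None,
    reference_levels: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> RegressionResult:
    """Fit the multivariable logistic regression of UTD status.

    ``children`` is either an iterable of ``(CovariateSet, utd)`` pairs or a
    DataFrame with a boolean ``utd`` column and categorical covariate
    columns. All covariates enter one model simultaneously, dummy-coded
    against their reference levels; odds ratios are exp(coefficient) with
    Wald confidence intervals and p-values. Degenerate inputs (single
    outcome class, an unobserved level, complete separation) raise
    :class:`SeparationError` naming the problem.
    """
    df = _as_model_frame(children)
    y = df["utd"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise SeparationError(
            "outcome 'utd' has a single class; the model is not identifiable"
        )
    if covariates is None:
        covariates = [c for c in df.columns if c != "utd"]
    refs = dict(REFERENCE_LEVELS)
    if reference_levels:
        refs.update(reference_levels)

    columns = []  # (variable, level) per dummy column
    X_parts = []
    level_counts: dict[tuple[str, str], int] = {}
    for var in covariates:
        observed = df[var].astype(str)
        declared = _LEVEL_ORDER.get(var)
        levels = [l for l in declared if l in set(observed)] if declared else sorted(
            observed.unique()
        )
        if declared:
            empty = sorted(set(declared) - set(observed))
            if empty:
                raise SeparationError(
                    f"covariate {var!r}: level(s) {empty} have no observations"
                )
        ref = refs.get(var, levels[0])
        if ref not in levels:
            raise SeparationError(
                f"covariate {var!r}: reference level {ref!r} has no observations"
            )
        for level in levels:
            level_counts[(var, level)] = int((observed == level).sum())
            if level == ref:
                continue
            columns.append((var, level))
            X_parts.append((observed == level).to_numpy(float))

    X = np.column_stack([np.ones(len(df))] + X_parts)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"complete separation in logistic fit: {exc}") from exc
    params = fit.params
    if not fit.mle_retvals.get("converged", True) or np.any(np.abs(params[1:]) > 15):
        raise SeparationError(
            "logistic fit did not converge to finite coefficients "
            "(quasi-separation in some covariate level)"
        )
    conf = fit.conf_int(alpha=alpha)

    rows = []
    for var in covariates:
        for (v, level), count in level_counts.items():
            if v != var:
                continue
            if (var, level) not in columns:
                rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "n": count,
                        "odds_ratio": 1.0,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p_value": np.nan,
                        "reference": True,
                    }
                )
            else:
                j = 1 + columns.index((var, level))
                rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "n": count,
                        "odds_ratio": float(np.exp(params[j])),
                        "ci_low": float(np.exp(conf[j, 0])),
                        "ci_high": float(np.exp(conf[j, 1])),
                        "p_value": float(fit.pvalues[j]),
                        "reference": False,
                    }
                )
    table = pd.DataFrame(rows)
    return RegressionResult(table, len(df), bool(fit.mle_retvals.get("converged", True)))
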