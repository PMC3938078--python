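"""EPI cluster-survey design: sample size, PPS cluster selection, household walk.

The design mirrors the WHO-style expanded-programme-on-immunization (EPI)
cluster survey: a required sample size from the usual proportion formula
inflated by a design effect, systematic probability-proportional-to-size
(PPS) selection of village clusters, and an in-village right-hand walk from
a random start household, interviewing the youngest eligible child per
household until the cluster quota is met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from operator import attrgetter
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._util import as_rng

__all__ = [
    "ClusterFrame",
    "DesignParameters",
    "ClusterPlan",
    "WalkResult",
    "required_sample_size",
    "plan_clusters",
    "pps_select",
    "household_walk",
]


@dataclass(frozen=True)
class ClusterFrame:
    """Sampling frame of clusters with their measures of size.

    The measure of size is the count of eligible children in the cluster
    (e.g. migrant children aged 12-59 months per village).
    """

    cluster_ids: tuple
    sizes: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "cluster_ids", tuple(self.cluster_ids))
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))
        if len(self.cluster_ids) != len(self.sizes):
            raise ValueError("cluster_ids and sizes differ in length")
        if len(set(self.cluster_ids)) != len(self.cluster_ids):
            raise ValueError("cluster ids are not unique")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("all cluster sizes must be positive")

    @property
    def total_size(self) -> int:
        return sum(self.sizes)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClusterFrame":
        df = pd.read_csv(path)
        if not {"cluster_id", "size"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns cluster_id, size")
        return cls(tuple(df["cluster_id"].astype(str)), tuple(df["size"]))


@dataclass(frozen=True)
class DesignParameters:
    """Parameters of the two-stage cluster design.

    Defaults are the 2011 Guangdong migrant-child survey's: assumed coverage
    75%, precision ±3 points, design effect 2, 95% confidence, 70 clusters.
    """

    assumed_coverage: float = 0.75
    precision_halfwidth: float = 0.03
    design_effect: float = 2.0
    confidence_z: float = 1.96
    clusters_selected: int = 70
    per_cluster_quota: int | None = None

    def __post_init__(self):
        if not 0 < self.assumed_coverage < 1:
            raise ValueError("assumed_coverage must be in (0, 1)")
        if self.precision_halfwidth <= 0:
            raise ValueError("precision_halfwidth must be positive")
        if self.design_effect < 1:
            raise ValueError("design_effect must be >= 1")
        if self.clusters_selected < 1:
            raise ValueError("clusters_selected must be >= 1")


def required_sample_size(params: DesignParameters) -> int:
    """Required number of children: ceil(deff * z^2 * p(1-p) / d^2)."""
    p = params.assumed_coverage
    d = params.precision_halfwidth
    n = params.design_effect * params.confidence_z**2 * p * (1 - p) / d**2
    return math.ceil(n)


@dataclass(frozen=True)
class ClusterPlan:
    n_required: int
    clusters: int
    per_cluster_quota: int

    @property
    def total(self) -> int:
        return self.per_cluster_quota * self.clusters


def plan_clusters(n_required: int, clusters_selected: int) -> ClusterPlan:
    """Spread the required sample over equal per-cluster quotas (ceiling)."""
    if clusters_selected < 1:
        raise ValueError("clusters_selected must be >= 1")
    quota = math.ceil(n_required / clusters_selected)
    return ClusterPlan(n_required, clusters_selected, quota)


def pps_select(frame: ClusterFrame, n_select: int, seed) -> list:
    """Systematic PPS selection of ``n_select`` clusters.

    Sizes are cumulated in frame order, the sampling interval is
    total/n_select, a start is drawn uniformly on [0, interval), and the
    cluster containing each of the n_select equally spaced points is taken.
    Deterministic given the seed. Clusters larger than the interval are
    certainty selections and may appear more than once (returned with
    multiplicity).
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    if n_select > len(frame.cluster_ids):
        raise ValueError(
            f"cannot select {n_select} clusters from a frame of "
            f"{len(frame.cluster_ids)}"
        )
    rng = as_rng(seed)
    sizes = np.asarray(frame.sizes, dtype=float)
    total = sizes.sum()
    interval = total / n_select
    start = rng.uniform(0.0, interval)
    points = start + interval * np.arange(n_select)
    cum = np.cumsum(sizes)
    idx = np.searchsorted(cum, points, side="right")
    return [frame.cluster_ids[i] for i in idx]


@dataclass(frozen=True)
class WalkResult:
    """Children picked by the household walk, plus a shortfall flag."""

    selected: tuple
    shortfall: bool
    households_visited: int


def household_walk(
    village: Sequence[Sequence],
    quota: int,
    seed,
    age_key: Callable = attrgetter("age_months_at_survey"),
) -> WalkResult:
    """Walk a village's ordered household list and select children.

    ``village`` is the ordered list of households (each a sequence of
    eligible children; may be empty). A start household is drawn at random,
    traversal proceeds cyclically ("to the right"), and from each household
    with eligible children exactly one — the youngest by ``age_key`` — is
    selected, until ``quota`` children are found or the whole village has
    been visited once (then the shortfall flag is set). At most one child
    per household, always.
    """
    if quota < 1:
        raise ValueError("quota must be >= 1")
    if not village:
        return WalkResult((), True, 0)
    rng = as_rng(seed)
    n = len(village)
    start = int(rng.integers(n))
    selected = []
    visited = 0
    for step in range(n):
        household = village[(start + step) % n]
        visited += 1
        if len(household) > 0:
            selected.append(min(household, key=age_key))
            if len(selected) == quota:
                return WalkResult(tuple(selected), False, visited)
    return WalkResult(tuple(selected), True, visited)
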