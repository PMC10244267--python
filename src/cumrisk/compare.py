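"""Demographic contrasts of cumulative exposure and hazard index.

Groups (gender × age band, body-weight quartiles) are compared with
two-sided Welch t-tests (unequal variances, Welch–Satterthwaite degrees
of freedom). Following the survey design, each study day is one
observation by default; this double-counts individuals (two days per
person) and therefore overstates the effective sample size, so the
individual-mean alternative is available via ``observation_unit``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cumulative import cumulative_exposure_series
from .exposure import ExposureMatrix, Individual
from .toxref import HBGV, RPFTable

__all__ = [
    "ComparisonResult",
    "GroupDef",
    "welch_t_test",
    "assign_weight_quartiles",
    "compare_groups",
]


@dataclass(frozen=True)
class GroupDef:
    """A named set of individuals entering a contrast."""

    label: str
    ids: frozenset[str]

    @classmethod
    def from_filter(
        cls,
        individuals: Sequence[Individual],
        label: str,
        gender: str | None = None,
        age_min: float | None = None,
        age_max: float | None = None,
        ids: Sequence[str] | None = None,
    ) -> "GroupDef":
        members = []
        allowed = set(ids) if ids is not None else None
        for ind in individuals:
            if gender is not None and ind.gender != gender:
                continue
            if age_min is not None and ind.age < age_min:
                continue
            if age_max is not None and ind.age > age_max:
                continue
            if allowed is not None and ind.id not in allowed:
                continue
            members.append(ind.id)
        return cls(label, frozenset(members))


@dataclass(frozen=True)
class ComparisonResult:
    endpoint: str
    group_a: str
    group_b: str
    mean_a: float  # mean cumulative exposure, µg/kg bw/d
    mean_b: float
    hi_a: float  # mean hazard index (= mean / index HBGV)
    hi_b: float
    t_statistic: float
    dof: float
    p_value: float
    n_a: int = 0
    n_b: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value must be in [0, 1], got {self.p_value}")
        if not self.dof > 0:
            raise ValueError(f"degrees of freedom must be > 0, got {self.dof}")


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided Welch t-test; returns (t, Welch–Satterthwaite dof, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each sample needs >= 2 observations (got {a.size}, {b.size})")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples are constant; Welch test undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def assign_weight_quartiles(individuals: Sequence[Individual]) -> dict[str, str]:
    """Quartile labels Q1..Q4 from empirical 25/50/75 weight percentiles.

    Boundaries use linear interpolation; an individual exactly on a
    boundary goes to the lower quartile (Q1 spans weights *up to and
    including* the 25th percentile).
    """
    if len(individuals) < 4:
        raise ValueError(f"need >= 4 individuals for quartiles, got {len(individuals)}")
    weights = np.array([i.body_weight for i in individuals], dtype=float)
    q1, q2, q3 = np.percentile(weights, [25, 50, 75])
    if q1 == q3:
        warnings.warn("degenerate weight distribution: all individuals assigned Q1")
        return {i.id: "Q1" for i in individuals}
    out = {}
    for ind in individuals:
        w = ind.body_weight
        if w <= q1:
            out[ind.id] = "Q1"
        elif w <= q2:
            out[ind.id] = "Q2"
        elif w <= q3:
            out[ind.id] = "Q3"
        else:
            out[ind.id] = "Q4"
    return out


def quartile_boundaries(individuals: Sequence[Individual]) -> tuple[float, float, float]:
    weights = np.array([i.body_weight for i in individuals], dtype=float)
    q1, q2, q3 = np.percentile(weights, [25, 50, 75])
    return float(q1), float(q2), float(q3)


def _observations(
    matrix: ExposureMatrix, rpf: RPFTable, ids: frozenset[str], unit: str
) -> np.ndarray:
    if unit == "day":
        entries = matrix.entries
        mask = entries.index.get_level_values("individual").isin(ids)
        return cumulative_exposure_series(entries[mask], rpf).to_numpy()
    if unit == "individual":
        means = matrix.individual_mean()
        sub = means[means.index.isin(ids)]
        return cumulative_exposure_series(sub, rpf).to_numpy()
    raise ValueError(f"unknown observation unit {unit!r}")


def compare_groups(
    matrix: ExposureMatrix,
    contrasts: Sequence[tuple[GroupDef, GroupDef]],
    endpoints: Mapping[str, tuple[RPFTable, Mapping[str, HBGV | float]]],
    observation_unit: str = "day",
) -> list[ComparisonResult]:
    """Welch contrasts of cumulative exposure between population groups.

    For each endpoint and (group A, group B) pair, the observations are
    day-level cumulative exposures (default) or individual means. Groups
    must be nonempty and disjoint; comparing a group with itself is
    allowed as a degenerate identity check (t = 0, p = 1).
    """
    results = []
    for ga, gb in contrasts:
        if not ga.ids or not gb.ids:
            raise ValueError(f"empty group in contrast {ga.label!r} vs {gb.label!r}")
        if ga.ids != gb.ids and ga.ids & gb.ids:
            raise ValueError(
                f"groups {ga.label!r} and {gb.label!r} overlap: "
                f"{sorted(ga.ids & gb.ids)[:5]}"
            )
        for name, (rpf, hbgvs) in endpoints.items():
            obs_a = _observations(matrix, rpf, ga.ids, observation_unit)
            obs_b = _observations(matrix, rpf, gb.ids, observation_unit)
            if ga.ids == gb.ids:
                t, dof, p = 0.0, float(len(obs_a) - 1), 1.0
            else:
                t, dof, p = welch_t_test(obs_a, obs_b)
            index_hbgv = hbgvs[rpf.index_chemical]
            hv = index_hbgv.value if isinstance(index_hbgv, HBGV) else float(index_hbgv)
            results.append(
                ComparisonResult(
                    endpoint=name,
                    group_a=ga.label,
                    group_b=gb.label,
                    mean_a=float(obs_a.mean()),
                    mean_b=float(obs_b.mean()),
                    hi_a=float(obs_a.mean()) / hv,
                    hi_b=float(obs_b.mean()) / hv,
                    t_statistic=t,
                    dof=dof,
                    p_value=p,
                    n_a=len(obs_a),
                    n_b=len(obs_b),
                )
            )
    return results
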