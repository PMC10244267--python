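"""Dose-addition mixture metrics: cumulative exposure and hazard index.

Cumulative exposure expresses a mixture dose in index-chemical
equivalents,

    cumulative exposure = Σ_i RPF_i × Exposure_i        (µg/kg bw/d)

and the hazard index normalises each component by its guidance value,

    HI = Σ_i Exposure_i / HBGV_i        (dimensionless; HI ≤ 1 negligible)

When the RPFs derive from the same HBGV set, HI equals cumulative
exposure divided by the index chemical's HBGV — an identity exploited in
reporting and verified by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .toxref import HBGV, RPFTable

__all__ = [
    "HazardResult",
    "cumulative_exposure",
    "cumulative_exposure_series",
    "hazard_index",
    "exceedance_fraction",
    "chemical_contribution_shares",
    "scale_disease_burden",
    "format_share",
]


def cumulative_exposure(exposures: Mapping[str, float], rpf: RPFTable) -> float:
    """RPF-weighted sum of per-chemical exposures (index equivalents).

    Chemicals in the table but absent from ``exposures`` contribute zero;
    an exposure for a chemical missing from the table is an error.
    """
    total = 0.0
    for chem, e in exposures.items():
        if chem not in rpf:
            raise ValueError(
                f"chemical {chem!r} has exposure but no RPF in endpoint {rpf.endpoint!r}"
            )
        if e < 0:
            raise ValueError(f"negative exposure for {chem!r}")
        total += rpf[chem] * e
    return total


def cumulative_exposure_series(entries: pd.DataFrame, rpf: RPFTable) -> pd.Series:
    """Row-wise Eq.-1 weighting of an exposure table (one row per record).

    Columns are restricted to the endpoint's chemicals; columns of
    ``entries`` not covered by the RPF table are ignored (not part of this
    endpoint's assessment group).
    """
    chems = [c for c in rpf.chemicals if c in entries.columns]
    weights = pd.Series({c: rpf[c] for c in chems})
    return entries[chems].mul(weights, axis=1).sum(axis=1)


def hazard_index(exposures: Mapping[str, float], hbgvs: Mapping[str, float | HBGV]) -> float:
    """Σ exposure_i / HBGV_i over the exposed chemicals."""
    total = 0.0
    for chem, e in exposures.items():
        if chem not in hbgvs:
            raise ValueError(f"no HBGV for exposed chemical {chem!r}")
        if e < 0:
            raise ValueError(f"negative exposure for {chem!r}")
        h = hbgvs[chem]
        total += e / (h.value if isinstance(h, HBGV) else h)
    return total


def exceedance_fraction(his: Mapping[str, float] | Sequence[float], threshold: float = 1.0) -> float:
    """Fraction of individuals with HI strictly above ``threshold``."""
    values = np.asarray(list(his.values()) if isinstance(his, Mapping) else his, dtype=float)
    if values.size == 0:
        raise ValueError("empty hazard-index collection")
    return float(np.mean(values > threshold))


def chemical_contribution_shares(
    mean_exposures: Mapping[str, float], rpf: RPFTable
) -> dict[str, float]:
    """Percent contribution of each chemical to the cumulative exposure."""
    weighted = {}
    for chem, e in mean_exposures.items():
        if chem not in rpf:
            raise ValueError(
                f"chemical {chem!r} has exposure but no RPF in endpoint {rpf.endpoint!r}"
            )
        weighted[chem] = rpf[chem] * e
    total = sum(weighted.values())
    if total <= 0:
        raise ValueError("cumulative exposure is zero; shares undefined")
    return {chem: 100.0 * w / total for chem, w in weighted.items()}


def scale_disease_burden(daly_index: float, share_index: float) -> float:
    """Linear scaling of an index-chemical disease burden to the mixture.

    If the index chemical causes ``daly_index`` DALY/year and contributes
    ``share_index`` of the mixture effect, the mixture burden under a
    linear dose–response is daly_index / share_index.
    """
    if not 0 < share_index <= 1:
        raise ValueError(f"share must be in (0, 1], got {share_index}")
    return daly_index / share_index


def format_share(pct: float) -> str:
    """Report formatting: whole percent, one decimal below 1%."""
    return f"{pct:.1f}%" if pct < 1 else f"{pct:.0f}%"


@dataclass
class HazardResult:
    """Per-endpoint hazard summary for a population.

    ``per_individual_hi`` and ``per_individual_cumexp`` hold individual
    averages over survey days; ``group_summaries`` rows are
    (group label, mean cumulative exposure, mean HI, exceedance fraction).
    """

    endpoint: str
    per_individual_hi: Mapping[str, float]
    per_individual_cumexp: Mapping[str, float]
    group_summaries: list[tuple[str, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ind, hi in self.per_individual_hi.items():
            if hi < 0:
                raise ValueError(f"negative HI for {ind!r}")


def summarize_endpoint(
    individual_means: pd.DataFrame,
    rpf: RPFTable,
    hbgvs: Mapping[str, HBGV],
    groups: Mapping[str, Sequence[str]] | None = None,
) -> HazardResult:
    """Hazard summary from per-individual mean exposures.

    ``individual_means`` is individuals × chemicals; ``groups`` maps a
    label to member individual ids (default: one group "all").
    """
    chems = [c for c in rpf.chemicals if c in individual_means.columns]
    sub = individual_means[chems]
    hvals = pd.Series({c: (hbgvs[c].value if isinstance(hbgvs[c], HBGV) else hbgvs[c]) for c in chems})
    cumexp = cumulative_exposure_series(sub, rpf)
    hi = sub.div(hvals, axis=1).sum(axis=1)
    if groups is None:
        groups = {"all": list(sub.index)}
    summaries = []
    for label, ids in groups.items():
        ids = [i for i in ids if i in hi.index]
        if not ids:
            continue
        summaries.append(
            (
                label,
                float(cumexp.loc[ids].mean()),
                float(hi.loc[ids].mean()),
                exceedance_fraction(hi.loc[ids].to_dict()),
            )
        )
    return HazardResult(rpf.endpoint, hi.to_dict(), cumexp.to_dict(), summaries)
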