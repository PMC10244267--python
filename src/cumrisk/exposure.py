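"""Lower-bound dietary exposure from consumption and occurrence data.

Occurrence measurements below the limit of quantification are substituted
with zero (lower-bound, LB, convention), foods with only non-detects for a
chemical are excluded, per-food mean concentrations are combined with
individual-day consumption amounts and body weight into exposure in
µg/kg bw/d, with the food-level breakdown retained for source attribution.

Units are fixed throughout: consumption g/day, concentration µg/kg food,
exposure µg/kg bw/d; the g→kg factor of 1/1000 is applied once in
:func:`daily_exposure` / :meth:`ExposureMatrix.compute`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .speciation import SPECIES, SpeciationRule, default_rules, speciated_concentration

__all__ = [
    "OccurrenceRecord",
    "ConsumptionRecord",
    "Individual",
    "ExposureMatrix",
    "lb_substitute",
    "exclude_all_nondetect_foods",
    "mean_concentration",
    "concentration_table",
    "daily_exposure",
]

logger = logging.getLogger("cumrisk")


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single analytical result for a chemical in a food item."""

    food: str
    chemical: str
    value: float | None  # µg/kg, present when detected
    loq: float
    detected: bool

    def __post_init__(self) -> None:
        if self.detected:
            if self.value is None or self.value < 0:
                raise ValueError(f"detected record needs value >= 0, got {self.value}")
        elif not self.loq > 0:
            raise ValueError(f"non-detect record needs loq > 0, got {self.loq}")


@dataclass(frozen=True)
class ConsumptionRecord:
    individual: str
    day: int
    food: str
    amount: float  # g/day

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"amount must be >= 0, got {self.amount}")


@dataclass(frozen=True)
class Individual:
    id: str
    age: float  # years, survey covers 25-74
    gender: str
    body_weight: float  # kg

    def __post_init__(self) -> None:
        if not self.body_weight > 0:
            raise ValueError(f"body_weight must be > 0, got {self.body_weight}")
        if not 25 <= self.age <= 74:
            raise ValueError(f"age must be in [25, 74], got {self.age}")


def lb_substitute(records: Sequence[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Lower-bound substitution: non-detects become zeros, detects unchanged."""
    return [
        r if r.detected else OccurrenceRecord(r.food, r.chemical, 0.0, r.loq, False)
        for r in records
    ]


def exclude_all_nondetect_foods(
    records: Sequence[OccurrenceRecord],
) -> set[tuple[str, str]]:
    """Retained (food, chemical) pairs: those with at least one detect.

    Food × chemical combinations measured but never quantified are dropped
    from the assessment; each exclusion is logged.
    """
    detects: set[tuple[str, str]] = set()
    measured: set[tuple[str, str]] = set()
    for r in records:
        key = (r.food, r.chemical)
        measured.add(key)
        if r.detected:
            detects.add(key)
    for food, chem in sorted(measured - detects):
        logger.info("excluding %s x %s: only non-detect measurements", food, chem)
    return detects


def mean_concentration(
    records: Sequence[OccurrenceRecord], food: str, chemical: str
) -> float:
    """Arithmetic mean of LB-substituted values for one food × chemical."""
    values = [
        (r.value if r.detected else 0.0)
        for r in records
        if r.food == food and r.chemical == chemical
    ]
    if not values:
        raise ValueError(f"no occurrence records for {food!r} x {chemical!r}")
    return float(np.mean(values))


def concentration_table(
    records: Sequence[OccurrenceRecord],
    food_categories: Mapping[str, str],
    rules: Sequence[SpeciationRule] | None = None,
) -> pd.DataFrame:
    """Per-food species-level mean concentrations, long format.

    Applies LB substitution, drops all-non-detect food × chemical pairs,
    averages, then converts total-element rows (As, Hg) to species
    concentrations using the food's category. Rows whose chemical is
    already a species (or not a speciated element) pass through.

    Returns a DataFrame with columns ``food``, ``chemical``, ``conc``.
    """
    if rules is None:
        rules = default_rules()
    retained = exclude_all_nondetect_foods(records)
    subbed = lb_substitute(records)
    rows = []
    for food, chem in sorted(retained):
        conc = mean_concentration(subbed, food, chem)
        category = food_categories.get(food, "other")
        if chem in ("As", "Hg"):
            for species, parent in SPECIES.items():
                if parent != chem:
                    continue
                sp_conc = speciated_concentration(conc, rules, species, category)
                if sp_conc > 0:
                    rows.append((food, species, sp_conc))
        else:
            rows.append((food, chem, conc))
    out = (
        pd.DataFrame(rows, columns=["food", "chemical", "conc"])
        .groupby(["food", "chemical"], as_index=False)["conc"]
        .sum()  # direct species measurements add to speciated totals
    )
    return out


def daily_exposure(
    individual: Individual,
    day: int,
    consumption: Sequence[ConsumptionRecord],
    conc: pd.DataFrame,
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """One individual-day exposure with its food breakdown.

    exposure_chem = Σ_foods (amount_g / 1000) × conc_µg_per_kg / body_weight

    Returns ``(per-chemical totals, {(food, chemical): contribution})``.
    Foods absent from the concentration table contribute nothing.
    """
    lookup = conc.set_index(["food", "chemical"])["conc"]
    totals: dict[str, float] = {}
    breakdown: dict[tuple[str, str], float] = {}
    for rec in consumption:
        if rec.individual != individual.id or rec.day != day:
            continue
        if rec.amount < 0:
            raise ValueError("negative consumption amount")
        if rec.food not in conc["food"].values:
            continue
        sub = lookup.loc[rec.food]
        for chem, c in sub.items():
            if c < 0:
                raise ValueError("negative concentration")
            contrib = (rec.amount / 1000.0) * c / individual.body_weight
            breakdown[(rec.food, chem)] = breakdown.get((rec.food, chem), 0.0) + contrib
            totals[chem] = totals.get(chem, 0.0) + contrib
    return totals, breakdown


class ExposureMatrix:
    """Individual-day × chemical exposures with food-level breakdown.

    ``entries`` is a DataFrame indexed by (individual, day) with one column
    per chemical; ``breakdown`` is long format with columns individual,
    day, food, chemical, exposure. Entries equal the sum of their food
    breakdown by construction. Externally modelled exposures (e.g. from a
    probabilistic exposure model) can be ingested with
    :meth:`from_entries`, in which case no breakdown is available.
    """

    def __init__(self, entries: pd.DataFrame, breakdown: pd.DataFrame | None = None):
        if (entries.values < 0).any():
            raise ValueError("exposure entries must be >= 0")
        self.entries = entries
        self.breakdown = breakdown

    @classmethod
    def compute(
        cls,
        individuals: Sequence[Individual],
        consumption: Sequence[ConsumptionRecord] | pd.DataFrame,
        conc: pd.DataFrame,
        days: Sequence[int] = (1, 2),
    ) -> "ExposureMatrix":
        """Vectorised exposure computation over the whole survey."""
        if not isinstance(consumption, pd.DataFrame):
            consumption = pd.DataFrame(
                [(r.individual, r.day, r.food, r.amount) for r in consumption],
                columns=["individual", "day", "food", "amount"],
            )
        bw = pd.DataFrame(
            [(i.id, i.body_weight) for i in individuals], columns=["individual", "bw"]
        )
        merged = consumption.merge(conc, on="food", how="inner").merge(bw, on="individual")
        merged["exposure"] = merged["amount"] / 1000.0 * merged["conc"] / merged["bw"]
        breakdown = (
            merged.groupby(["individual", "day", "food", "chemical"], as_index=False)[
                "exposure"
            ].sum()
        )
        chemicals = sorted(conc["chemical"].unique())
        grid = pd.MultiIndex.from_product(
            [[i.id for i in individuals], list(days)], names=["individual", "day"]
        )
        entries = (
            breakdown.pivot_table(
                index=["individual", "day"],
                columns="chemical",
                values="exposure",
                aggfunc="sum",
                fill_value=0.0,
            )
            .reindex(grid, fill_value=0.0)
            .reindex(columns=chemicals, fill_value=0.0)
            .astype(float)
        )
        entries.columns.name = None
        return cls(entries, breakdown)

    @classmethod
    def from_entries(cls, entries: pd.DataFrame) -> "ExposureMatrix":
        return cls(entries.astype(float), breakdown=None)

    @property
    def chemicals(self) -> list[str]:
        return list(self.entries.columns)

    @property
    def individuals(self) -> list[str]:
        return list(self.entries.index.get_level_values("individual").unique())

    def individual_mean(self) -> pd.DataFrame:
        """Per-individual mean exposure across survey days, per chemical."""
        return self.entries.groupby(level="individual").mean()

    def individual_mean_exposure(self, individual: str) -> pd.Series:
        means = self.individual_mean()
        if individual not in means.index:
            raise ValueError(f"unknown individual {individual!r}")
        return means.loc[individual]

    def mean_food_breakdown(self, ids: Iterable[str] | None = None) -> pd.DataFrame:
        """Mean exposure per food × chemical over all individual-days.

        Days without consumption of a food count as zero, so the mean is
        the summed contribution divided by the number of individual-days
        in the (optionally restricted) population.
        """
        if self.breakdown is None:
            raise ValueError("no food breakdown available (matrix ingested from entries)")
        bd = self.breakdown
        n_days = len(self.entries)
        if ids is not None:
            ids = set(ids)
            bd = bd[bd["individual"].isin(ids)]
            n_days = int(
                self.entries.index.get_level_values("individual").isin(ids).sum()
            )
        if n_days == 0:
            raise ValueError("empty population selection")
        out = bd.groupby(["food", "chemical"], as_index=False)["exposure"].sum()
        out["exposure"] = out["exposure"] / n_days
        return out
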