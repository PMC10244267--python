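"""Element-to-species conversion for occurrence data.

Monitoring data report total arsenic and total mercury, but toxicity is
species-specific (inorganic As, methyl mercury, inorganic mercury). Fixed
fractions per food category convert totals to the toxicologically relevant
species; rice is a pass-through for iAs because speciated measurements are
available there.

The inorganic-mercury fractions are a package assumption (complement of
the MeHg convention: 100% of total Hg in non-seafood foods, 20% in
crustaceans/mollusks, 0% in fish) and can be overridden via a rule file.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FOOD_CATEGORIES",
    "SPECIES",
    "SpeciationRule",
    "speciated_concentration",
    "load_rules",
    "default_rules",
]

FOOD_CATEGORIES = ("fish", "crustaceans_mollusks", "water", "rice", "other")
SPECIES = {"iAs": "As", "MeHg": "Hg", "iHg": "Hg"}


@dataclass(frozen=True)
class SpeciationRule:
    parent_element: str
    species: str
    food_category: str
    fraction: float
    passthrough: bool = False  # measured value already is the species

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if SPECIES[self.species] != self.parent_element:
            raise ValueError(
                f"species {self.species!r} does not derive from {self.parent_element!r}"
            )


def _find_rule(
    rules: Sequence[SpeciationRule], species: str, category: str
) -> SpeciationRule:
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    for rule in rules:
        if rule.species == species and rule.food_category == category:
            return rule
    if category != "other":
        # unmatched categories fall into the residual rule
        return _find_rule(rules, species, "other")
    raise ValueError(f"no speciation rule for species {species!r}")


def speciated_concentration(
    total: float,
    rule_set: Sequence[SpeciationRule],
    species: str,
    category: str,
) -> float:
    """Species concentration (µg/kg) from a total-element concentration.

    Pass-through rules (speciated measurement, e.g. iAs in rice) return
    the measured value unchanged.
    """
    if total < 0:
        raise ValueError(f"total concentration must be >= 0, got {total}")
    rule = _find_rule(rule_set, species, category)
    if rule.passthrough:
        return total
    return total * rule.fraction


def load_rules(path) -> list[SpeciationRule]:
    """Rule TSV: parent_element, species, food_category, fraction, passthrough."""
    df = pd.read_csv(path, sep="\t")
    rules = [
        SpeciationRule(
            parent_element=row.parent_element,
            species=row.species,
            food_category=row.food_category,
            fraction=float(row.fraction),
            passthrough=bool(int(getattr(row, "passthrough", 0))),
        )
        for row in df.itertuples(index=False)
    ]
    _validate(rules)
    return rules


def _validate(rules: Iterable[SpeciationRule]) -> None:
    sums: dict[tuple[str, str], float] = {}
    for r in rules:
        if not r.passthrough:
            key = (r.parent_element, r.food_category)
            sums[key] = sums.get(key, 0.0) + r.fraction
    for (elem, cat), s in sums.items():
        if s > 1 + 1e-9:
            raise ValueError(
                f"species fractions for {elem} in {cat!r} sum to {s} > 1"
            )


def default_rules() -> list[SpeciationRule]:
    """Shipped default rule set (iAs and MeHg fractions per food category)."""
    with resources.files("cumrisk.data").joinpath("speciation_default.tsv").open() as fh:
        return load_rules(fh)
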