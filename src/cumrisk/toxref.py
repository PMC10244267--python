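"""Toxicological reference values for mixture risk assessment.

Encodes points of departure (NOAEL, LOAEL, BMDL, TWI, or pre-derived
tolerable doses) together with their assessment-factor chains, derives
health-based guidance values (HBGV, here equal to the tolerable daily
intake) and, from those, relative potency factors (RPF) anchored to an
index chemical — the chemical with the lowest effective dose, lead for
every endpoint shipped with this package.

All arithmetic is carried at full floating-point precision; rounding to
the display precision used in reports (2 significant figures for RPFs)
happens only through :func:`round_sig` at render time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ENDPOINTS",
    "ROUTES",
    "POD_TYPES",
    "AssessmentFactor",
    "ToxRecord",
    "HBGV",
    "RPFTable",
    "convert_route",
    "apply_assessment_factors",
    "weekly_to_daily",
    "derive_hbgv",
    "average_hbgv",
    "derive_rpf",
    "endpoint_hbgvs",
    "round_sig",
    "load_tox_records",
    "builtin_records",
]

ENDPOINTS = ("neuro6", "neuro_dtu", "kidney", "fertility")
ROUTES = ("oral", "intraperitoneal")
#: TWI doses are per week and are divided by 7 during derivation; DTD doses
#: are already lifetime-safe daily doses and pass through unchanged.
POD_TYPES = ("NOAEL", "LOAEL", "BMDL01", "BMDL05", "TWI", "DTD")


@dataclass(frozen=True)
class AssessmentFactor:
    """A single uncertainty/assessment factor (≥ 1) with its reason."""

    value: float
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.value >= 1:
            raise ValueError(
                f"assessment factor must be >= 1 (factors only shrink the dose), got {self.value}"
            )


@dataclass(frozen=True)
class ToxRecord:
    """A chemical × endpoint point of departure with its factor chain.

    ``pod_value`` is in µg/kg bw/d, except for ``pod_type == 'TWI'`` where
    it is µg/kg bw/week. ``oral_bioavailability`` is only consulted for
    non-oral routes. NOAEL is treated as equivalent to BMDL10 (metadata
    only; no numerical adjustment is applied).
    """

    chemical: str
    endpoint: str
    species: str
    effect_class: str  # "A" developmental neurotoxicity/cognition, "B" neuropathy
    pod_value: float
    pod_type: str
    assessment_factors: tuple[AssessmentFactor, ...] = ()
    route: str = "oral"
    oral_bioavailability: float | None = None

    def __post_init__(self) -> None:
        if not self.pod_value > 0:
            raise ValueError(f"pod_value must be > 0, got {self.pod_value}")
        if self.pod_type not in POD_TYPES:
            raise ValueError(f"unknown pod_type {self.pod_type!r}")
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.oral_bioavailability is not None and not (
            0 < self.oral_bioavailability <= 1
        ):
            raise ValueError(
                f"oral_bioavailability must be in (0, 1], got {self.oral_bioavailability}"
            )


@dataclass(frozen=True)
class HBGV:
    """Health-based guidance value (µg/kg bw/d) with derivation provenance."""

    chemical: str
    endpoint: str
    value: float
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"HBGV must be > 0, got {self.value}")


@dataclass(frozen=True)
class RPFTable:
    """Endpoint-specific relative potencies anchored to an index chemical.

    ``rpf[index_chemical]`` is exactly 1; every other entry equals
    HBGV[index] / HBGV[chemical] at full precision.
    """

    endpoint: str
    index_chemical: str
    rpf: Mapping[str, float]
    rounding_digits: int = 2  # significant figures used at report time

    def __post_init__(self) -> None:
        if self.index_chemical not in self.rpf:
            raise ValueError(f"index chemical {self.index_chemical!r} missing from table")
        if self.rpf[self.index_chemical] != 1.0:
            raise ValueError("rpf of the index chemical must be exactly 1")
        for chem, value in self.rpf.items():
            if not value > 0:
                raise ValueError(f"rpf[{chem!r}] must be > 0, got {value}")

    @property
    def chemicals(self) -> tuple[str, ...]:
        return tuple(self.rpf)

    def __getitem__(self, chemical: str) -> float:
        return self.rpf[chemical]

    def __contains__(self, chemical: str) -> bool:
        return chemical in self.rpf

    def rounded(self) -> dict[str, float]:
        """Display version, rounded to ``rounding_digits`` significant figures."""
        return {c: round_sig(v, self.rounding_digits) for c, v in self.rpf.items()}


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def convert_route(pod: float, route: str, oral_bioavailability: float | None = None) -> float:
    """Convert a point of departure to an equivalent oral dose.

    An intraperitoneal dose (assumed 100% bioavailable) corresponds to the
    oral dose whose absorbed amount matches it, i.e. pod / fraction.
    """
    if not pod > 0:
        raise ValueError(f"pod must be > 0, got {pod}")
    if route == "oral":
        return pod
    if route == "intraperitoneal":
        if oral_bioavailability is None:
            raise ValueError("oral_bioavailability required for intraperitoneal route")
        if not 0 < oral_bioavailability <= 1:
            raise ValueError(
                f"oral_bioavailability must be in (0, 1], got {oral_bioavailability}"
            )
        return pod / oral_bioavailability
    raise ValueError(f"unknown route {route!r}")


def apply_assessment_factors(
    dose: float, factors: Sequence[AssessmentFactor | float]
) -> tuple[float, tuple[str, ...]]:
    """Divide ``dose`` by the product of the factors; return (dose, steps)."""
    if not dose > 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    steps: list[str] = []
    out = dose
    for f in factors:
        if not isinstance(f, AssessmentFactor):
            f = AssessmentFactor(float(f))
        out = out / f.value
        reason = f" ({f.reason})" if f.reason else ""
        steps.append(f"/{f.value:g}{reason}")
    return out, tuple(steps)


def weekly_to_daily(twi: float) -> float:
    """Convert a tolerable weekly intake to the daily dose (÷ 7)."""
    if not twi > 0:
        raise ValueError(f"TWI must be > 0, got {twi}")
    return twi / 7.0


def derive_hbgv(record: ToxRecord) -> HBGV:
    """Derive the HBGV from a point of departure.

    Route conversion first, then division by the assessment-factor chain;
    a TWI is additionally divided by 7 to the daily dose. A DTD passes
    through (it is already a lifetime-safe daily dose).
    """
    steps: list[str] = [f"{record.pod_type} {record.pod_value:g} ({record.route})"]
    dose = record.pod_value
    if record.route != "oral":
        dose = convert_route(dose, record.route, record.oral_bioavailability)
        steps.append(
            f"route {record.route}->oral /{record.oral_bioavailability:g} -> {dose:g}"
        )
    if record.pod_type == "TWI":
        dose = weekly_to_daily(dose)
        steps.append(f"TWI/7 -> {dose:g}")
    dose, factor_steps = apply_assessment_factors(dose, record.assessment_factors)
    steps.extend(factor_steps)
    steps.append(f"HBGV {dose:g}")
    return HBGV(record.chemical, record.endpoint, dose, tuple(steps))


def average_hbgv(candidates: Sequence[HBGV]) -> HBGV:
    """Arithmetic mean of candidate HBGVs for one chemical × endpoint."""
    if not candidates:
        raise ValueError("need at least one candidate HBGV")
    chems = {c.chemical for c in candidates}
    endpoints = {c.endpoint for c in candidates}
    if len(chems) != 1 or len(endpoints) != 1:
        raise ValueError(
            f"cannot average across chemicals/endpoints: {sorted(chems)}, {sorted(endpoints)}"
        )
    if len(candidates) == 1:
        return candidates[0]
    value = sum(c.value for c in candidates) / len(candidates)
    prov = tuple(
        f"candidate {i + 1}: " + " | ".join(c.provenance) for i, c in enumerate(candidates)
    ) + (f"average of {len(candidates)} candidates -> {value:g}",)
    return HBGV(candidates[0].chemical, candidates[0].endpoint, value, prov)


def derive_rpf(hbgvs: Sequence[HBGV], index_chemical: str, rounding_digits: int = 2) -> RPFTable:
    """RPF table from HBGVs: rpf[i] = HBGV[index] / HBGV[i], index exactly 1."""
    chems = [h.chemical for h in hbgvs]
    if len(set(chems)) != len(chems):
        raise ValueError(f"duplicate chemical in HBGV list: {chems}")
    endpoints = {h.endpoint for h in hbgvs}
    if len(endpoints) != 1:
        raise ValueError(f"HBGVs span multiple endpoints: {sorted(endpoints)}")
    by_chem = {h.chemical: h for h in hbgvs}
    if index_chemical not in by_chem:
        raise ValueError(f"index chemical {index_chemical!r} not among HBGVs")
    anchor = by_chem[index_chemical].value
    rpf = {
        chem: 1.0 if chem == index_chemical else anchor / h.value
        for chem, h in by_chem.items()
    }
    return RPFTable(endpoints.pop(), index_chemical, rpf, rounding_digits)


def endpoint_hbgvs(records: Iterable[ToxRecord], endpoint: str) -> dict[str, HBGV]:
    """Derive one HBGV per chemical for ``endpoint``.

    Records sharing a chemical (e.g. a NOAEL and a LOAEL track for the
    same study) are derived separately and averaged.
    """
    per_chem: dict[str, list[HBGV]] = {}
    for rec in records:
        if rec.endpoint != endpoint:
            continue
        per_chem.setdefault(rec.chemical, []).append(derive_hbgv(rec))
    if not per_chem:
        raise ValueError(f"no records for endpoint {endpoint!r}")
    return {chem: average_hbgv(cands) for chem, cands in per_chem.items()}


# ---------------------------------------------------------------------------
# I/O

def _parse_factors(cell: str) -> tuple[AssessmentFactor, ...]:
    if not cell or (isinstance(cell, float) and math.isnan(cell)):
        return ()
    out = []
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            value, reason = part.split(":", 1)
        else:
            value, reason = part, ""
        out.append(AssessmentFactor(float(value), reason.strip()))
    return tuple(out)


def load_tox_records(path) -> list[ToxRecord]:
    """Read a toxicology reference TSV into validated records.

    Columns: chemical, endpoint, species, effect_class, pod_value_ug_kg_bw_d,
    pod_type, route, oral_bioavailability, factors (``value:reason`` pairs,
    semicolon-separated).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        bio = getattr(row, "oral_bioavailability", "")
        records.append(
            ToxRecord(
                chemical=row.chemical,
                endpoint=row.endpoint,
                species=row.species,
                effect_class=row.effect_class,
                pod_value=float(row.pod_value_ug_kg_bw_d),
                pod_type=row.pod_type,
                assessment_factors=_parse_factors(getattr(row, "factors", "")),
                route=row.route or "oral",
                oral_bioavailability=float(bio) if bio else None,
            )
        )
    return records


def builtin_records(which: str = "all") -> list[ToxRecord]:
    """Shipped reference tables.

    ``"neuro6"``: the six-chemical neurotoxicity assessment (PODs with
    factor chains). ``"dtd"``: derived tolerable doses for the cognition,
    kidney and fertility endpoints. ``"all"``: both.
    """
    names = {"neuro6": ["tox_neuro6.tsv"], "dtd": ["tox_dtd.tsv"],
             "all": ["tox_neuro6.tsv", "tox_dtd.tsv"]}
    if which not in names:
        raise ValueError(f"unknown reference table {which!r}")
    records: list[ToxRecord] = []
    for fname in names[which]:
        with resources.files("cumrisk.data").joinpath(fname).open() as fh:
            records.extend(load_tox_records(fh))
    return records
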