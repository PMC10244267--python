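"""Full assessment workflow: reference values → exposure → risk reports.

Chains the stages — HBGV/RPF derivation, speciation, lower-bound
exposure, cumulative risk per endpoint, source attribution and
demographic contrasts — and writes a deterministic report bundle of tidy
CSV tables, a JSON summary and a provenance log of every HBGV
derivation step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .attribution import food_group_contribution
from .compare import (
    ComparisonResult,
    GroupDef,
    assign_weight_quartiles,
    compare_groups,
    quartile_boundaries,
    welch_t_test,
)
from .cumulative import (
    chemical_contribution_shares,
    cumulative_exposure_series,
    exceedance_fraction,
    format_share,
)
from .exposure import (
    ConsumptionRecord,
    ExposureMatrix,
    Individual,
    OccurrenceRecord,
    concentration_table,
)
from .speciation import default_rules, load_rules
from .synthetic import SyntheticSurvey, default_config, generate_survey
from .toxref import ENDPOINTS, HBGV, RPFTable, builtin_records, derive_rpf, endpoint_hbgvs

__all__ = ["RunConfig", "AssessmentReport", "run_assessment", "load_survey_csv", "endpoint_tables"]

logger = logging.getLogger("cumrisk")

AGE_DECADES = ((25, 34), (35, 44), (45, 54), (55, 64), (65, 74))
AGE_STRATA = ((25, 45), (46, 64), (65, 74))
SOURCE_STRATA = ((25, 64), (65, 74))


@dataclass
class RunConfig:
    """Inputs and switches for one assessment run.

    Either the four CSV paths are given, or ``synthetic_n`` requests a
    generated survey (seeded). ``observation_unit`` selects day-level
    (survey convention: each study day is one data point) or
    individual-mean observations for the statistical contrasts.
    """

    outdir: Path | str = "results"
    consumption: Path | str | None = None
    individuals: Path | str | None = None
    occurrence: Path | str | None = None
    food_groups: Path | str | None = None
    speciation_rules: Path | str | None = None
    synthetic_n: int | None = None
    seed: int = 0
    endpoints: tuple[str, ...] = ENDPOINTS
    observation_unit: str = "day"

    def __post_init__(self) -> None:
        if self.observation_unit not in ("day", "individual"):
            raise ValueError(f"unknown observation unit {self.observation_unit!r}")
        paths = [self.consumption, self.individuals, self.occurrence, self.food_groups]
        if self.synthetic_n is None:
            missing = [p for p in paths if p is None]
            if missing:
                raise ValueError("either synthetic_n or all four input CSV paths are required")
            for p in paths + ([self.speciation_rules] if self.speciation_rules else []):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        unknown = set(self.endpoints) - set(ENDPOINTS)
        if unknown:
            raise ValueError(f"unknown endpoints {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "endpoints" in raw:
            raw["endpoints"] = tuple(raw["endpoints"])
        return cls(**raw)


def load_survey_csv(
    consumption: Path | str,
    individuals: Path | str,
    occurrence: Path | str,
    food_groups: Path | str,
):
    """Read the survey CSV schemas into validated in-memory objects."""
    ind_df = pd.read_csv(individuals)
    inds = [
        Individual(str(r.id), float(r.age), str(r.gender), float(r.weight_kg))
        for r in ind_df.itertuples(index=False)
    ]
    cons_df = pd.read_csv(consumption).rename(
        columns={"individual_id": "individual", "food_id": "food", "grams": "amount"}
    )
    occ_df = pd.read_csv(occurrence)
    occ = [
        OccurrenceRecord(
            str(r.food_id),
            str(r.chemical),
            None if not int(r.detected) else float(r.value_ug_kg),
            float(r.loq_ug_kg),
            bool(int(r.detected)),
        )
        for r in occ_df.itertuples(index=False)
    ]
    fmap = pd.read_csv(food_groups)
    groups = dict(zip(fmap["food_id"].astype(str), fmap["group"]))
    categories = (
        dict(zip(fmap["food_id"].astype(str), fmap["category"]))
        if "category" in fmap.columns
        else {}
    )
    return inds, cons_df, occ, categories, groups


def endpoint_tables(
    endpoints: Sequence[str] = ENDPOINTS,
) -> dict[str, tuple[RPFTable, dict[str, HBGV]]]:
    """Derive (RPF table, HBGV set) for each requested endpoint from the
    shipped reference tables; lead is the index chemical throughout."""
    records = builtin_records("all")
    out = {}
    for ep in endpoints:
        hbgvs = endpoint_hbgvs(records, ep)
        out[ep] = (derive_rpf(list(hbgvs.values()), "Pb"), hbgvs)
    return out


def _age_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def _age_groups(
    individuals: Sequence[Individual], bands: Sequence[tuple[int, int]]
) -> dict[str, dict[str, list[str]]]:
    """gender → age-band label → ids."""
    out: dict[str, dict[str, list[str]]] = {}
    for ind in individuals:
        for lo, hi in bands:
            if lo <= ind.age <= hi:
                out.setdefault(ind.gender, {}).setdefault(_age_label(lo, hi), []).append(ind.id)
                break
    return out


@dataclass
class AssessmentReport:
    rpf_hbgv: pd.DataFrame
    hi_by_group: pd.DataFrame
    exceedance: pd.DataFrame
    chemical_shares: pd.DataFrame
    source_shares: pd.DataFrame
    contrasts: pd.DataFrame
    provenance: list[str]
    summary: dict
    matrix: ExposureMatrix = field(repr=False, default=None)

    def write(self, outdir: Path | str) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        tables = {
            "rpf_hbgv": self.rpf_hbgv,
            "hi_by_group": self.hi_by_group,
            "exceedance": self.exceedance,
            "chemical_shares": self.chemical_shares,
            "source_shares": self.source_shares,
            "contrasts": self.contrasts,
        }
        for name, df in tables.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = p
        p = outdir / "provenance.txt"
        p.write_text("\n".join(self.provenance) + "\n")
        paths["provenance"] = p
        p = outdir / "summary.json"
        p.write_text(json.dumps(self.summary, indent=2, sort_keys=True) + "\n")
        paths["summary"] = p
        return paths


def run_assessment(config: RunConfig) -> AssessmentReport:
    """Run the whole assessment and return the report bundle.

    Deterministic: the same config (and seed, for synthetic input)
    produces byte-identical report files.
    """
    # --- inputs -----------------------------------------------------------
    if config.synthetic_n is not None:
        logger.info("generating synthetic survey (n=%d, seed=%d)", config.synthetic_n, config.seed)
        survey = generate_survey(default_config(seed=config.seed, n_individuals=config.synthetic_n))
        individuals, occurrence = survey.individuals, survey.occurrence
        consumption = pd.DataFrame(
            [(c.individual, c.day, c.food, c.amount) for c in survey.consumption],
            columns=["individual", "day", "food", "amount"],
        )
        categories, groups = survey.food_categories, survey.food_groups
        n_days = survey.config.n_days
    else:
        individuals, consumption, occurrence, categories, groups = load_survey_csv(
            config.consumption, config.individuals, config.occurrence, config.food_groups
        )
        n_days = int(consumption["day"].max()) if len(consumption) else 1
    rules = load_rules(config.speciation_rules) if config.speciation_rules else default_rules()

    # --- reference values -------------------------------------------------
    endpoints = endpoint_tables(config.endpoints)
    provenance: list[str] = []
    rpf_rows = []
    for ep, (rpf, hbgvs) in endpoints.items():
        rounded = rpf.rounded()
        for chem in sorted(hbgvs):
            provenance.append(f"{ep} {chem}: " + " | ".join(hbgvs[chem].provenance))
            rpf_rows.append((ep, chem, hbgvs[chem].value, rpf[chem], rounded[chem]))
    rpf_hbgv = pd.DataFrame(
        rpf_rows, columns=["endpoint", "chemical", "hbgv_ug_kg_bw_d", "rpf", "rpf_rounded"]
    )

    # --- exposure ---------------------------------------------------------
    conc = concentration_table(occurrence, categories, rules)
    matrix = ExposureMatrix.compute(individuals, consumption, conc, days=range(1, n_days + 1))
    ind_means = matrix.individual_mean()
    by_id = {i.id: i for i in individuals}

    # --- per-endpoint summaries ------------------------------------------
    decades = _age_groups(individuals, AGE_DECADES)
    hi_rows, exc_rows, share_rows, src_rows = [], [], [], []
    summary: dict = {"n_individuals": len(individuals), "endpoints": {}}
    for ep, (rpf, hbgvs) in endpoints.items():
        hv_index = hbgvs[rpf.index_chemical].value
        cum_ind = cumulative_exposure_series(ind_means, rpf)
        hi_ind = cum_ind / hv_index
        for gender in sorted(decades):
            for label in sorted(decades[gender]):
                ids = decades[gender][label]
                hi_rows.append(
                    (
                        ep,
                        gender,
                        label,
                        float(cum_ind.loc[ids].mean()),
                        float(hi_ind.loc[ids].mean()),
                        len(ids),
                    )
                )
                exc_rows.append(
                    (ep, gender, label, 100.0 * exceedance_fraction(list(hi_ind.loc[ids])))
                )
        mean_exp = {
            c: float(ind_means[c].mean()) for c in rpf.chemicals if c in ind_means.columns
        }
        shares = chemical_contribution_shares(mean_exp, rpf)
        for chem in sorted(shares):
            share_rows.append((ep, chem, shares[chem], format_share(shares[chem])))
        for lo, hi in SOURCE_STRATA:
            ids = [i.id for i in individuals if lo <= i.age <= hi]
            if not ids:
                continue
            contrib = food_group_contribution(
                matrix.mean_food_breakdown(ids), rpf, groups, stratum=_age_label(lo, hi)
            )
            for grp in sorted(contrib.group_shares):
                src_rows.append((ep, contrib.population_stratum, grp, contrib.group_shares[grp]))
        summary["endpoints"][ep] = {
            "mean_cumulative_exposure": round(float(cum_ind.mean()), 6),
            "mean_hazard_index": round(float(hi_ind.mean()), 4),
            "pct_hi_above_1": round(100.0 * exceedance_fraction(list(hi_ind)), 2),
            "index_chemical": rpf.index_chemical,
            "index_hbgv": hv_index,
        }

    # --- contrasts --------------------------------------------------------
    quartiles = assign_weight_quartiles(individuals)
    q1_ids = [i for i, q in quartiles.items() if q == "Q1"]
    q4_ids = [i for i, q in quartiles.items() if q == "Q4"]
    contrast_pairs = [
        (
            GroupDef.from_filter(individuals, "women 25-45", gender="female", age_min=25, age_max=45),
            GroupDef.from_filter(individuals, "men 25-45", gender="male", age_min=25, age_max=45),
        ),
        (
            GroupDef.from_filter(individuals, "women 25-45", gender="female", age_min=25, age_max=45),
            GroupDef.from_filter(individuals, "women 46-64", gender="female", age_min=46, age_max=64),
        ),
        (GroupDef("weight Q1", frozenset(q1_ids)), GroupDef("weight Q4", frozenset(q4_ids))),
    ]
    contrast_pairs = [(a, b) for a, b in contrast_pairs if a.ids and b.ids]
    results = compare_groups(matrix, contrast_pairs, endpoints, config.observation_unit)
    rows = []
    for ga, gb in contrast_pairs:
        wa = [by_id[i].body_weight for i in sorted(ga.ids)]
        wb = [by_id[i].body_weight for i in sorted(gb.ids)]
        t, dof, p = welch_t_test(wa, wb)
        rows.append(
            (
                "body_weight_kg",
                ga.label,
                gb.label,
                float(pd.Series(wa).mean()),
                float(pd.Series(wb).mean()),
                "",
                "",
                t,
                dof,
                p,
                len(wa),
                len(wb),
            )
        )
    for r in results:
        rows.append(
            (
                r.endpoint,
                r.group_a,
                r.group_b,
                r.mean_a,
                r.mean_b,
                r.hi_a,
                r.hi_b,
                r.t_statistic,
                r.dof,
                r.p_value,
                r.n_a,
                r.n_b,
            )
        )
    contrasts = pd.DataFrame(
        rows,
        columns=[
            "endpoint",
            "group_a",
            "group_b",
            "mean_a",
            "mean_b",
            "hi_a",
            "hi_b",
            "t",
            "dof",
            "p",
            "n_a",
            "n_b",
        ],
    )
    q1b, q2b, q3b = quartile_boundaries(individuals)
    summary["weight_quartile_boundaries_kg"] = [round(q1b, 2), round(q2b, 2), round(q3b, 2)]
    summary["observation_unit"] = config.observation_unit
    if config.observation_unit == "day":
        summary["note"] = (
            "day-level observations treat the two survey days of one person "
            "as independent; individual-mean observations are available via "
            "observation_unit=individual"
        )

    return AssessmentReport(
        rpf_hbgv=rpf_hbgv,
        hi_by_group=pd.DataFrame(
            hi_rows, columns=["endpoint", "gender", "age_group", "mean_cumexp", "mean_hi", "n"]
        ),
        exceedance=pd.DataFrame(
            exc_rows, columns=["endpoint", "gender", "age_group", "pct_hi_above_1"]
        ),
        chemical_shares=pd.DataFrame(
            share_rows, columns=["endpoint", "chemical", "share_pct", "share_display"]
        ),
        source_shares=pd.DataFrame(
            src_rows, columns=["endpoint", "stratum", "food_group", "share_pct"]
        ),
        contrasts=contrasts,
        provenance=provenance,
        summary=summary,
        matrix=matrix,
    )
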