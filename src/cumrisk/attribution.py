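"""Source attribution: which food groups drive the cumulative exposure.

The RPF-weighted mean exposure per food is aggregated to reporting food
groups (cereal products, non-alcoholic drinks, vegetables, fruit and
berries, dairy, fish, meat, others) and expressed as percent shares of
the total cumulative exposure for a population stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .toxref import RPFTable

__all__ = ["DEFAULT_FOOD_GROUPS", "SourceContribution", "food_group_contribution"]

DEFAULT_FOOD_GROUPS = (
    "cereal products",
    "non-alcoholic drinks",
    "vegetables",
    "fruit and berries",
    "dairy",
    "fish",
    "meat",
    "others",
)


@dataclass(frozen=True)
class SourceContribution:
    endpoint: str
    group_shares: Mapping[str, float]  # percent, sums to 100
    population_stratum: str = "all"

    def __post_init__(self) -> None:
        total = sum(self.group_shares.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"shares must sum to 100, got {total}")
        if any(s < 0 for s in self.group_shares.values()):
            raise ValueError("shares must be >= 0")


def food_group_contribution(
    breakdown: pd.DataFrame,
    rpf: RPFTable,
    grouping: Mapping[str, str],
    stratum: str = "all",
) -> SourceContribution:
    """Percent share of each food group in the cumulative exposure.

    ``breakdown`` has columns food, chemical, exposure (mean exposure per
    individual-day for the stratum). Chemicals without an RPF in this
    endpoint are not part of its assessment group and are dropped; foods
    missing from ``grouping`` fall into "others".
    """
    bd = breakdown[breakdown["chemical"].isin(rpf.chemicals)].copy()
    if bd.empty:
        raise ValueError("no breakdown rows for this endpoint's chemicals")
    bd["weighted"] = bd.apply(lambda r: rpf[r["chemical"]] * r["exposure"], axis=1)
    bd["group"] = bd["food"].map(lambda f: grouping.get(f, "others"))
    per_group = bd.groupby("group")["weighted"].sum()
    total = per_group.sum()
    if total <= 0:
        raise ValueError("total cumulative exposure is zero; shares undefined")
    shares = (100.0 * per_group / total).to_dict()
    return SourceContribution(rpf.endpoint, shares, stratum)


def plot_source_shares(contributions, path) -> None:
    """Optional stacked-bar export of source contributions (one bar per
    endpoint/stratum). Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{c.endpoint}\n{c.population_stratum}" for c in contributions]
    groups = sorted({g for c in contributions for g in c.group_shares})
    fig, ax = plt.subplots(figsize=(1.5 * len(labels) + 2, 5))
    bottom = [0.0] * len(labels)
    for g in groups:
        vals = [c.group_shares.get(g, 0.0) for c in contributions]
        ax.bar(labels, vals, bottom=bottom, label=g)
        bottom = [b + v for b, v in zip(bottom, vals)]
    ax.set_ylabel("share of cumulative exposure (%)")
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
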