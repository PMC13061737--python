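"""Objective evaluation for candidate diets.

A candidate diet is scored on three axes:

* economic cost  C(Q) = sum_i Q_i * R_i / 1000   ($/person/day; R_i $/kg)
* emissions      E(Q) = sum_i Q_i * EF_i / 1000  (kg CO2e/person/day)
* nutrition      capped-min adequacy over the scenario's priority nutrients

plus a quadratic nutrient-deficit penalty.  Deficits are
d_j = max(0, RDA_j - supply_j); by default they are normalized by the RDA
before squaring so micrograms of B12 and grams of protein contribute on the
same dimensionless scale (the raw sum of squared deficits is available for
comparison via ``normalized=False``).

All operations take an item table: a DataFrame indexed by item id with
``producer_price``, ``emission_factor``, ``category`` and per-100 g nutrient
columns.  Items may be raw commodities or pre-aggregated ASF categories; the
algebra is identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dietopt.constants import ASF_CATEGORIES, NUTRIENTS, TRACKED_NUTRIENTS


@dataclass
class DietVector:
    """Daily intakes (g/person/day): searched ASF part + fixed plant part."""

    asf: dict[str, float]
    plant_background: dict[str, float] = field(default_factory=dict)

    def items(self) -> dict[str, float]:
        merged = dict(self.plant_background)
        for k, v in self.asf.items():
            merged[k] = merged.get(k, 0.0) + v
        return merged

    def validate(self) -> None:
        for k, v in self.items().items():
            if v < 0:
                raise ValueError(f"negative intake for {k}")


@dataclass
class ObjectiveValues:
    cost: float            # $/person/day
    emissions: float       # kg CO2e/person/day
    nutrition_score: float  # dimensionless in [0, 1]
    penalty: float = 0.0   # dimensionless >= 0
    violation: float = 0.0  # energy/protein constraint violation measure


@dataclass
class NutrientAdequacy:
    supply: dict[str, float]
    ratio: dict[str, float]    # supply / RDA
    deficits: dict[str, float]  # max(0, RDA - supply)
    rda: dict[str, float]


def _item_value(table: pd.DataFrame, item: str, column: str) -> float:
    try:
        val = float(table.at[item, column])
    except KeyError:
        raise KeyError(f"item {item!r} missing from table column {column!r}")
    if math.isnan(val):
        raise ValueError(f"item {item!r} has missing {column!r}")
    return val


def dietary_cost(Q: DietVector, table: pd.DataFrame) -> float:
    """Daily dietary cost in $: intakes (g) x producer prices ($/kg) / 1000."""
    return sum(
        q * _item_value(table, item, "producer_price") / 1000.0
        for item, q in Q.items().items()
    )


def dietary_emissions(Q: DietVector, table: pd.DataFrame) -> float:
    """Daily emissions in kg CO2e: intakes (g) x factors (kg/kg) / 1000."""
    return sum(
        q * _item_value(table, item, "emission_factor") / 1000.0
        for item, q in Q.items().items()
    )


def nutrient_supply_and_adequacy(
    Q: DietVector, table: pd.DataFrame, rda: dict[str, float]
) -> NutrientAdequacy:
    """Per-nutrient supply, adequacy ratio, and deficit of a diet.

    Densities are per 100 g, so supply_j = sum_i Q_i * N_ij / 100; plant
    background intakes contribute alongside the searched ASF part.
    """
    supply = {nut: 0.0 for nut in NUTRIENTS if nut in table.columns}
    for item, q in Q.items().items():
        for nut in supply:
            supply[nut] += q * _item_value(table, item, nut) / 100.0
    ratio = {nut: supply[nut] / rda[nut] for nut in rda if nut in supply}
    deficits = {
        nut: max(0.0, rda[nut] - supply[nut]) for nut in rda if nut in supply
    }
    return NutrientAdequacy(supply=supply, ratio=ratio, deficits=deficits,
                            rda={n: rda[n] for n in rda if n in supply})


def penalty(
    adequacy: NutrientAdequacy, scale: float = 1.0, normalized: bool = True
) -> float:
    """Quadratic deficit penalty: scale x sum_j (d_j / RDA_j)^2.

    Zero exactly when every tracked RDA is met.  ``normalized=False`` gives
    the raw sum of squared deficits (unit-inconsistent across nutrients but
    kept for fidelity comparisons).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    total = 0.0
    for nut, d in adequacy.deficits.items():
        total += (d / adequacy.rda[nut]) ** 2 if normalized else d**2
    return scale * total


def nutrition_objective(adequacy: NutrientAdequacy, spec) -> float:
    """Capped-min adequacy score over the scenario's priority nutrients.

    score = min_j min(ratio_j, 1) over the priority set; baseline scenarios
    (empty priority set) use all four tracked nutrients.  The cap prevents an
    oversupplied nutrient from masking a deficit elsewhere.
    """
    priority = tuple(getattr(spec, "priority_nutrients", ()) or TRACKED_NUTRIENTS)
    missing = [n for n in priority if n not in adequacy.ratio]
    if missing:
        raise ValueError(f"adequacy lacks priority nutrients: {missing}")
    if not adequacy.ratio:
        raise ValueError("empty adequacy")
    return min(min(adequacy.ratio[n], 1.0) for n in priority)


def animal_protein_share(Q: DietVector, table: pd.DataFrame) -> float:
    """Fraction of total protein supplied by animal-source foods."""
    asf = set(ASF_CATEGORIES)
    animal = total = 0.0
    for item, q in Q.items().items():
        p = q * _item_value(table, item, "protein") / 100.0
        total += p
        if str(table.at[item, "category"]) in asf:
            animal += p
    if total <= 0:
        raise ValueError("total protein is zero")
    return animal / total


def excess_over_reference(total: float, reference: float) -> float:
    """Percentage excess of an intake over a reference, 100*(x-ref)/ref."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (total - reference) / reference


# ---------------------------------------------------------------------------
# Category aggregation: 8-dimensional decision space over a commodity table
# ---------------------------------------------------------------------------

def diet_to_vector(diet, table: pd.DataFrame) -> DietVector:
    """Split a harmonized commodity diet into ASF and plant-background parts."""
    asf_set = set(ASF_CATEGORIES)
    asf: dict[str, float] = {}
    plant: dict[str, float] = {}
    for cid, q in diet.intakes.items():
        if str(table.at[cid, "category"]) in asf_set:
            asf[cid] = q
        else:
            plant[cid] = q
    return DietVector(asf=asf, plant_background=plant)


def category_table(table: pd.DataFrame, baseline_diet) -> pd.DataFrame:
    """Aggregate commodities into the 8 ASF decision categories.

    Within each category, coefficients (price, emission factor, nutrient
    densities) are weighted by the baseline diet's within-category intake
    shares, so a category intake of Q grams is distributed over member
    commodities exactly as the guideline diet distributes it.  Plant
    commodities pass through unchanged.
    """
    rows = []
    value_cols = ["producer_price", "emission_factor", *[
        n for n in NUTRIENTS if n in table.columns
    ]]
    for cat in ASF_CATEGORIES:
        members = table.index[table["category"] == cat]
        if len(members) == 0:
            continue
        weights = np.array([
            baseline_diet.intakes.get(cid, 0.0) for cid in members
        ], dtype=float)
        if weights.sum() <= 0:
            weights = np.ones(len(members))
        weights = weights / weights.sum()
        sub = table.loc[members, value_cols].to_numpy(dtype=float)
        agg = weights @ sub
        row = dict(zip(value_cols, agg))
        row.update(item_id=cat, category=cat, name=cat)
        rows.append(row)
    for cid in table.index[table["category"] == "plant_group"]:
        row = {c: float(table.at[cid, c]) for c in value_cols}
        row.update(item_id=cid, category="plant_group",
                   name=str(table.at[cid, "name"]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("item_id")


def baseline_category_intakes(diet, table: pd.DataFrame) -> dict[str, float]:
    """Total baseline intake per ASF category (g/person/day)."""
    out = {cat: 0.0 for cat in ASF_CATEGORIES}
    for cid, q in diet.intakes.items():
        cat = str(table.at[cid, "category"])
        if cat in out:
            out[cat] += q
    return out
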