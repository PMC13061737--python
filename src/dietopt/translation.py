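"""FBDG-to-commodity translation.

Food-based dietary guidelines recommend intakes for broad food groups
("red meat", "grains").  This module turns those group recommendations into
a quantified commodity-level daily diet:

* allocate each group's grams across its commodities using the country's
  fractional composition (mass-balance preserving),
* disaggregate composite foods into primary ingredients via recipe
  compositions (recursive with cycle detection),
* impute missing nutrient densities with the arithmetic mean of
  same-subcategory, same-nutrient donor values,
* validate mass balance group by group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from dietopt.constants import NUTRIENTS
from dietopt.synthetic import CommodityRecord, CountryProfile


@dataclass
class RecipeDefinition:
    """Mass-fraction breakdown of a composite food into ingredients."""

    composite_id: str
    ingredients: dict[str, float]

    def validate(self) -> None:
        total = sum(self.ingredients.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"recipe {self.composite_id}: fractions sum to {total}, not 1"
            )
        if any(f < 0 for f in self.ingredients.values()):
            raise ValueError(f"recipe {self.composite_id}: negative fraction")


@dataclass
class HarmonizedDiet:
    """Commodity-level daily intakes in g/person/day with group provenance."""

    intakes: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for cid, q in self.intakes.items():
            if q < 0:
                raise ValueError(f"negative intake for {cid}")

    def total_mass(self) -> float:
        return sum(self.intakes.values())


def allocate_groups(profile: CountryProfile) -> HarmonizedDiet:
    """Allocate group recommendations across commodities by composition.

    For every group g, the allocated commodity intakes sum exactly to the
    group recommendation (mass balance).  Groups are processed in sorted
    order so the result is independent of dict insertion order; a commodity
    appearing in several groups accumulates intake, with provenance pointing
    at the largest contributor.
    """
    profile.validate()
    intakes: dict[str, float] = {}
    contribution: dict[str, dict[str, float]] = {}
    for gid in sorted(profile.fbdg_groups):
        rec = profile.fbdg_groups[gid]
        for cid in sorted(profile.composition[gid]):
            frac = profile.composition[gid][cid]
            amount = rec * frac
            intakes[cid] = intakes.get(cid, 0.0) + amount
            contribution.setdefault(cid, {})[gid] = amount
    provenance = {
        cid: max(srcs, key=lambda g: (srcs[g], g))
        for cid, srcs in contribution.items()
    }
    diet = HarmonizedDiet(intakes=intakes, provenance=provenance)
    diet.validate()
    return diet


def disaggregate_recipes(
    diet: HarmonizedDiet,
    recipes: list[RecipeDefinition],
    composite_ids: set[str] | None = None,
) -> HarmonizedDiet:
    """Replace composite foods by their primary ingredients, conserving mass.

    Resolution is iterative to a fixed point, so recipe ingredients that are
    themselves composites are expanded too.  Cyclic recipes raise.
    ``composite_ids`` marks which diet items are composites (defaults to the
    ids the recipe list defines); a marked composite without a recipe is an
    error naming it.
    """
    by_id = {}
    for r in recipes:
        r.validate()
        by_id[r.composite_id] = r
    if composite_ids is not None:
        orphans = sorted(
            cid for cid in composite_ids
            if cid not in by_id and cid in diet.intakes
        )
        if orphans:
            raise ValueError(f"no recipe for composite(s): {', '.join(orphans)}")

    intakes = dict(diet.intakes)
    provenance = dict(diet.provenance)
    max_depth = len(by_id) + 1
    for _ in range(max_depth):
        composites = [cid for cid in intakes if cid in by_id and intakes[cid] > 0]
        if not composites:
            break
        for cid in sorted(composites):
            mass = intakes.pop(cid)
            src = provenance.pop(cid, cid)
            for ing, frac in by_id[cid].ingredients.items():
                intakes[ing] = intakes.get(ing, 0.0) + mass * frac
                provenance.setdefault(ing, src)
    else:
        raise ValueError(
            "cyclic recipe definitions: expansion did not reach a fixed point"
        )
    # drop zero-mass composite entries left behind
    intakes = {cid: q for cid, q in intakes.items() if not (cid in by_id and q == 0)}
    out = HarmonizedDiet(intakes=intakes, provenance=provenance)
    out.validate()
    return out


def impute_missing_nutrients(
    records: list[CommodityRecord],
) -> list[CommodityRecord]:
    """Fill missing nutrient densities from same-subcategory means.

    Each missing (commodity, nutrient) cell gets the unweighted arithmetic
    mean of the non-missing values for that nutrient among commodities in
    the same subcategory.  Non-missing cells are untouched; a subcategory
    with no donor for a needed nutrient is an error.
    """
    donors: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        for nut in NUTRIENTS:
            val = rec.nutrients.get(nut, float("nan"))
            if not _isnan(val):
                donors.setdefault((rec.subcategory, nut), []).append(val)

    missing_no_donor = []
    out = []
    for rec in records:
        nutrients = dict(rec.nutrients)
        for nut in NUTRIENTS:
            val = nutrients.get(nut, float("nan"))
            if _isnan(val):
                pool = donors.get((rec.subcategory, nut))
                if not pool:
                    missing_no_donor.append((rec.subcategory, nut))
                    continue
                nutrients[nut] = sum(pool) / len(pool)
        out.append(CommodityRecord(
            commodity_id=rec.commodity_id, name=rec.name, category=rec.category,
            nutrients=nutrients, emission_factor=rec.emission_factor,
            producer_price=rec.producer_price, subcategory=rec.subcategory,
        ))
    if missing_no_donor:
        raise ValueError(
            "no imputation donors for: " + ", ".join(
                f"({sub}, {nut})" for sub, nut in sorted(set(missing_no_donor))
            )
        )
    return out


def validate_mass_balance(
    diet: HarmonizedDiet,
    profile: CountryProfile,
    tolerance: float = 1e-6,
) -> pd.DataFrame:
    """Per-group discrepancy between allocated mass and the recommendation.

    Returns a frame with columns recommended, allocated, discrepancy, flagged;
    a group is flagged when |discrepancy| exceeds ``tolerance`` grams.
    """
    rows = []
    for gid in sorted(profile.fbdg_groups):
        rec = profile.fbdg_groups[gid]
        # assumes each commodity is supplied by a single group, which holds
        # for generated profiles; shared commodities would double-count
        allocated = sum(
            diet.intakes.get(cid, 0.0)
            for cid in profile.composition.get(gid, {})
        )
        disc = allocated - rec
        rows.append(dict(group_id=gid, recommended=rec, allocated=allocated,
                         discrepancy=disc, flagged=abs(disc) > tolerance))
    return pd.DataFrame(rows).set_index("group_id")


def _isnan(val: float) -> bool:
    return val is None or (isinstance(val, float) and math.isnan(val))
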