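"""Seeded synthetic country datasets for dietary optimization.

Real national inputs to this kind of analysis are commodity tables (nutrient
composition, life-cycle emission factors under GWP20 mass allocation,
PPP-adjusted producer prices) plus country profiles (FBDG food-group
recommendations and group-to-commodity composition fractions).  This module
generates datasets with the same statistical structure for four country
archetypes so the full pipeline can be exercised and tested end to end:

* a US-like archetype (beef/poultry/dairy heavy),
* a China-like archetype (pork/aquaculture heavy, lower dairy),
* Australia- and New Zealand-like archetypes (ruminant/dairy heavy).

Each archetype is calibrated so that the translated guideline diet delivers
an exact (total protein, animal protein) pair: 85/45 g (US-like), 87/36 g
(China-like), 85/43 g (Australia-like) and 88/43 g (New Zealand-like),
spanning animal-protein shares of 0.41-0.53.  Nutrient densities are drawn
from log-normal distributions around archetype means (strictly positive and
right-skewed, like real composition tables); plant commodities carry no
vitamin B12 and no EPA/DHA; ruminant emission factors dominate
poultry/fish/plant factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dietopt.constants import (
    ASF_CATEGORIES,
    NUTRIENTS,
    PLANT_CATEGORY,
    PROTECTED_NUTRIENTS,
    WHO_PROTEIN_G,
)

ARCHETYPES = ("us_like", "cn_like", "au_like", "nz_like")


@dataclass
class CommodityRecord:
    """One food item: nutrient densities, emission factor, producer price.

    Nutrient densities are per 100 g edible mass; emission_factor is
    kg CO2e per kg product (GWP20, mass allocation); producer_price is
    constant-2020 international $ per kg.  Missing nutrient values are NaN,
    distinguishable from a true zero.
    """

    commodity_id: str
    name: str
    category: str
    nutrients: dict[str, float]
    emission_factor: float
    producer_price: float
    subcategory: str

    def validate(self) -> None:
        if self.category not in ASF_CATEGORIES + (PLANT_CATEGORY,):
            raise ValueError(f"unknown category {self.category!r}")
        if self.emission_factor < 0 or self.producer_price < 0:
            raise ValueError(f"{self.commodity_id}: negative factor or price")
        for nut, val in self.nutrients.items():
            if not _is_missing(val) and val < 0:
                raise ValueError(f"{self.commodity_id}: negative {nut}")
        if self.category == PLANT_CATEGORY:
            for nut in ("vitamin_b12", "epa", "dha"):
                val = self.nutrients.get(nut, 0.0)
                if not _is_missing(val) and val != 0.0:
                    raise ValueError(
                        f"plant commodity {self.commodity_id} has nonzero {nut}"
                    )


@dataclass
class CountryProfile:
    """FBDG group recommendations, composition fractions, and RDA vector."""

    country_id: str
    fbdg_groups: dict[str, float]           # group_id -> g/person/day
    composition: dict[str, dict[str, float]]  # group_id -> commodity -> fraction
    rda: dict[str, float]                   # nutrient -> daily allowance
    energy_target: float                    # kcal/person/day
    who_protein_target: float = WHO_PROTEIN_G

    def validate(self) -> None:
        for grp, rec in self.fbdg_groups.items():
            if rec < 0:
                raise ValueError(f"group {grp}: negative recommendation")
            fracs = self.composition.get(grp)
            if not fracs:
                raise ValueError(f"group {grp}: no composition fractions")
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"group {grp}: composition fractions sum to {total}, not 1"
                )
            if any(f < 0 for f in fracs.values()):
                raise ValueError(f"group {grp}: negative fraction")
        for nut, val in self.rda.items():
            if val <= 0:
                raise ValueError(f"rda[{nut}] must be > 0")


@dataclass
class GeneratorConfig:
    seed: int
    archetype: str = "us_like"
    n_plant_commodities: int = 6
    missingness_rate: float = 0.0
    noise_scale: float = 0.05

    def validate(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(
                f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}"
            )
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must be in [0, 1)")
        if not 4 <= self.n_plant_commodities <= 10:
            raise ValueError("n_plant_commodities must be in [4, 10]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def _is_missing(val: float) -> bool:
    return val is None or (isinstance(val, float) and math.isnan(val))


# ---------------------------------------------------------------------------
# Archetype parameter tables
# ---------------------------------------------------------------------------

# Per-commodity nutrient density means (per 100 g):
#   protein g, vitamin_a ugRAE, vitamin_b12 ug, ala g, epa g, dha g, energy kcal
# plus emission factor (kg CO2e/kg, GWP20 -- methane-heavy ruminant products
# sit far above monogastrics) and producer price ($/kg).
_ASF_COMMODITIES: list[dict] = [
    dict(commodity_id="beef_meat", name="Bovine meat", category="beef",
         subcategory="ruminant_meat",
         nutrients=(26.0, 10.0, 2.5, 0.05, 0.010, 0.005, 250.0),
         ef=120.0, price=6.0),
    dict(commodity_id="sheep_meat", name="Sheep meat", category="other_asf",
         subcategory="ruminant_meat",
         nutrients=(25.0, 8.0, 2.6, 0.10, 0.010, 0.005, 260.0),
         ef=95.0, price=6.5),
    dict(commodity_id="goat_meat", name="Goat meat", category="other_asf",
         subcategory="ruminant_meat",
         nutrients=(27.0, 6.0, 1.1, 0.02, 0.005, 0.003, 143.0),
         ef=85.0, price=6.0),
    dict(commodity_id="pork_meat", name="Pig meat", category="pork",
         subcategory="monogastric_meat",
         nutrients=(25.0, 5.0, 0.7, 0.10, 0.010, 0.005, 270.0),
         ef=14.0, price=3.5),
    dict(commodity_id="chicken_meat", name="Poultry meat", category="poultry",
         subcategory="monogastric_meat",
         nutrients=(27.0, 15.0, 0.4, 0.05, 0.010, 0.020, 190.0),
         ef=6.5, price=2.6),
    dict(commodity_id="turkey_meat", name="Turkey meat", category="poultry",
         subcategory="monogastric_meat",
         nutrients=(29.0, 10.0, 0.8, 0.05, 0.005, 0.010, 160.0),
         ef=7.2, price=3.2),
    dict(commodity_id="marine_fish", name="Marine finfish", category="fish",
         subcategory="seafood",
         nutrients=(20.0, 30.0, 4.0, 0.10, 0.700, 1.000, 140.0),
         ef=7.0, price=4.5),
    dict(commodity_id="freshwater_fish", name="Freshwater fish", category="fish",
         subcategory="seafood",
         nutrients=(18.0, 15.0, 2.0, 0.15, 0.250, 0.400, 120.0),
         ef=6.8, price=3.8),
    dict(commodity_id="shellfish", name="Molluscs and crustaceans",
         category="aquatic_other", subcategory="seafood",
         nutrients=(16.0, 20.0, 9.0, 0.03, 0.300, 0.250, 90.0),
         ef=9.0, price=5.5),
    dict(commodity_id="hen_eggs", name="Hen eggs", category="eggs",
         subcategory="eggs_dairy",
         nutrients=(12.5, 160.0, 1.1, 0.05, 0.010, 0.060, 143.0),
         ef=5.0, price=2.4),
    dict(commodity_id="milk_whole", name="Whole cow milk", category="dairy",
         subcategory="eggs_dairy",
         nutrients=(3.4, 46.0, 0.45, 0.010, 0.001, 0.001, 61.0),
         ef=4.5, price=0.9),
    dict(commodity_id="fermented_milk", name="Fermented milk products",
         category="dairy", subcategory="eggs_dairy",
         nutrients=(3.8, 40.0, 0.50, 0.010, 0.001, 0.001, 72.0),
         ef=5.0, price=1.4),
]

# Aggregate plant groups with fixed background intakes (g/day); vitamin B12
# and EPA/DHA are structurally zero in plants.
_PLANT_COMMODITIES: list[dict] = [
    dict(commodity_id="grains", name="Cereal grains",
         nutrients=(12.0, 0.0, 0.0, 0.05, 0.0, 0.0, 340.0),
         ef=0.9, price=0.45, intake=280.0),
    dict(commodity_id="vegetables", name="Vegetables",
         nutrients=(2.0, 50.0, 0.0, 0.05, 0.0, 0.0, 30.0),
         ef=0.5, price=0.70, intake=350.0),
    dict(commodity_id="fruits", name="Fruits",
         nutrients=(0.8, 25.0, 0.0, 0.02, 0.0, 0.0, 55.0),
         ef=0.5, price=0.90, intake=250.0),
    dict(commodity_id="legumes", name="Legumes and pulses",
         nutrients=(21.0, 1.0, 0.0, 0.30, 0.0, 0.0, 330.0),
         ef=0.8, price=0.90, intake=60.0),
    dict(commodity_id="nuts_seeds", name="Nuts and seeds",
         nutrients=(18.0, 1.0, 0.0, 3.00, 0.0, 0.0, 600.0),
         ef=1.5, price=4.00, intake=25.0),
    dict(commodity_id="tubers", name="Roots and tubers",
         nutrients=(2.0, 1.0, 0.0, 0.01, 0.0, 0.0, 86.0),
         ef=0.4, price=0.40, intake=120.0),
    dict(commodity_id="veg_oils", name="Vegetable oils",
         nutrients=(0.0, 0.0, 0.0, 8.00, 0.0, 0.0, 880.0),
         ef=2.5, price=1.60, intake=25.0),
    dict(commodity_id="sugar_sweeteners", name="Sugar and sweeteners",
         nutrients=(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 390.0),
         ef=1.0, price=0.50, intake=30.0),
    dict(commodity_id="soy_products", name="Soy products",
         nutrients=(12.0, 0.0, 0.0, 0.40, 0.0, 0.0, 120.0),
         ef=1.2, price=1.10, intake=40.0),
    dict(commodity_id="fungi_algae", name="Fungi and algae",
         nutrients=(3.0, 0.0, 0.0, 0.02, 0.0, 0.0, 30.0),
         ef=0.6, price=1.50, intake=15.0),
]

# Pre-calibration FBDG group recommendations (g/person/day) by archetype,
# reflecting the dominant-livestock profiles of the four country types.
_ARCHETYPE_ASF_GROUPS: dict[str, dict[str, float]] = {
    "us_like": dict(beef=45, pork=25, poultry=65, fish=25, eggs=30,
                    dairy=400, other_asf=5, aquatic_other=5),
    "cn_like": dict(beef=15, pork=60, poultry=35, fish=50, eggs=40,
                    dairy=120, other_asf=8, aquatic_other=25),
    "au_like": dict(beef=55, pork=25, poultry=45, fish=25, eggs=40,
                    dairy=380, other_asf=20, aquatic_other=5),
    "nz_like": dict(beef=50, pork=25, poultry=40, fish=30, eggs=35,
                    dairy=420, other_asf=25, aquatic_other=5),
}

# Calibration targets: (total FBDG protein g, animal FBDG protein g).
ARCHETYPE_PROTEIN_TARGETS: dict[str, tuple[float, float]] = {
    "us_like": (85.0, 45.0),
    "cn_like": (87.0, 36.0),
    "au_like": (85.0, 43.0),
    "nz_like": (88.0, 43.0),
}

# Mild producer-price multipliers capturing comparative advantage
# (e.g. cheap ruminant production in exporter archetypes, cheap pork in
# the China-like archetype).
_ARCHETYPE_PRICE_MULT: dict[str, dict[str, float]] = {
    "us_like": {"poultry": 0.85, "beef": 0.95},
    "cn_like": {"pork": 0.80, "fish": 0.85, "aquatic_other": 0.85},
    "au_like": {"beef": 0.85, "other_asf": 0.80, "dairy": 0.90},
    "nz_like": {"dairy": 0.75, "other_asf": 0.80, "beef": 0.90},
}

# Group-to-commodity composition fractions within multi-commodity groups.
_GROUP_COMPOSITION: dict[str, dict[str, float]] = {
    "beef": {"beef_meat": 1.0},
    "pork": {"pork_meat": 1.0},
    "poultry": {"chicken_meat": 0.85, "turkey_meat": 0.15},
    "fish": {"marine_fish": 0.6, "freshwater_fish": 0.4},
    "eggs": {"hen_eggs": 1.0},
    "dairy": {"milk_whole": 0.8, "fermented_milk": 0.2},
    "other_asf": {"sheep_meat": 0.7, "goat_meat": 0.3},
    "aquatic_other": {"shellfish": 1.0},
}

_DEFAULT_RDA: dict[str, float] = {
    "protein": 60.0,     # g; WHO adult reference
    "vitamin_a": 800.0,  # ug RAE
    "vitamin_b12": 2.4,  # ug
    "ala": 1.6,          # g
    "epa": 0.125,        # g; EPA+DHA 250 mg/day split evenly
    "dha": 0.125,        # g
}


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _lognormal_noise(rng: np.random.Generator, sigma: float) -> float:
    if sigma == 0:
        return 1.0
    # mean-one lognormal multiplier
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))


def generate_country_dataset(
    config: GeneratorConfig,
) -> tuple[CountryProfile, list[CommodityRecord]]:
    """Generate one archetype's country profile and commodity table.

    The FBDG group recommendations are rescaled so the translated diet
    delivers the archetype's exact (total, animal) protein pair; the
    profile's energy target is then set to the calibrated diet's energy,
    making the baseline guideline diet isocaloric by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    records: list[CommodityRecord] = []
    for spec in _ASF_COMMODITIES:
        mult = _ARCHETYPE_PRICE_MULT[config.archetype].get(spec["category"], 1.0)
        nutrients = {
            nut: base * _lognormal_noise(rng, config.noise_scale)
            for nut, base in zip(NUTRIENTS, spec["nutrients"])
        }
        records.append(CommodityRecord(
            commodity_id=spec["commodity_id"],
            name=spec["name"],
            category=spec["category"],
            nutrients=nutrients,
            emission_factor=spec["ef"] * _lognormal_noise(rng, config.noise_scale),
            producer_price=spec["price"] * mult
            * _lognormal_noise(rng, config.noise_scale),
            subcategory=spec["subcategory"],
        ))

    plant_specs = _PLANT_COMMODITIES[: config.n_plant_commodities]
    plant_intakes: dict[str, float] = {}
    for spec in plant_specs:
        nutrients = {}
        for nut, base in zip(NUTRIENTS, spec["nutrients"]):
            if nut in ("vitamin_b12", "epa", "dha"):
                nutrients[nut] = 0.0  # structurally absent in plants
            else:
                nutrients[nut] = base * _lognormal_noise(rng, config.noise_scale)
        records.append(CommodityRecord(
            commodity_id=spec["commodity_id"],
            name=spec["name"],
            category=PLANT_CATEGORY,
            nutrients=nutrients,
            emission_factor=spec["ef"] * _lognormal_noise(rng, config.noise_scale),
            producer_price=spec["price"] * _lognormal_noise(rng, config.noise_scale),
            subcategory="plant",
        ))
        plant_intakes[spec["commodity_id"]] = spec["intake"]

    by_id = {r.commodity_id: r for r in records}

    # Build the uncalibrated group recommendations.
    groups: dict[str, float] = dict(_ARCHETYPE_ASF_GROUPS[config.archetype])
    composition: dict[str, dict[str, float]] = {
        g: dict(f) for g, f in _GROUP_COMPOSITION.items()
    }
    for cid, intake in plant_intakes.items():
        groups[f"plant_{cid}"] = intake
        composition[f"plant_{cid}"] = {cid: 1.0}

    def group_protein(gid: str) -> float:
        # protein delivered per day by one group at its current recommendation
        return groups[gid] * sum(
            frac * by_id[cid].nutrients["protein"] / 100.0
            for cid, frac in composition[gid].items()
        )

    asf_ids = list(_ARCHETYPE_ASF_GROUPS[config.archetype])
    plant_ids = [g for g in groups if g.startswith("plant_")]
    animal_protein = sum(group_protein(g) for g in asf_ids)
    plant_protein = sum(group_protein(g) for g in plant_ids)

    total_target, animal_target = ARCHETYPE_PROTEIN_TARGETS[config.archetype]
    asf_scale = animal_target / animal_protein
    plant_scale = (total_target - animal_target) / plant_protein
    for g in asf_ids:
        groups[g] *= asf_scale
    for g in plant_ids:
        groups[g] *= plant_scale

    def group_energy(gid: str) -> float:
        return groups[gid] * sum(
            frac * by_id[cid].nutrients["energy"] / 100.0
            for cid, frac in composition[gid].items()
        )

    energy_target = sum(group_energy(g) for g in groups)

    profile = CountryProfile(
        country_id=config.archetype,
        fbdg_groups=groups,
        composition=composition,
        rda=dict(_DEFAULT_RDA),
        energy_target=energy_target,
    )
    profile.validate()
    for rec in records:
        rec.validate()

    if config.missingness_rate > 0:
        records = inject_missing_nutrients(
            records, config.missingness_rate, seed=config.seed + 1
        )
    return profile, records


def inject_missing_nutrients(
    records: list[CommodityRecord], rate: float, seed: int
) -> list[CommodityRecord]:
    """Mask nutrient cells at random with NaN to emulate incomplete tables.

    Protein and energy are never masked: every scenario needs them.  Cells
    are masked independently with probability ``rate``.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return records
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        nutrients = dict(rec.nutrients)
        for nut in NUTRIENTS:
            if nut in PROTECTED_NUTRIENTS or nut not in nutrients:
                continue
            if rng.random() < rate:
                nutrients[nut] = float("nan")
        out.append(CommodityRecord(
            commodity_id=rec.commodity_id, name=rec.name, category=rec.category,
            nutrients=nutrients, emission_factor=rec.emission_factor,
            producer_price=rec.producer_price, subcategory=rec.subcategory,
        ))
    return out


# ---------------------------------------------------------------------------
# DataFrame bridge
# ---------------------------------------------------------------------------

def records_to_frame(records: list[CommodityRecord]) -> pd.DataFrame:
    """Commodity table as a DataFrame indexed by commodity_id."""
    rows = []
    for r in records:
        row = {
            "commodity_id": r.commodity_id,
            "name": r.name,
            "category": r.category,
            "subcategory": r.subcategory,
            "emission_factor": r.emission_factor,
            "producer_price": r.producer_price,
        }
        row.update({nut: r.nutrients.get(nut, float("nan")) for nut in NUTRIENTS})
        rows.append(row)
    return pd.DataFrame(rows).set_index("commodity_id")


def frame_to_records(frame: pd.DataFrame) -> list[CommodityRecord]:
    records = []
    for cid, row in frame.iterrows():
        records.append(CommodityRecord(
            commodity_id=str(cid),
            name=str(row["name"]),
            category=str(row["category"]),
            nutrients={nut: float(row[nut]) for nut in NUTRIENTS},
            emission_factor=float(row["emission_factor"]),
            producer_price=float(row["producer_price"]),
            subcategory=str(row["subcategory"]),
        ))
    return records


def emission_ordering_ok(records: list[CommodityRecord]) -> bool:
    """Check the structural emission-factor ordering of the food system.

    Per kg: beef > pork > poultry ~ fish (within a factor of 2) > plants.
    Per g protein: beef > dairy > pork (dairy is mostly water, so its
    ruminant signal shows on a protein basis, not a mass basis).
    """
    frame = records_to_frame(records)

    def cat_mean(col: str, cat: str) -> float:
        return float(frame.loc[frame["category"] == cat, col].mean())

    ef = {c: cat_mean("emission_factor", c)
          for c in ("beef", "pork", "poultry", "fish", "dairy")}
    plant_max = float(
        frame.loc[frame["category"] == PLANT_CATEGORY, "emission_factor"].max()
    )
    per_protein = {
        c: ef[c] / (cat_mean("protein", c) * 10.0)  # g protein per kg
        for c in ("beef", "pork", "dairy")
    }
    return (
        ef["beef"] > ef["pork"] > ef["poultry"]
        and 0.5 < ef["poultry"] / ef["fish"] < 2.0
        and min(ef["poultry"], ef["fish"]) > plant_max
        and per_protein["beef"] > per_protein["dairy"] > per_protein["pork"]
    )


def archetype_protein_summary(seed: int = 0) -> pd.DataFrame:
    """Calibrated protein totals and animal shares across all archetypes."""
    from dietopt.translation import allocate_groups

    rows = []
    for arch in ARCHETYPES:
        profile, records = generate_country_dataset(
            GeneratorConfig(seed=seed, archetype=arch)
        )
        diet = allocate_groups(profile)
        table = records_to_frame(records)
        protein = {
            cid: q * table.loc[cid, "protein"] / 100.0
            for cid, q in diet.intakes.items()
        }
        animal = sum(
            p for cid, p in protein.items()
            if table.loc[cid, "category"] in ASF_CATEGORIES
        )
        total = sum(protein.values())
        rows.append(dict(archetype=arch, total_protein=total,
                         animal_protein=animal, share=animal / total))
    return pd.DataFrame(rows).set_index("archetype")
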