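"""Scenario compilation: named diet scenarios -> explicit constraint sets.

Six policy scenarios are analyzed per country:

* ``Baseline_FBDG``   - the guideline diet itself (fixed reference point),
* ``MaxProt``         - all protein-contributing intakes scaled uniformly so
                        total protein equals the WHO 60 g/day reference,
* ``MaxVitamins_FBDG`` / ``MaxVitamins_Protein``   - maximize vitamin A/B12
  adequacy under FBDG-native or WHO-60 protein budgets,
* ``MaxFattyAcids_FBDG`` / ``MaxFattyAcids_Protein`` - likewise for EPA/DHA.

The optimized scenarios search the 8-dimensional ASF intake space inside
EAT-Lancet intake ranges (red meat 0-28 g shared across beef/pork/sheep-goat,
poultry 0-58, seafood 0-100 shared across fish/other aquatic, dairy 0-500,
eggs 0-25), an isocaloric energy band around the national FBDG energy level,
and the scenario's protein cap or target.  Plant foods are a fixed background
during the search; afterwards they are rescaled to close any protein gap left
by reduced animal intake, subject to the energy band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from dietopt.constants import ASF_CATEGORIES
from dietopt.objectives import baseline_category_intakes
from dietopt.synthetic import CountryProfile
from dietopt.translation import HarmonizedDiet, allocate_groups


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    protein_mode: str                     # "fbdg_native" | "who60"
    priority_nutrients: tuple[str, ...]   # empty for the two baselines
    pinned: bool = False                  # fixed reference point, no search


SCENARIOS: dict[str, ScenarioSpec] = {
    "Baseline_FBDG": ScenarioSpec("Baseline_FBDG", "fbdg_native", (), pinned=True),
    "MaxProt": ScenarioSpec("MaxProt", "who60", (), pinned=True),
    "MaxVitamins_FBDG": ScenarioSpec(
        "MaxVitamins_FBDG", "fbdg_native", ("vitamin_a", "vitamin_b12")),
    "MaxVitamins_Protein": ScenarioSpec(
        "MaxVitamins_Protein", "who60", ("vitamin_a", "vitamin_b12")),
    "MaxFattyAcids_FBDG": ScenarioSpec(
        "MaxFattyAcids_FBDG", "fbdg_native", ("epa", "dha")),
    "MaxFattyAcids_Protein": ScenarioSpec(
        "MaxFattyAcids_Protein", "who60", ("epa", "dha")),
}


@dataclass
class EATLancetReference:
    """EAT-Lancet planetary-health intake ranges and point targets (g/day).

    Ranges bound the optimization; point targets are the single reference
    intakes used for compliance ratios (the two differ in the source
    framework and are kept separate here).
    """

    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "red_meat": (0.0, 28.0),
        "poultry": (0.0, 58.0),
        "fish": (0.0, 100.0),
        "dairy": (0.0, 500.0),
        "eggs": (0.0, 25.0),
    })
    point_targets: dict[str, float] = field(default_factory=lambda: {
        "fish": 28.0, "pork": 7.0, "eggs": 13.0,
        "poultry": 29.0, "beef": 7.0, "milk": 250.0,
    })

    def validate(self) -> None:
        for cat, (lo, hi) in self.ranges.items():
            if lo < 0 or lo > hi:
                raise ValueError(f"range for {cat} invalid: ({lo}, {hi})")
        if any(v < 0 for v in self.point_targets.values()):
            raise ValueError("negative point target")


# Which EAT-Lancet range constrains each ASF decision category.  Red meat and
# seafood ranges are shared across several categories via group bounds.
_CATEGORY_RANGE = {
    "beef": "red_meat", "pork": "red_meat", "other_asf": "red_meat",
    "poultry": "poultry",
    "fish": "fish", "aquatic_other": "fish",
    "dairy": "dairy",
    "eggs": "eggs",
}
_SHARED_GROUPS = {
    "red_meat": ("beef", "pork", "other_asf"),
    "fish": ("fish", "aquatic_other"),
}


@dataclass
class ConstraintSet:
    """Compiled, scenario-specific constraints over the 8 ASF categories."""

    bounds: dict[str, tuple[float, float]]
    energy_band: tuple[float, float] | None   # (target kcal, tolerance frac)
    total_protein_cap: float | None
    total_protein_target: float | None
    rda_active: dict[str, float]
    group_bounds: dict[str, tuple[tuple[str, ...], float, float]] = field(
        default_factory=dict)
    protein_tolerance: float = 0.02

    def validate(self) -> None:
        for cat, (lo, hi) in self.bounds.items():
            if lo < 0 or lo > hi:
                raise ValueError(f"bounds for {cat} invalid: ({lo}, {hi})")
        if self.energy_band is not None and self.energy_band[1] < 0:
            raise ValueError("energy tolerance must be >= 0")


def total_protein(intakes: dict[str, float], table: pd.DataFrame) -> float:
    """Total daily protein (g) delivered by a set of intakes."""
    return sum(
        q * float(table.at[item, "protein"]) / 100.0
        for item, q in intakes.items()
    )


def build_constraints(
    spec: ScenarioSpec,
    profile: CountryProfile,
    reference: EATLancetReference,
    table: pd.DataFrame,
    energy_tolerance: float = 0.02,
) -> ConstraintSet:
    """Compile a scenario into explicit bounds, energy band, and protein caps.

    ``table`` is the (imputed) commodity table, needed to evaluate the
    guideline diet's protein and energy.  Pinned scenarios (Baseline_FBDG,
    MaxProt) fix every category at its reference intake and anchor the
    energy band at the pinned diet's own energy; searched scenarios get
    EAT-Lancet bounds and the national FBDG energy level.
    """
    reference.validate()
    baseline = allocate_groups(profile)
    cat_intakes = baseline_category_intakes(baseline, table)
    fbdg_protein = total_protein(baseline.intakes, table)

    if spec.protein_mode == "who60":
        cap = target = profile.who_protein_target
    elif spec.protein_mode == "fbdg_native":
        cap, target = fbdg_protein, None
    else:
        raise ValueError(f"unknown protein mode {spec.protein_mode!r}")

    rda_active = dict(profile.rda)

    if spec.pinned:
        if spec.name == "MaxProt":
            diet = scale_to_protein_target(
                baseline, profile.who_protein_target, table)
        else:
            diet = baseline
        pinned = baseline_category_intakes(diet, table)
        bounds = {cat: (pinned[cat], pinned[cat]) for cat in ASF_CATEGORIES}
        # the pinned point defines its own energy level; non-protein plant
        # foods are unscaled, so MaxProt energy sits below the FBDG level
        pinned_energy = sum(
            q * float(table.at[cid, "energy"]) / 100.0
            for cid, q in diet.intakes.items()
        )
        cs = ConstraintSet(bounds=bounds, energy_band=(pinned_energy, energy_tolerance),
                           total_protein_cap=cap, total_protein_target=target,
                           rda_active=rda_active)
        cs.validate()
        return cs

    bounds = {}
    group_bounds = {}
    for cat in ASF_CATEGORIES:
        rng_key = _CATEGORY_RANGE.get(cat)
        if rng_key is None or rng_key not in reference.ranges:
            raise ValueError(f"category {cat!r} unmappable to a reference range")
        bounds[cat] = reference.ranges[rng_key]
    for rng_key, cats in _SHARED_GROUPS.items():
        lo, hi = reference.ranges[rng_key]
        group_bounds[rng_key] = (cats, lo, hi)

    cs = ConstraintSet(
        bounds=bounds,
        energy_band=(profile.energy_target, energy_tolerance),
        total_protein_cap=cap,
        total_protein_target=target,
        rda_active=rda_active,
        group_bounds=group_bounds,
    )
    cs.validate()
    return cs


def scale_to_protein_target(
    diet: HarmonizedDiet, target: float, table: pd.DataFrame
) -> HarmonizedDiet:
    """Scale all protein-contributing intakes uniformly to a protein total.

    Foods with zero protein density (oils, sugar) are untouched; everything
    else is multiplied by target/current so total protein lands exactly on
    the target.
    """
    current = total_protein(diet.intakes, table)
    if current <= 0:
        raise ValueError("diet supplies no protein; cannot scale")
    factor = target / current
    intakes = {}
    for cid, q in diet.intakes.items():
        dens = float(table.at[cid, "protein"])
        intakes[cid] = q * factor if dens > 0 else q
    return HarmonizedDiet(intakes=intakes, provenance=dict(diet.provenance))


def eat_lancet_ratio(
    category_intakes: dict[str, float], reference: EATLancetReference
) -> dict[str, float]:
    """Intake / EAT-Lancet point target per category (1.0 = exact compliance).

    Dairy intakes are compared against the milk point target.  A zero target
    with nonzero intake is flagged as an infinite ratio.
    """
    alias = {"dairy": "milk"}
    out = {}
    for cat, intake in category_intakes.items():
        key = alias.get(cat, cat)
        if key not in reference.point_targets:
            continue
        target = reference.point_targets[key]
        if target <= 0:
            out[cat] = math.inf if intake > 0 else 0.0
        else:
            out[cat] = intake / target
    return out


def check_feasible(
    asf_intakes: dict[str, float],
    constraints: ConstraintSet,
    table: pd.DataFrame,
    plant_background: dict[str, float] | None = None,
    tol: float = 1e-9,
) -> tuple[bool, list[dict]]:
    """Check a candidate against bounds, energy band, and protein cap/target.

    Returns (feasible, violations); each violation names the constraint and
    its magnitude.  Energy and protein are evaluated on the full diet (ASF
    plus plant background).
    """
    violations: list[dict] = []
    for cat, (lo, hi) in constraints.bounds.items():
        q = asf_intakes.get(cat, 0.0)
        if q < lo - tol:
            violations.append(dict(constraint=f"{cat}_lower", magnitude=lo - q))
        if q > hi + tol:
            violations.append(dict(constraint=f"{cat}_upper", magnitude=q - hi))
    for name, (cats, lo, hi) in constraints.group_bounds.items():
        s = sum(asf_intakes.get(c, 0.0) for c in cats)
        if s > hi + tol:
            violations.append(dict(constraint=f"group_{name}_upper",
                                   magnitude=s - hi))
        if s < lo - tol:
            violations.append(dict(constraint=f"group_{name}_lower",
                                   magnitude=lo - s))

    full = dict(plant_background or {})
    for cat, q in asf_intakes.items():
        full[cat] = full.get(cat, 0.0) + q

    if constraints.energy_band is not None:
        target, frac = constraints.energy_band
        energy = sum(
            q * float(table.at[item, "energy"]) / 100.0
            for item, q in full.items()
        )
        dev = abs(energy - target)
        if dev > frac * target + tol:
            violations.append(dict(constraint="energy_band",
                                   magnitude=dev - frac * target))

    protein = total_protein(full, table)
    if constraints.total_protein_cap is not None:
        if protein > constraints.total_protein_cap * (1 + tol) + tol:
            violations.append(dict(
                constraint="protein_cap",
                magnitude=protein - constraints.total_protein_cap))
    if constraints.total_protein_target is not None:
        t = constraints.total_protein_target
        dev = abs(protein - t)
        if dev > constraints.protein_tolerance * t + tol:
            violations.append(dict(
                constraint="protein_target",
                magnitude=dev - constraints.protein_tolerance * t))
    return (len(violations) == 0, violations)


def fill_protein_gap(
    asf_intakes: dict[str, float],
    plant_background: dict[str, float],
    constraints: ConstraintSet,
    table: pd.DataFrame,
) -> dict[str, float]:
    """Rescale plant intakes so total protein meets the scenario's budget.

    Plant groups are scaled by a common factor so that total protein reaches
    the protein target (or cap, for FBDG-native scenarios), clamped to keep
    total energy inside the energy band.  Returns the adjusted plant
    background; ASF intakes are never modified here.
    """
    level = constraints.total_protein_target or constraints.total_protein_cap
    if level is None or not plant_background:
        return dict(plant_background)
    asf_protein = total_protein(asf_intakes, table)
    plant_protein = total_protein(plant_background, table)
    if plant_protein <= 0:
        return dict(plant_background)
    factor = max(0.0, (level - asf_protein) / plant_protein)

    if constraints.energy_band is not None:
        target, frac = constraints.energy_band
        asf_energy = sum(
            q * float(table.at[item, "energy"]) / 100.0
            for item, q in asf_intakes.items()
        )
        plant_energy = sum(
            q * float(table.at[item, "energy"]) / 100.0
            for item, q in plant_background.items()
        )
        if plant_energy > 0:
            f_lo = (target * (1 - frac) - asf_energy) / plant_energy
            f_hi = (target * (1 + frac) - asf_energy) / plant_energy
            factor = min(max(factor, f_lo, 0.0), max(f_hi, 0.0))

    return {cid: q * factor for cid, q in plant_background.items()}
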