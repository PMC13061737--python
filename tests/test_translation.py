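"""Translation: allocation mass balance, recipe expansion, imputation."""

import math

import numpy as np
import pytest

from dietopt.synthetic import (
    CommodityRecord,
    CountryProfile,
    GeneratorConfig,
    generate_country_dataset,
    inject_missing_nutrients,
    records_to_frame,
)
from dietopt.translation import (
    HarmonizedDiet,
    RecipeDefinition,
    allocate_groups,
    disaggregate_recipes,
    impute_missing_nutrients,
    validate_mass_balance,
)


def _random_profile(rng: np.random.Generator) -> CountryProfile:
    n_groups = rng.integers(2, 8)
    groups, comp = {}, {}
    for g in range(n_groups):
        gid = f"g{g}"
        groups[gid] = float(rng.uniform(0, 500))
        n_items = rng.integers(1, 5)
        w = rng.dirichlet(np.ones(n_items))
        comp[gid] = {f"g{g}_c{i}": float(w[i]) for i in range(n_items)}
        # renormalize exactly to 1 to satisfy the profile invariant
        total = sum(comp[gid].values())
        comp[gid] = {k: v / total for k, v in comp[gid].items()}
    return CountryProfile(country_id="random", fbdg_groups=groups,
                          composition=comp, rda={"protein": 60.0},
                          energy_target=2000.0)


def test_allocation_direct_fractions():
    profile = CountryProfile(
        country_id="t", fbdg_groups={"g": 100.0},
        composition={"g": {"x": 0.6, "y": 0.4}},
        rda={"protein": 60.0}, energy_target=2000.0)
    diet = allocate_groups(profile)
    assert diet.intakes == {"x": 60.0, "y": 40.0}
    assert diet.provenance == {"x": "g", "y": "g"}


def test_allocation_single_commodity_identity():
    profile = CountryProfile(
        country_id="t", fbdg_groups={"g": 123.4},
        composition={"g": {"only": 1.0}},
        rda={"protein": 60.0}, energy_target=2000.0)
    assert allocate_groups(profile).intakes == {"only": 123.4}


def test_allocation_rejects_bad_fractions():
    profile = CountryProfile(
        country_id="t", fbdg_groups={"g": 100.0},
        composition={"g": {"x": 0.6, "y": 0.5}},
        rda={"protein": 60.0}, energy_target=2000.0)
    with pytest.raises(ValueError, match="sum"):
        allocate_groups(profile)


def test_allocation_mass_balance_over_seeded_profiles():
    """Per-group allocated mass equals the recommendation on 100 profiles."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        profile = _random_profile(rng)
        diet = allocate_groups(profile)
        for gid, rec in profile.fbdg_groups.items():
            allocated = sum(diet.intakes[cid]
                            for cid in profile.composition[gid])
            assert abs(allocated - rec) <= 1e-9
        report = validate_mass_balance(diet, profile, tolerance=1e-9)
        assert not report["flagged"].any()


def test_allocation_order_independent():
    rng = np.random.default_rng(3)
    profile = _random_profile(rng)
    shuffled = CountryProfile(
        country_id=profile.country_id,
        fbdg_groups=dict(reversed(list(profile.fbdg_groups.items()))),
        composition=dict(reversed(list(profile.composition.items()))),
        rda=profile.rda, energy_target=profile.energy_target)
    assert allocate_groups(profile).intakes == allocate_groups(shuffled).intakes


def test_recipe_direct_expansion():
    diet = HarmonizedDiet(intakes={"stew": 100.0})
    recipes = [RecipeDefinition("stew", {"a": 0.7, "b": 0.3})]
    out = disaggregate_recipes(diet, recipes)
    assert out.intakes == {"a": 70.0, "b": 30.0}


def test_recipe_no_composites_identity():
    diet = HarmonizedDiet(intakes={"a": 10.0, "b": 5.0})
    out = disaggregate_recipes(diet, [RecipeDefinition("x", {"a": 1.0})])
    assert out.intakes == diet.intakes


def test_recipe_nested_resolves_to_manual_expansion():
    diet = HarmonizedDiet(intakes={"pie": 200.0})
    recipes = [
        RecipeDefinition("pie", {"filling": 0.5, "flour": 0.5}),
        RecipeDefinition("filling", {"beef_meat": 0.8, "onion": 0.2}),
    ]
    out = disaggregate_recipes(diet, recipes)
    # manual expansion: 200*0.5=100 flour; 100*0.8=80 beef; 100*0.2=20 onion
    assert out.intakes == pytest.approx(
        {"flour": 100.0, "beef_meat": 80.0, "onion": 20.0})
    assert abs(sum(out.intakes.values()) - 200.0) <= 1e-9


def test_recipe_mass_conserved():
    rng = np.random.default_rng(8)
    intakes = {f"comp{i}": float(rng.uniform(1, 100)) for i in range(5)}
    recipes = []
    for i in range(5):
        w = rng.dirichlet(np.ones(3))
        w = w / w.sum()
        recipes.append(RecipeDefinition(
            f"comp{i}", {f"ing{i}_{j}": float(w[j]) for j in range(3)}))
    out = disaggregate_recipes(HarmonizedDiet(intakes=intakes), recipes)
    assert abs(sum(out.intakes.values()) - sum(intakes.values())) <= 1e-9
    assert not any(cid.startswith("comp") for cid in out.intakes)


def test_recipe_cycle_detected():
    diet = HarmonizedDiet(intakes={"a": 10.0})
    recipes = [RecipeDefinition("a", {"b": 1.0}),
               RecipeDefinition("b", {"a": 1.0})]
    with pytest.raises(ValueError, match="cyclic"):
        disaggregate_recipes(diet, recipes)


def test_recipe_missing_raises_with_name():
    diet = HarmonizedDiet(intakes={"casserole": 50.0})
    with pytest.raises(ValueError, match="casserole"):
        disaggregate_recipes(diet, [], composite_ids={"casserole"})


def _tiny_records(vals):
    recs = []
    for i, v in enumerate(vals):
        recs.append(CommodityRecord(
            commodity_id=f"c{i}", name=f"c{i}", category="beef",
            nutrients=dict(protein=20.0, vitamin_a=v, vitamin_b12=1.0,
                           ala=0.1, epa=0.1, dha=0.1, energy=200.0),
            emission_factor=1.0, producer_price=1.0, subcategory="sub"))
    return recs


def test_imputation_fills_with_subcategory_mean():
    recs = _tiny_records([2.0, 4.0, float("nan")])
    out = impute_missing_nutrients(recs)
    assert out[2].nutrients["vitamin_a"] == pytest.approx(3.0)
    assert out[0].nutrients["vitamin_a"] == 2.0  # donors untouched


def test_imputation_identity_when_complete():
    recs = _tiny_records([2.0, 4.0])
    out = impute_missing_nutrients(recs)
    assert records_to_frame(out).equals(records_to_frame(recs))


def test_imputation_idempotent():
    recs = _tiny_records([2.0, 4.0, float("nan")])
    once = impute_missing_nutrients(recs)
    twice = impute_missing_nutrients(once)
    assert records_to_frame(once).equals(records_to_frame(twice))


def test_imputation_error_names_subcategory_and_nutrient():
    recs = _tiny_records([float("nan"), float("nan")])
    with pytest.raises(ValueError, match=r"\(sub, vitamin_a\)"):
        impute_missing_nutrients(recs)


def test_imputation_preserves_subcategory_means():
    """Imputed tables keep each subcategory's column mean for complete cols."""
    for seed in range(20):
        _, records = generate_country_dataset(GeneratorConfig(seed=seed))
        masked = inject_missing_nutrients(records, 0.1, seed=seed + 100)
        before = records_to_frame(records)
        masked_nan = records_to_frame(masked).drop(
            columns=["name", "category"]).isna()
        donorless = masked_nan.groupby(
            records_to_frame(masked)["subcategory"]).all().any().any()
        if donorless:
            # precondition violated: the error must name the gap
            with pytest.raises(ValueError, match="no imputation donors"):
                impute_missing_nutrients(masked)
            continue
        after = records_to_frame(impute_missing_nutrients(masked))
        assert not after.isna().any().any()
        masked_frame = records_to_frame(masked)
        for sub, grp in masked_frame.groupby("subcategory"):
            for nut in ("protein", "energy"):  # never masked
                assert after.loc[grp.index, nut].mean() == pytest.approx(
                    before.loc[grp.index, nut].mean())


def test_mass_balance_flags_perturbed_group():
    profile = CountryProfile(
        country_id="t", fbdg_groups={"g": 100.0, "h": 50.0},
        composition={"g": {"x": 1.0}, "h": {"y": 1.0}},
        rda={"protein": 60.0}, energy_target=2000.0)
    diet = allocate_groups(profile)
    diet.intakes["x"] += 1.0
    report = validate_mass_balance(diet, profile)
    assert report.loc["g", "flagged"]
    assert report.loc["g", "discrepancy"] == pytest.approx(1.0)
    assert not report.loc["h", "flagged"]


def test_mass_balance_empty_diet_zero_recommendations():
    profile = CountryProfile(
        country_id="t", fbdg_groups={"g": 0.0},
        composition={"g": {"x": 1.0}},
        rda={"protein": 60.0}, energy_target=2000.0)
    report = validate_mass_balance(HarmonizedDiet(intakes={}), profile)
    assert not report["flagged"].any()
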