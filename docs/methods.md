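# Methods

This note records the model, its parameters, and the numerical choices made
in `dietopt`, in the package's own terms.

## Synthetic data generator

Real food-balance, price, and life-cycle inventories are licensed datasets,
so all inputs here are synthetic. `synthetic.generate_country_dataset` emits,
per country archetype, a commodity table (12 animal-source commodities plus a
configurable number of plant groups, default 6) and a guideline profile
(food-group recommendations, within-group commodity fractions, RDAs, energy
target).

What it emulates:

- **Protein calibration.** Group recommendations are rescaled post hoc so the
  translated guideline diet delivers exactly the archetype's (total, animal)
  protein pair: 85/45 g (`us_like`), 87/36 g (`cn_like`), 85/43 g
  (`au_like`), 88/43 g (`nz_like`). The calibration applies one factor to
  animal groups and one to plant groups, so within-group structure is
  untouched. The profile's energy target is then set to the calibrated
  diet's energy, making the baseline isocaloric band self-consistent.
- **Emission-factor structure.** Mean factors preserve the orderings that
  drive the substitution logic: per kg, beef ≫ pork > poultry ≈ fish >
  plants; per g protein, beef > dairy > pork. Ruminant meat is set around
  120 kg CO2e/kg (20-year-horizon magnitudes), poultry/fish near 6–7,
  plants below 2.
- **Nutrient structure.** B12, EPA, and DHA are absent from plant groups;
  EPA/DHA concentrate in marine commodities; RDAs default to 60 g protein,
  800 µg vitamin A, 2.4 µg B12, 1.6 g ALA, 0.125 g each EPA and DHA.
- **Noise and missingness.** Commodity attributes are archetype means times
  mean-one lognormal noise (`noise_scale`, default 0.05).
  `inject_missing_nutrients` masks maskable nutrient cells at a configured
  rate (never protein or energy) for exercising the imputation path.

What it does not emulate: real price levels and dispersion, full nutrient
panels, trade or seasonality, within-country heterogeneity, or any
population dynamics. Generated numbers support method validation and
synthetic studies, not country-level claims.

## Translation

`allocate_groups` splits each group recommendation across its commodities by
the profile's fractions (fractions must sum to 1 per group; allocation is
order-independent and mass-balanced to 1e-9). `disaggregate_recipes` expands
composite foods through mass-fraction recipes by fixed-point iteration,
detecting cycles and missing recipes by name. `impute_missing_nutrients`
fills missing nutrient cells with the unweighted subcategory mean and fails
loudly when a (subcategory, nutrient) pair has no donors.
`validate_mass_balance` reports per-group discrepancies against a tolerance.

## Decision space and objectives

Searches operate on the eight ASF categories; commodity detail is aggregated
to category level with weights equal to each commodity's share of its
category in the baseline diet, so category nutrient/price/emission profiles
reflect the national consumption mix. The plant background is held fixed
during the search and rescaled afterwards (see gap fill below).

Objectives for intake vector `Q` (g/day): cost `Σ Q_i R_i / 1000` ($/day,
prices in $/kg), emissions `Σ Q_i EF_i / 1000` (kg CO2e/day), and nutrition
`min_j min(supply_j/RDA_j, 1)` over the scenario's priority nutrients
(vitamins A and B12, or EPA and DHA; the baseline reports the capped minimum
over all four tracked nutrients). The cap means surpluses cannot compensate
shortfalls and the score lives in [0, 1].

The adequacy penalty is `s · Σ_j (d_j/RDA_j)²` with `d_j = max(0, RDA_j −
supply_j)`; normalizing by the RDA makes nutrients with different units
commensurable, and the quadratic keeps the gradient proportional to the
deficit. The penalty is folded into dominance by adding it to both minimized
objectives and subtracting it from the nutrition score.

## Scenarios and constraints

Six presets cross two protein modes with three objectives-of-interest:

- **Pinned:** `Baseline_FBDG` (the guideline diet itself) and `MaxProt` (the
  guideline scaled uniformly — over protein-containing foods — to the 60 g
  WHO reference). Both are fixed points: their "front" is the single
  evaluated diet, and their energy band is anchored at their own energy.
- **Searched:** `MaxVitamins_FBDG`, `MaxVitamins_Protein`,
  `MaxFattyAcids_FBDG`, `MaxFattyAcids_Protein`. Bounds per category are the
  EAT-Lancet ranges (red meat 0–28 g split over beef/pork/other ASF as a
  group bound, poultry 0–58, fish 0–100 shared with other aquatic, dairy
  0–500, eggs 0–25). `_FBDG` caps total protein at the guideline's own
  total; `_Protein` pins it to 60 g (±2% tolerance). All searched scenarios
  keep energy within ±2% of the guideline's energy target.

`fill_protein_gap` closes each candidate's protein gap by scaling the plant
background with a single common factor, clamped to the interval the energy
band allows; candidates whose clamped diet still misses the protein rule or
energy band carry a squared-relative violation measure used by
feasibility-first selection.

## Optimizer

A self-contained NSGA-II: fast non-dominated sorting and crowding distance
on the penalized objective triples, simulated binary crossover (η = 15),
polynomial mutation (η = 20), binary tournaments with feasibility-first
rules (feasible beats infeasible; infeasible compare by violation), and
proportional repair of box and group bounds. Defaults: population 200,
100 generations, crossover probability 0.7, mutation probability 0.2; the
shipped demo uses a reduced 64×40 budget. The penalty scale grows linearly
over generations (`s_g = s_0 (1 + g/G)`, `s_0 = 10`), loose early for
exploration and tight late for adequacy. An external archive keeps every
feasible non-dominated solution found (deduplicated, capped at 512 by
crowding), which makes best-so-far objectives and archive hypervolume
monotone across generations; the archive is the returned front, with the
final population's first front as fallback when no feasible point was seen.

`brute_force_pareto` enumerates an explicit grid with the same evaluator and
exact non-dominated filtering; `hypervolume` implements exact 2-D sweep and
3-D slicing. These are the oracles the test suite holds NSGA-II to (≥ 95%
oracle hypervolume, members within grid resolution of oracle points).

**Thin fronts are expected in some scenarios.** With protein pinned at 60 g,
the feasible set is a thin manifold (uniform random sampling virtually never
hits it), and when priority RDAs are unattainable within the EAT-Lancet
bounds (EPA/DHA at capped fish intake) the penalty term dominates the
objective differences and induces a near-total order, so the archive
legitimately collapses toward the minimum-deficit feasible diet. The knee
point — the member nearest the ideal point after per-axis min-max
normalization, degenerate axes ignored — is the scenario summary either way.

## Robustness

Prices and emission factors are perturbed multiplicatively, `p' = p(1 + ε)`,
`ε ~ N(0, σ²)`, σ = 0.10 by default, clipped at zero with a warning.
Each Monte Carlo run gets an independent generator spawned from the master
seed (numpy `SeedSequence`); the default mode re-prices the unperturbed
knee diet per run (re-optimization at reduced budget is available). Runs
failing beyond 5% abort the experiment. Summaries: mean, SD (ddof = 1),
CV = SD/mean, normal-approximation 95% CI. Convergence compares means at
nested prefixes of one seed stream (500/1000/2000 by default) against a 1%
relative-difference rule. Deterministic sweeps perturb one parameter at a
time at graduated levels (5–25%) in both directions and report the symmetric
elasticity `(|ΔY⁺| + |ΔY⁻|)/(2 Y₀ δ)`, which is exactly 1 for proportional
and 2 for quadratic metrics — the analytic anchors the tests use.

## Reporting

Scenario knee points are compared to the evaluated guideline baseline as
percent changes in cost, emissions, and nutrition. Note that nutrition
scores are scenario-specific (different priority sets), so cross-scenario
nutrition changes are indicative, not commensurable. Per country, dietary
cost is regressed on emissions (statsmodels OLS; slope with 95% CI and
two-sided p, R²) over front members (or knee points). EAT-Lancet compliance
ratios (intake/point target, dairy mapped to the milk target, zero targets
flagged as infinite) and adequacy radar matrices round out the bundle;
rendering to PNG is optional and nothing downstream depends on it.

## Reproducibility

Every stage seed derives from one master seed via `SeedSequence` (all seeds
kept below 2³¹), and `manifest.json` records SHA-256 checksums of every
artifact; reruns with the same config reproduce the hashes exactly.

## Limitations

- Synthetic inputs: magnitudes are structurally plausible, not measured.
- Category-level search hides within-category substitutions.
- The plant background rescales as one block; plant-side reallocation is
  out of scope.
- The penalty formulation returns thin fronts when adequacy binds (above).
- Emission factors and prices are treated as independent in Monte Carlo;
  correlated shocks are not modeled.
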