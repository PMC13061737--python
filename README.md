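# dietopt

Multi-objective optimization of food-based dietary guidelines (FBDGs):
given a country's recommended daily intakes by food group, find
animal-source-food (ASF) substitutions that jointly reduce dietary cost and
greenhouse-gas emissions while protecting nutrient adequacy.

## Scientific problem

National FBDGs recommend daily intakes per food group. Translated into
commodities, they typically deliver far more protein than the 60 g/day WHO
reference for an average adult, and a large share of it comes from
animal-source foods with high climate footprints. That surplus is a
substitution margin: protein can be shifted toward cheaper, lower-emission
sources without compromising adequacy.

The package formalizes this as a constrained three-objective problem over
daily intakes `Q_i` (g/day) of eight ASF categories (beef, pork, poultry,
fish, eggs, dairy, other terrestrial ASF, other aquatic ASF) on top of a
plant-food background:

- **Cost** `C(Q) = Σ Q_i · R_i / 1000` ($/day), with `R_i` the producer
  price in $/kg — minimized.
- **Emissions** `E(Q) = Σ Q_i · EF_i / 1000` (kg CO2e/day), with `EF_i` the
  life-cycle emission factor in kg CO2e/kg — minimized.
- **Nutrition** `N(Q) = min_j min(supply_j / RDA_j, 1)` over the scenario's
  priority nutrients — maximized, capped at 1 so surpluses earn no credit.

Unmet recommended allowances are discouraged by a quadratic penalty
`P(Q) = s · Σ_j (max(0, RDA_j − supply_j) / RDA_j)²` folded into dominance
comparisons, with the scale `s` tightening over generations. Constraints are
per-category EAT-Lancet intake ranges, an isocaloric band (±2% of the
guideline diet's energy), and a total-protein rule that depends on the
scenario: capped at the guideline's own total, or pinned to the 60 g WHO
reference.

Six scenarios are analyzed per country: the pinned guideline baseline
(`Baseline_FBDG`), the guideline scaled uniformly to 60 g protein
(`MaxProt`), and four searched scenarios crossing two priority-nutrient sets
(vitamins A + B12; EPA + DHA) with the two protein modes. Searched scenarios
are solved with a penalty-constrained NSGA-II (non-dominated sorting,
crowding distance, simulated binary crossover, polynomial mutation,
feasibility-first tournaments, and an external archive), validated against a
brute-force grid oracle on enumerable problems. Each front is summarized by
its knee point; scenarios are compared as relative changes against the
baseline. Monte Carlo perturbation of prices and emission factors
(multiplicative, σ = 0.10) and graduated deterministic sweeps (5–25%)
quantify robustness.

All inputs are synthetic: a calibrated generator emits country archetypes
(`us_like`, `cn_like`, `au_like`, `nz_like`) whose guideline diets deliver
exactly the reported (total, animal) protein pairs — e.g. 85/45 g for
`us_like` — with realistic emission-factor orderings. See
[docs/methods.md](docs/methods.md) for model details and assumptions.

## Worked example

Run the shipped four-archetype study (about one minute on one CPU):

```bash
dietopt run-all --config configs/demo.yaml
```

With the shipped configuration (master seed 1), the guideline diets deliver
animal-protein shares of 0.41–0.53 across archetypes and exceed the 60 g
WHO protein reference by 41.7% (`us_like`) up to 46.7% (`nz_like`). For the
`us_like` archetype the knee-point solutions change cost and emissions
relative to the guideline baseline as follows:

| Scenario               | Emissions   | Cost     |
|------------------------|-------------|----------|
| MaxProt                | −29.4%      | −29.4%   |
| MaxVitamins_FBDG       | −22.8%      | +21.8%   |
| MaxVitamins_Protein    | −87.3%      | −38.0%   |
| MaxFattyAcids_FBDG     | −25.1%      | +25.3%   |
| MaxFattyAcids_Protein  | −85.5%      | −38.6%   |

Uniformly scaling the guideline to 60 g protein (MaxProt) cuts emissions and
cost by exactly the protein excess, 29.4%. Reoptimizing at the guideline's
own protein level improves adequacy but raises cost (+22–25%); combining
reoptimization with the 60 g protein target yields the deep emission cuts.
Under Monte Carlo perturbation of prices and emission factors (σ = 0.10,
50 runs) the selected `MaxFattyAcids_Protein` diet's emissions vary with a
coefficient of variation of 0.036. On the two-commodity validation toy the
NSGA-II front attains 103% of the 1 g-grid brute-force front's hypervolume
(continuous solutions slightly dominate grid points).

Artifacts land under `results/demo/`: per-country datasets and baseline
diets (`data/`), Pareto fronts with provenance sidecars (`fronts/`), Monte
Carlo and sensitivity tables (`robustness/`), comparison/heatmap/regression
tables (`report/`), and a `manifest.json` with SHA-256 checksums of every
artifact.

## Reproduction

Every stochastic stage derives its seed from the single master seed in the
config, so reruns reproduce every artifact hash exactly:

```bash
dietopt run-all --config configs/demo.yaml --seed 1
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script runs the full study at the given seed and writes the
headline quantities (protein shares and excesses, per-scenario cost and
emission changes, regression slope and R², Monte Carlo CV, oracle
hypervolume ratio) as JSON. The numbers in the table above are the seed-1
values from `results/acceptance.json`.

## Command-line interface

```
dietopt generate   --archetype us_like --seed 1 --out data/us   # synthetic dataset
dietopt translate  --data data/us --out diets/us.csv            # FBDG -> commodity diet
dietopt optimize   --config configs/demo.yaml                   # scenario fronts only
dietopt robustness --config configs/demo.yaml                   # + Monte Carlo, sweeps
dietopt report     --config configs/demo.yaml --render          # + rendered heatmap
dietopt run-all    --config configs/demo.yaml                   # everything
```

## Layout

- `src/dietopt/synthetic.py` — calibrated synthetic country generator
- `src/dietopt/translation.py` — FBDG group → commodity translation, recipe
  disaggregation, nutrient imputation, mass-balance validation
- `src/dietopt/scenarios.py` — scenario presets, EAT-Lancet reference,
  constraint compilation, feasibility checking
- `src/dietopt/objectives.py` — cost, emissions, adequacy, penalty
- `src/dietopt/optimizer.py` — NSGA-II, brute-force oracle, hypervolume
- `src/dietopt/robustness.py` — Monte Carlo, convergence, elasticities
- `src/dietopt/reporting.py` — knee points, OLS, report bundles
- `src/dietopt/pipeline.py`, `src/dietopt/cli.py` — orchestration and CLI
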