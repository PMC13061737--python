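# Shipped demonstration study: four synthetic country archetypes, all six
# scenarios, Monte Carlo + graduated sensitivity at reduced budget.
# Run with:  dietopt run-all --config configs/demo.yaml
outdir: results/demo
seed: 1

archetypes: [us_like, cn_like, au_like, nz_like]
scenarios:
  - Baseline_FBDG
  - MaxProt
  - MaxVitamins_FBDG
  - MaxVitamins_Protein
  - MaxFattyAcids_FBDG
  - MaxFattyAcids_Protein

# synthetic data
n_plant_commodities: 6
missingness_rate: 0.05
noise_scale: 0.05

# NSGA-II search budget
population_size: 64
generations: 40
crossover_prob: 0.7
mutation_prob: 0.2

# robustness (reduced budget: re-evaluation of the knee diet per run)
mc_runs: 50
mc_sigma: 0.10
mc_reoptimize: false
mc_population_size: 24
mc_generations: 12
robustness_archetypes: [us_like]
robustness_scenario: MaxFattyAcids_Protein
sensitivity_levels: [0.05, 0.10, 0.15, 0.20, 0.25]
sensitivity_parameters:
  - price_beef
  - price_poultry
  - price_fish
  - fish_availability

log_level: INFO
render_plots: false
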