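"""End-to-end orchestration: generate -> translate -> optimize -> robustness -> report.

The stages mirror the analysis workflow: country datasets are generated (or
loaded), FBDG recommendations are translated to commodity diets, each of the
six scenarios is compiled to constraints and searched (the two reference
scenarios are fixed points and skip the search), Monte Carlo and graduated
sensitivity quantify robustness of the selected solutions, and the report
bundle compares scenarios against the guideline baseline.

Every stochastic stage derives its seed deterministically from the single
master seed, so a rerun with the same config reproduces every artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dietopt.constants import ASF_CATEGORIES
from dietopt.io import (
    load_commodities,
    load_profile,
    save_commodities,
    save_front,
    save_profile,
    write_manifest,
)
from dietopt.objectives import (
    DietVector,
    ObjectiveValues,
    baseline_category_intakes,
    category_table,
    diet_to_vector,
    dietary_cost,
    dietary_emissions,
    nutrient_supply_and_adequacy,
    nutrition_objective,
    penalty,
)
from dietopt.optimizer import Individual, NSGAConfig, ParetoFront, evolve
from dietopt.reporting import build_report, knee_point, write_report_bundle
from dietopt.robustness import (
    DEFAULT_LEVELS,
    PerturbationConfig,
    perturb,
    run_monte_carlo,
    sensitivity_sweep,
)
from dietopt.scenarios import (
    SCENARIOS,
    ConstraintSet,
    EATLancetReference,
    ScenarioSpec,
    build_constraints,
    check_feasible,
    fill_protein_gap,
)
from dietopt.synthetic import (
    ARCHETYPES,
    CommodityRecord,
    CountryProfile,
    GeneratorConfig,
    generate_country_dataset,
    records_to_frame,
)
from dietopt.translation import allocate_groups, impute_missing_nutrients

logger = logging.getLogger(__name__)


@dataclass
class CountryContext:
    """Everything needed to evaluate diets for one country."""

    profile: CountryProfile
    records: list[CommodityRecord]
    table: pd.DataFrame          # commodity-level, imputed
    baseline_diet: object        # HarmonizedDiet
    cat_table: pd.DataFrame      # 8 ASF categories + plant groups
    baseline_categories: dict[str, float]
    plant_background: dict[str, float]
    reference: EATLancetReference


def make_context(
    profile: CountryProfile,
    records: list[CommodityRecord],
    reference: EATLancetReference | None = None,
) -> CountryContext:
    records = impute_missing_nutrients(records)
    table = records_to_frame(records)
    baseline = allocate_groups(profile)
    vec = diet_to_vector(baseline, table)
    return CountryContext(
        profile=profile,
        records=records,
        table=table,
        baseline_diet=baseline,
        cat_table=category_table(table, baseline),
        baseline_categories=baseline_category_intakes(baseline, table),
        plant_background=vec.plant_background,
        reference=reference or EATLancetReference(),
    )


def _violation_measure(violations: list[dict], constraints: ConstraintSet
                       ) -> float:
    """Sum of squared relative energy/protein violations."""
    total = 0.0
    for v in violations:
        name = v["constraint"]
        if name == "energy_band" and constraints.energy_band:
            scale = constraints.energy_band[0]
        elif name.startswith("protein"):
            scale = (constraints.total_protein_target
                     or constraints.total_protein_cap or 1.0)
        else:
            continue  # box/group bounds are enforced by repair
        total += (v["magnitude"] / scale) ** 2
    return total


def scenario_evaluator(ctx: CountryContext, spec: ScenarioSpec,
                       constraints: ConstraintSet):
    """Build the NSGA-II evaluator for one (country, scenario) pair.

    For each candidate ASF vector, plant intakes are rescaled to close the
    protein gap within the energy band, then cost, emissions, adequacy,
    quadratic deficit penalty (at the supplied adaptive scale) and the
    energy/protein violation measure are computed on the full diet.
    """
    cats = list(constraints.bounds)
    rda = {n: v for n, v in constraints.rda_active.items()}

    def evaluator(q: np.ndarray, scale: float) -> ObjectiveValues:
        asf = dict(zip(cats, map(float, np.clip(q, 0.0, None))))
        plants = fill_protein_gap(asf, ctx.plant_background, constraints,
                                  ctx.cat_table)
        Q = DietVector(asf=asf, plant_background=plants)
        adequacy = nutrient_supply_and_adequacy(Q, ctx.cat_table, rda)
        _, violations = check_feasible(asf, constraints, ctx.cat_table, plants)
        return ObjectiveValues(
            cost=dietary_cost(Q, ctx.cat_table),
            emissions=dietary_emissions(Q, ctx.cat_table),
            nutrition_score=nutrition_objective(adequacy, spec),
            penalty=penalty(adequacy, scale),
            violation=_violation_measure(violations, constraints),
        )

    return evaluator


def evaluate_pinned(ctx: CountryContext, spec: ScenarioSpec,
                    constraints: ConstraintSet) -> ParetoFront:
    """Evaluate a pinned (no-search) scenario as a single-member front."""
    q = np.array([constraints.bounds[c][0] for c in constraints.bounds])
    evaluator = scenario_evaluator(ctx, spec, constraints)
    ov = evaluator(q, scale=1.0)
    cats = list(constraints.bounds)
    plants = fill_protein_gap(dict(zip(cats, q)), ctx.plant_background,
                              constraints, ctx.cat_table)
    ind = Individual(
        Q=DietVector(asf=dict(zip(cats, map(float, q))),
                     plant_background=plants),
        objectives=ov, rank=0)
    return ParetoFront(members=[ind])


def run_scenario(
    ctx: CountryContext,
    spec: ScenarioSpec,
    nsga: NSGAConfig,
    constraints: ConstraintSet | None = None,
) -> tuple[ParetoFront, ConstraintSet]:
    """Compile one scenario's constraints and produce its Pareto front."""
    if constraints is None:
        constraints = build_constraints(spec, ctx.profile, ctx.reference,
                                        ctx.table)
    if spec.pinned:
        return evaluate_pinned(ctx, spec, constraints), constraints
    evaluator = scenario_evaluator(ctx, spec, constraints)
    cats = list(constraints.bounds)

    def make_diet(q: np.ndarray) -> DietVector:
        asf = dict(zip(cats, map(float, q)))
        plants = fill_protein_gap(asf, ctx.plant_background, constraints,
                                  ctx.cat_table)
        return DietVector(asf=asf, plant_background=plants)

    # seed the population with the guideline diet (clipped into bounds)
    lo = np.array([constraints.bounds[c][0] for c in cats])
    hi = np.array([constraints.bounds[c][1] for c in cats])
    baseline_q = np.clip(
        np.array([ctx.baseline_categories.get(c, 0.0) for c in cats]), lo, hi)
    front = evolve(baseline_q[None, :], nsga, evaluator, constraints,
                   make_diet=make_diet)
    return front, constraints


def evaluate_baseline(ctx: CountryContext) -> ObjectiveValues:
    """Objective values of the unmodified guideline diet."""
    spec = SCENARIOS["Baseline_FBDG"]
    constraints = build_constraints(spec, ctx.profile, ctx.reference, ctx.table)
    front = evaluate_pinned(ctx, spec, constraints)
    return front.members[0].objectives


# ---------------------------------------------------------------------------
# Robustness wiring
# ---------------------------------------------------------------------------

def _perturbed_table(table: pd.DataFrame, rng: np.random.Generator,
                     sigma: float, parameters: tuple[str, ...]) -> pd.DataFrame:
    out = table.copy()
    if "prices" in parameters:
        eps = rng.normal(0.0, sigma, size=len(out))
        out["producer_price"] = perturb(out["producer_price"].to_numpy(), eps)
    if "emission_factors" in parameters:
        eps = rng.normal(0.0, sigma, size=len(out))
        out["emission_factor"] = perturb(out["emission_factor"].to_numpy(), eps)
    return out


def monte_carlo_pipeline(
    ctx: CountryContext,
    spec: ScenarioSpec,
    constraints: ConstraintSet,
    pconfig: PerturbationConfig,
    metric: str = "emissions",
    reoptimize: bool = False,
    nsga: NSGAConfig | None = None,
    knee_diet: DietVector | None = None,
):
    """Build the per-run Monte Carlo callable for one scenario.

    In re-evaluation mode the knee-point diet from the unperturbed run is
    repriced under each perturbed table; in re-optimization mode the NSGA-II
    search is rerun (at a reduced budget) on the perturbed table and the new
    knee point is measured.
    """
    if not reoptimize and knee_diet is None:
        raise ValueError("re-evaluation mode needs the knee-point diet")

    def pipeline(rng: np.random.Generator) -> float:
        table = _perturbed_table(ctx.cat_table, rng, pconfig.sigma,
                                 pconfig.perturbed_parameters)
        pctx = dataclasses.replace(ctx, cat_table=table)
        if reoptimize:
            cfg = dataclasses.replace(
                nsga, seed=int(rng.integers(0, 2**31)))
            evaluator = scenario_evaluator(pctx, spec, constraints)
            front = evolve(None, cfg, evaluator, constraints)
            ov = knee_point(front).objectives
        else:
            evaluator = scenario_evaluator(pctx, spec, constraints)
            cats = list(constraints.bounds)
            q = np.array([knee_diet.asf.get(c, 0.0) for c in cats])
            ov = evaluator(q, 1.0)
        return getattr(ov, metric if metric != "nutrition" else
                       "nutrition_score")

    return pipeline


def sensitivity_pipeline(
    ctx: CountryContext,
    spec: ScenarioSpec,
    constraints: ConstraintSet,
    nsga: NSGAConfig,
    metric: str = "cost",
):
    """Deterministic perturbation callable for the graduated sweep.

    Parameters named ``price_<category>`` scale that category's producer
    price; ``fish_availability`` scales the fish category's upper intake
    bound (availability constrains intake, not price).  Each call reruns the
    reduced-budget search at a fixed seed so differences reflect only the
    perturbed parameter.
    """
    def pipeline(param: str, factor: float) -> float:
        table = ctx.cat_table
        cons = constraints
        if param.startswith("price_"):
            cat = param.removeprefix("price_")
            table = table.copy()
            table.loc[cat, "producer_price"] *= factor
        elif param == "fish_availability":
            lo, hi = constraints.bounds["fish"]
            bounds = dict(constraints.bounds)
            bounds["fish"] = (lo, hi * factor)
            group_bounds = {
                name: (cats, g_lo, g_hi * factor if "fish" in cats else g_hi)
                for name, (cats, g_lo, g_hi) in constraints.group_bounds.items()
            }
            cons = dataclasses.replace(constraints, bounds=bounds,
                                       group_bounds=group_bounds)
        else:
            raise ValueError(f"unknown sensitivity parameter {param!r}")
        pctx = dataclasses.replace(ctx, cat_table=table)
        evaluator = scenario_evaluator(pctx, spec, cons)
        front = evolve(None, nsga, evaluator, cons)
        ov = knee_point(front).objectives
        return getattr(ov, metric if metric != "nutrition" else
                       "nutrition_score")

    return pipeline


# ---------------------------------------------------------------------------
# Pipeline configuration and runner
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    archetypes: tuple[str, ...] = ARCHETYPES
    scenarios: tuple[str, ...] = tuple(SCENARIOS)
    dataset_dir: str | None = None      # load datasets instead of generating
    n_plant_commodities: int = 6
    missingness_rate: float = 0.0
    noise_scale: float = 0.05
    population_size: int = 64
    generations: int = 40
    crossover_prob: float = 0.7
    mutation_prob: float = 0.2
    mc_runs: int = 50
    mc_sigma: float = 0.10
    mc_reoptimize: bool = False
    mc_population_size: int = 24
    mc_generations: int = 12
    robustness_archetypes: tuple[str, ...] | None = None
    robustness_scenario: str = "MaxFattyAcids_Protein"
    sensitivity_levels: tuple[float, ...] = DEFAULT_LEVELS
    sensitivity_parameters: tuple[str, ...] = (
        "price_beef", "price_pork", "price_poultry", "price_fish",
        "price_eggs", "price_dairy", "fish_availability",
    )
    log_level: str = "INFO"
    render_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("archetypes", "scenarios", "robustness_archetypes",
                    "sensitivity_levels", "sensitivity_parameters"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for arch in self.archetypes:
            if arch not in ARCHETYPES:
                raise ValueError(f"unknown archetype {arch!r}")
        for scen in self.scenarios:
            if scen not in SCENARIOS:
                raise ValueError(f"unknown scenario {scen!r}")
        if self.dataset_dir is not None and not Path(self.dataset_dir).exists():
            raise ValueError(f"dataset_dir {self.dataset_dir!r} does not exist")


def _stage_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0]
               % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write artifacts under ``config.outdir``."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = EATLancetReference()
    results: dict = dict(fronts={}, baselines={}, robustness={})
    contexts: dict[str, CountryContext] = {}
    fronts: dict[tuple[str, str], ParetoFront] = {}
    constraint_sets: dict[tuple[str, str], ConstraintSet] = {}

    for ai, arch in enumerate(config.archetypes):
        logger.info("stage=generate country=%s", arch)
        if config.dataset_dir:
            profile = load_profile(Path(config.dataset_dir) / arch / "profile")
            records = load_commodities(
                Path(config.dataset_dir) / arch / "commodities.csv")
        else:
            profile, records = generate_country_dataset(GeneratorConfig(
                seed=_stage_seed(config.seed, 0, ai),
                archetype=arch,
                n_plant_commodities=config.n_plant_commodities,
                missingness_rate=config.missingness_rate,
                noise_scale=config.noise_scale,
            ))
        data_dir = outdir / "data" / arch
        data_dir.mkdir(parents=True, exist_ok=True)
        save_commodities(records, data_dir / "commodities.csv")
        save_profile(profile, data_dir / "profile")

        logger.info("stage=translate country=%s", arch)
        ctx = make_context(profile, records, reference)
        contexts[arch] = ctx
        pd.Series(ctx.baseline_diet.intakes, name="g_per_day").rename_axis(
            "commodity_id").to_csv(data_dir / "baseline_diet.csv")

        results["baselines"][arch] = evaluate_baseline(ctx)

        front_dir = outdir / "fronts"
        front_dir.mkdir(exist_ok=True)
        for si, scen in enumerate(config.scenarios):
            logger.info("stage=optimize country=%s scenario=%s", arch, scen)
            nsga = NSGAConfig(
                population_size=config.population_size,
                generations=config.generations,
                crossover_prob=config.crossover_prob,
                mutation_prob=config.mutation_prob,
                seed=_stage_seed(config.seed, 1, ai, si),
            )
            front, cons = run_scenario(ctx, SCENARIOS[scen], nsga)
            fronts[(arch, scen)] = front
            constraint_sets[(arch, scen)] = cons
            save_front(front, front_dir / f"{arch}__{scen}.csv",
                       meta=dict(country=arch, scenario=scen, seed=nsga.seed,
                                 population_size=nsga.population_size,
                                 generations=nsga.generations))

    results["fronts"] = fronts

    # robustness on a subset of countries (every run re-prices or re-solves)
    rob_dir = outdir / "robustness"
    rob_dir.mkdir(exist_ok=True)
    rob_archs = (config.robustness_archetypes
                 if config.robustness_archetypes is not None
                 else (config.archetypes[0],))
    scen = config.robustness_scenario
    for ai, arch in enumerate(rob_archs):
        if (arch, scen) not in fronts:
            continue
        logger.info("stage=robustness country=%s scenario=%s", arch, scen)
        ctx = contexts[arch]
        cons = constraint_sets[(arch, scen)]
        pconfig = PerturbationConfig(
            sigma=config.mc_sigma, n_runs=config.mc_runs,
            seed=_stage_seed(config.seed, 2, ai),
            levels=config.sensitivity_levels)
        knee = knee_point(fronts[(arch, scen)])
        small = NSGAConfig(population_size=config.mc_population_size,
                           generations=config.mc_generations,
                           seed=_stage_seed(config.seed, 3, ai))
        mc_pipe = monte_carlo_pipeline(
            ctx, SCENARIOS[scen], cons, pconfig, metric="emissions",
            reoptimize=config.mc_reoptimize, nsga=small, knee_diet=knee.Q)
        mc = run_monte_carlo(mc_pipe, pconfig)
        pd.DataFrame(dict(run=np.arange(len(mc.per_run)),
                          emissions=mc.per_run)).to_csv(
            rob_dir / f"{arch}__mc_runs.csv", index=False)
        sens_pipe = sensitivity_pipeline(ctx, SCENARIOS[scen], cons, small,
                                         metric="cost")
        estimates = sensitivity_sweep(sens_pipe, pconfig,
                                      parameters=config.sensitivity_parameters)
        pd.DataFrame([dataclasses.asdict(e) for e in estimates]).to_csv(
            rob_dir / f"{arch}__sensitivity.csv", index=False)
        summary = dict(mean=mc.mean, sd=mc.sd, cv=mc.cv,
                       ci95=list(mc.ci95), n_runs=len(mc.per_run),
                       n_failed=mc.n_failed)
        with open(rob_dir / f"{arch}__mc_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        results["robustness"][arch] = dict(monte_carlo=mc,
                                           sensitivity=estimates)

    logger.info("stage=report")

    def adequacy_fn(country: str, ind: Individual):
        c = contexts[country]
        return nutrient_supply_and_adequacy(ind.Q, c.cat_table, c.profile.rda)

    bundle = build_report(fronts, results["baselines"], reference=reference,
                          adequacy_fn=adequacy_fn)
    write_report_bundle(bundle, outdir / "report", render=config.render_plots)
    results["report"] = bundle

    write_manifest(outdir, dataclasses.asdict(config), config.seed)
    return results
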