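"""Scenario comparison statistics and report assembly.

A scenario is summarized by its Pareto front's knee point: the member
closest, after per-axis min-max normalization, to the ideal point.  Reports
compare knee points against the country baseline (relative changes in cost,
emissions, nutrition), regress dietary cost on emissions per country (OLS
with slope CI and two-sided p), tabulate EAT-Lancet compliance ratios, and
emit heatmap/radar data matrices.  Rendering is optional; every acceptance
check operates on the matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from dietopt.objectives import NutrientAdequacy, ObjectiveValues
from dietopt.optimizer import Individual, ParetoFront, penalized_triple
from dietopt.scenarios import EATLancetReference, eat_lancet_ratio


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_ci95: tuple[float, float]
    p_value: float
    n: int


def relative_change(baseline: float, scenario: float) -> float:
    """Percent change of a scenario value relative to baseline."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * (scenario - baseline) / baseline


def ols_cost_vs_environment(
    points: list[tuple[float, float]] | np.ndarray,
) -> RegressionResult:
    """OLS of dietary cost (y) against emissions (x) across candidates.

    Returns the slope with its 95% CI and two-sided p-value (t statistic,
    n-2 df) and the regression R^2.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >= 3 (emissions, cost) points")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate emissions variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        slope_ci95=(float(ci[1][0]), float(ci[1][1])),
        p_value=float(model.pvalues[1]),
        n=len(arr),
    )


def pearson_correlation(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need two equal-length series with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance series")
    return float(stats.pearsonr(x, y)[0])


def knee_point(front: ParetoFront) -> Individual:
    """Front member closest to the ideal point after min-max normalization.

    Axes are the penalized minimize-orientation objectives; degenerate axes
    (zero range over the front) are ignored.  Ties break to the first member.
    """
    if not front.members:
        raise ValueError("empty front")
    F = front.objective_array()
    lo, hi = F.min(axis=0), F.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    norm = (F - lo) / span
    norm[:, hi <= lo] = 0.0
    d = np.sqrt((norm**2).sum(axis=1))
    return front.members[int(np.argmin(d))]


def build_report(
    fronts: dict[tuple[str, str], ParetoFront],
    baselines: dict[str, ObjectiveValues],
    baseline_scenario: str = "Baseline_FBDG",
    reference: EATLancetReference | None = None,
    adequacy_fn: Callable[[str, Individual], NutrientAdequacy] | None = None,
    regression_points: str = "front",
) -> dict[str, pd.DataFrame]:
    """Assemble the scenario-comparison report bundle.

    ``fronts`` maps (country, scenario) to a Pareto front; ``baselines``
    holds each country's evaluated guideline diet.  ``regression_points``
    selects what feeds each country's cost-vs-emissions OLS: every front
    member ("front"), one knee point per scenario ("knee"), or knee points
    plus the baseline ("knee+baseline").
    """
    countries = sorted({c for c, _ in fronts})
    missing = [c for c in countries if c not in baselines]
    if missing:
        raise ValueError(f"missing baselines for: {missing}")

    comp_rows, eat_rows, radar_rows = [], [], []
    reg_results = {}
    for country in countries:
        scen_fronts = {s: f for (c, s), f in fronts.items() if c == country}
        base = baselines[country]
        points = []
        for scen in sorted(scen_fronts):
            knee = knee_point(scen_fronts[scen])
            ov = knee.objectives
            for metric, b_val, s_val in (
                ("cost", base.cost, ov.cost),
                ("emissions", base.emissions, ov.emissions),
                ("nutrition", base.nutrition_score, ov.nutrition_score),
            ):
                change = (0.0 if scen == baseline_scenario
                          else relative_change(b_val, s_val))
                comp_rows.append(dict(
                    country=country, scenario=scen, metric=metric,
                    baseline_value=b_val, scenario_value=s_val,
                    relative_change_pct=change,
                ))
            if reference is not None:
                for cat, ratio in eat_lancet_ratio(knee.Q.asf, reference).items():
                    eat_rows.append(dict(country=country, scenario=scen,
                                         category=cat, ratio=ratio))
            if adequacy_fn is not None:
                adequacy = adequacy_fn(country, knee)
                for nut, ratio in adequacy.ratio.items():
                    radar_rows.append(dict(country=country, scenario=scen,
                                           nutrient=nut, ratio=ratio))
            if regression_points == "knee":
                points.append((ov.emissions, ov.cost))
            elif regression_points == "knee+baseline":
                points.append((ov.emissions, ov.cost))
            else:
                points.extend(
                    (m.objectives.emissions, m.objectives.cost)
                    for m in scen_fronts[scen].members
                )
        if regression_points == "knee+baseline":
            points.append((base.emissions, base.cost))
        try:
            reg_results[country] = ols_cost_vs_environment(points)
        except ValueError:
            reg_results[country] = None

    comparisons = pd.DataFrame(comp_rows)
    reg_rows = []
    for country, res in reg_results.items():
        if res is None:
            continue
        reg_rows.append(dict(country=country, slope=res.slope,
                             intercept=res.intercept, r_squared=res.r_squared,
                             slope_ci_lo=res.slope_ci95[0],
                             slope_ci_hi=res.slope_ci95[1],
                             p_value=res.p_value, n=res.n))
    regressions = pd.DataFrame(reg_rows)

    heatmap = comparisons[comparisons["metric"] == "emissions"].pivot(
        index="country", columns="scenario", values="relative_change_pct")

    bundle = dict(comparisons=comparisons, regressions=regressions,
                  heatmap=heatmap)
    if eat_rows:
        bundle["eat_ratios"] = pd.DataFrame(eat_rows)
    if radar_rows:
        bundle["radar"] = pd.DataFrame(radar_rows).pivot_table(
            index=["country", "scenario"], columns="nutrient", values="ratio")
    return bundle


def write_report_bundle(bundle: dict[str, pd.DataFrame], outdir: str | Path,
                        render: bool = False) -> dict:
    """Write report tables as CSV plus a JSON index; optionally render PNGs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = {}
    for name, frame in bundle.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path)
        index[name] = path.name
    if render:
        _render_plots(bundle, outdir, index)
    with open(outdir / "index.json", "w") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)
    return index


def _render_plots(bundle: dict[str, pd.DataFrame], outdir: Path,
                  index: dict) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    if "heatmap" in bundle:
        fig, ax = plt.subplots(figsize=(8, 4))
        hm = bundle["heatmap"]
        im = ax.imshow(hm.to_numpy(), cmap="RdYlGn_r", aspect="auto")
        ax.set_xticks(range(len(hm.columns)), hm.columns, rotation=45,
                      ha="right")
        ax.set_yticks(range(len(hm.index)), hm.index)
        fig.colorbar(im, ax=ax, label="emissions change vs baseline (%)")
        fig.tight_layout()
        fig.savefig(outdir / "heatmap.png", dpi=120)
        plt.close(fig)
        index["heatmap_png"] = "heatmap.png"


def front_to_frame(front: ParetoFront) -> pd.DataFrame:
    """Flatten a Pareto front into a table of intakes and objectives."""
    rows = []
    for m in front.members:
        row = {f"q_{k}": v for k, v in m.Q.asf.items()}
        row.update(cost=m.objectives.cost, emissions=m.objectives.emissions,
                   nutrition=m.objectives.nutrition_score,
                   penalty=m.objectives.penalty,
                   violation=m.objectives.violation)
        rows.append(row)
    frame = pd.DataFrame(rows)
    trip = np.array([penalized_triple(m.objectives) for m in front.members])
    if len(trip):
        frame["penalized_cost"] = trip[:, 0]
        frame["penalized_emissions"] = trip[:, 1]
    return frame
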