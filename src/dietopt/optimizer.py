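"""Penalty-constrained NSGA-II over the ASF intake space.

The search minimizes dietary cost and emissions while maximizing a nutrient
adequacy score.  Nutrient-deficit penalties are folded into dominance by
adding the (adaptively scaled) penalty to both minimized axes and
subtracting it from the nutrition axis; energy/protein constraint violations
are handled feasibility-first in tournament selection and survival, the
standard constrained-NSGA-II rule.

Variables are real-coded with simulated binary crossover (eta=15) and
polynomial mutation (eta=20), clipped to the box bounds; shared group caps
(e.g. total red meat) are enforced by proportional repair.  An external
archive keeps every non-dominated feasible solution found, which makes the
attained hypervolume nondecreasing over generations and the best value per
objective monotone.

``brute_force_pareto`` provides the exact oracle on enumerable grids for
validating the search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from dietopt.objectives import DietVector, ObjectiveValues
from dietopt.scenarios import ConstraintSet

Evaluator = Callable[[np.ndarray, float], ObjectiveValues]

OBJECTIVE_SENSE = (("cost", "min"), ("emissions", "min"), ("nutrition", "max"))


@dataclass
class Individual:
    Q: DietVector
    objectives: ObjectiveValues
    rank: int | None = None
    crowding: float | None = None


@dataclass
class NSGAConfig:
    population_size: int = 200
    generations: int = 100
    crossover_prob: float = 0.7
    mutation_prob: float = 0.2
    seed: int = 0
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    penalty_scale: float = 10.0   # base adaptive-penalty coefficient
    archive_max: int = 512

    def validate(self) -> None:
        if self.population_size <= 0 or self.generations <= 0:
            raise ValueError("population_size and generations must be > 0")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class ParetoFront:
    members: list[Individual]
    objective_sense: tuple = OBJECTIVE_SENSE
    history: list[dict] = field(default_factory=list)

    def objective_array(self) -> np.ndarray:
        """Penalized minimize-orientation objective matrix, one row/member."""
        return np.array([
            penalized_triple(m.objectives) for m in self.members
        ])


def penalized_triple(o: ObjectiveValues) -> tuple[float, float, float]:
    """Map ObjectiveValues to a minimize-all triple with penalty folded in."""
    return (
        o.cost + o.penalty,
        o.emissions + o.penalty,
        -(o.nutrition_score - o.penalty),
    )


def dominates(a: ObjectiveValues, b: ObjectiveValues) -> bool:
    """Pareto dominance: no worse on all axes, strictly better on >= 1."""
    ta, tb = penalized_triple(a), penalized_triple(b)
    return all(x <= y for x, y in zip(ta, tb)) and any(
        x < y for x, y in zip(ta, tb))


def _dominates_rows(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def non_dominated_sort(population: Sequence[Individual]) -> list[list[Individual]]:
    """Fast non-dominated sorting into fronts; assigns ranks in place."""
    for ind in population:
        if ind.objectives is None:
            raise ValueError("unevaluated individual in population")
    F = np.array([penalized_triple(ind.objectives) for ind in population])
    fronts_idx = _sort_rows(F)
    fronts = []
    for rank, idxs in enumerate(fronts_idx):
        front = [population[i] for i in idxs]
        for ind in front:
            ind.rank = rank
        fronts.append(front)
    return fronts


def _sort_rows(F: np.ndarray) -> list[list[int]]:
    n = len(F)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates_rows(F[i], F[j]):
                dominated_by[i].append(j)
                counts[j] += 1
            elif _dominates_rows(F[j], F[i]):
                dominated_by[j].append(i)
                counts[i] += 1
    fronts = []
    current = [i for i in range(n) if counts[i] == 0]
    while current:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                counts[j] -= 1
                if counts[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def crowding_distance(front: Sequence[Individual]) -> np.ndarray:
    """Crowding distances; boundary members per objective get infinity.

    Interior distances are sums of range-normalized neighbor gaps; the
    result is invariant to the order members are supplied in.
    """
    if len(front) == 0:
        raise ValueError("empty front")
    F = np.array([penalized_triple(ind.objectives) for ind in front])
    n, m = F.shape
    dist = np.zeros(n)
    if n <= 2:
        dist[:] = np.inf
    else:
        for k in range(m):
            order = np.argsort(F[:, k], kind="stable")
            span = F[order[-1], k] - F[order[0], k]
            dist[order[0]] = dist[order[-1]] = np.inf
            if span > 0:
                gaps = (F[order[2:], k] - F[order[:-2], k]) / span
                dist[order[1:-1]] += gaps
    for ind, d in zip(front, dist):
        ind.crowding = float(d)
    return dist


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _sbx(p1: np.ndarray, p2: np.ndarray, eta: float, prob: float,
         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > prob:
        return c1, c2
    for k in range(len(p1)):
        if rng.random() > 0.5 or p1[k] == p2[k]:
            continue
        u = rng.random()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else (
            1 / (2 * (1 - u))) ** (1 / (eta + 1))
        c1[k] = 0.5 * ((1 + beta) * p1[k] + (1 - beta) * p2[k])
        c2[k] = 0.5 * ((1 - beta) * p1[k] + (1 + beta) * p2[k])
    return c1, c2


def _poly_mutation(x: np.ndarray, lo: np.ndarray, hi: np.ndarray, eta: float,
                   prob: float, rng: np.random.Generator) -> np.ndarray:
    y = x.copy()
    for k in range(len(x)):
        if hi[k] <= lo[k] or rng.random() > prob:
            continue
        u = rng.random()
        delta = (2 * u) ** (1 / (eta + 1)) - 1 if u < 0.5 else (
            1 - (2 * (1 - u)) ** (1 / (eta + 1)))
        y[k] = x[k] + delta * (hi[k] - lo[k])
    return y


def _repair(q: np.ndarray, lo: np.ndarray, hi: np.ndarray,
            group_bounds: list[tuple[np.ndarray, float, float]]) -> np.ndarray:
    q = np.clip(q, lo, hi)
    for idx, g_lo, g_hi in group_bounds:
        s = q[idx].sum()
        if s > g_hi > 0:
            q[idx] *= g_hi / s
        elif s > g_hi:  # g_hi == 0
            q[idx] = 0.0
    return q


def latin_hypercube(lo: np.ndarray, hi: np.ndarray, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Latin-hypercube sample of n points inside the box [lo, hi]."""
    d = len(lo)
    u = (rng.permuted(np.tile(np.arange(n), (d, 1)), axis=1).T
         + rng.random((n, d))) / n
    return lo + u * (hi - lo)


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _constrained_better(vi: float, vj: float, ranki: int, rankj: int,
                        crowdi: float, crowdj: float) -> bool:
    """Feasibility-first comparator: less violation, then rank, then crowding."""
    if vi != vj:
        return vi < vj
    if ranki != rankj:
        return ranki < rankj
    return crowdi > crowdj


def evolve(
    initial: np.ndarray | None,
    config: NSGAConfig,
    evaluator: Evaluator,
    constraints: ConstraintSet,
    make_diet: Callable[[np.ndarray], DietVector] | None = None,
) -> ParetoFront:
    """Run the penalty-constrained NSGA-II and return the archived front.

    ``evaluator(q, scale)`` must return ObjectiveValues for any q inside the
    box bounds; ``scale`` is the adaptive penalty coefficient, which grows
    linearly from the base value to twice the base over the run.  ``initial``
    may seed the population (e.g. with the baseline diet); remaining slots
    are filled by Latin-hypercube sampling.  Fixed seed implies an identical
    front.
    """
    config.validate()
    cats = list(constraints.bounds)
    lo = np.array([constraints.bounds[c][0] for c in cats], dtype=float)
    hi = np.array([constraints.bounds[c][1] for c in cats], dtype=float)
    if np.any(lo > hi):
        raise ValueError("infeasible bounds: lo > hi")
    group_bounds = [
        (np.array([cats.index(c) for c in gc if c in cats], dtype=int), g_lo, g_hi)
        for gc, g_lo, g_hi in constraints.group_bounds.values()
    ]
    if make_diet is None:
        def make_diet(q: np.ndarray) -> DietVector:
            return DietVector(asf=dict(zip(cats, map(float, q))))

    rng = np.random.default_rng(config.seed)
    n = config.population_size
    pop_q = latin_hypercube(lo, hi, n, rng)
    if initial is not None:
        initial = np.atleast_2d(np.asarray(initial, dtype=float))
        k = min(len(initial), n)
        pop_q[:k] = initial[:k]
    pop_q = np.array([_repair(q, lo, hi, group_bounds) for q in pop_q])

    def scale_at(gen: int) -> float:
        return config.penalty_scale * (1.0 + gen / config.generations)

    def evaluate(Q: np.ndarray, gen: int) -> list[Individual]:
        s = scale_at(gen)
        return [Individual(Q=make_diet(q), objectives=evaluator(q, s))
                for q in Q]

    pop = evaluate(pop_q, 0)
    archive: list[Individual] = []
    history: list[dict] = []
    _update_archive(archive, pop, config.archive_max)
    _record(history, 0, archive, pop)

    for gen in range(1, config.generations + 1):
        fronts = non_dominated_sort(pop)
        for front in fronts:
            crowding_distance(front)
        viol = [ind.objectives.violation for ind in pop]

        def tournament() -> int:
            i, j = rng.integers(0, len(pop), size=2)
            return i if _constrained_better(
                viol[i], viol[j], pop[i].rank, pop[j].rank,
                pop[i].crowding, pop[j].crowding) else j

        child_q = []
        while len(child_q) < n:
            p1 = pop_q[tournament()]
            p2 = pop_q[tournament()]
            c1, c2 = _sbx(p1, p2, config.eta_crossover, config.crossover_prob, rng)
            c1 = _poly_mutation(c1, lo, hi, config.eta_mutation,
                                config.mutation_prob, rng)
            c2 = _poly_mutation(c2, lo, hi, config.eta_mutation,
                                config.mutation_prob, rng)
            child_q.append(_repair(c1, lo, hi, group_bounds))
            if len(child_q) < n:
                child_q.append(_repair(c2, lo, hi, group_bounds))
        child_q = np.array(child_q)
        children = evaluate(child_q, gen)

        combined = pop + children
        combined_q = np.vstack([pop_q, child_q])
        # feasibility-first survival: feasible individuals fill first, ranked
        # by dominance and crowding; infeasible ones follow by violation
        order = _survival_order(combined)
        keep = order[:n]
        pop = [combined[i] for i in keep]
        pop_q = combined_q[keep]

        _update_archive(archive, children, config.archive_max)
        _record(history, gen, archive, pop)

    members = [ind for ind in archive]
    if not members:  # no feasible solution found; fall back to final front
        members = non_dominated_sort(pop)[0]
    front = ParetoFront(members=members, history=history)
    return front


def _survival_order(combined: list[Individual]) -> list[int]:
    viol = [ind.objectives.violation for ind in combined]
    feas = [i for i, v in enumerate(viol) if v <= 0]
    infeas = sorted((i for i, v in enumerate(viol) if v > 0),
                    key=lambda i: viol[i])
    order: list[int] = []
    if feas:
        F = np.array([penalized_triple(combined[i].objectives) for i in feas])
        for rank, front_idx in enumerate(_sort_rows(F)):
            front = [combined[feas[k]] for k in front_idx]
            for ind in front:
                ind.rank = rank
            dist = crowding_distance(front)
            ranked = sorted(range(len(front_idx)), key=lambda k: -dist[k])
            order.extend(feas[front_idx[k]] for k in ranked)
    order.extend(infeas)
    return order


def _update_archive(archive: list[Individual], new: list[Individual],
                    max_size: int) -> None:
    candidates = archive + [
        ind for ind in new if ind.objectives.violation <= 0
    ]
    if not candidates:
        return
    F = np.array([penalized_triple(ind.objectives) for ind in candidates])
    mask = _pareto_mask(F)
    # drop duplicate objective vectors, keeping the first occurrence
    seen: set[tuple] = set()
    kept = []
    for i in np.flatnonzero(mask):
        key = tuple(F[i])
        if key not in seen:
            seen.add(key)
            kept.append(candidates[i])
    if len(kept) > max_size:
        dist = crowding_distance(kept)
        ranked = sorted(range(len(kept)), key=lambda k: -dist[k])[:max_size]
        kept = [kept[k] for k in sorted(ranked)]
    archive[:] = kept


def _record(history: list[dict], gen: int, archive: list[Individual],
            pop: list[Individual]) -> None:
    source = archive if archive else pop
    F = np.array([penalized_triple(ind.objectives) for ind in source])
    history.append(dict(
        generation=gen,
        archive_size=len(archive),
        best=dict(cost=float(F[:, 0].min()), emissions=float(F[:, 1].min()),
                  nutrition=float(-F[:, 2].min())),
        archive_objectives=F if source is archive else None,
    ))


# ---------------------------------------------------------------------------
# Exact oracle and hypervolume
# ---------------------------------------------------------------------------

def brute_force_pareto(
    grid: np.ndarray,
    evaluator: Evaluator,
    make_diet: Callable[[np.ndarray], DietVector] | None = None,
    max_points: int = 10**6,
) -> ParetoFront:
    """Exact maximal non-dominated set of an enumerated candidate grid."""
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if len(grid) > max_points:
        raise ValueError(f"grid of {len(grid)} points exceeds {max_points}")
    if make_diet is None:
        def make_diet(q: np.ndarray) -> DietVector:
            return DietVector(asf={f"x{k}": float(v) for k, v in enumerate(q)})
    inds = [Individual(Q=make_diet(q), objectives=evaluator(q, 1.0))
            for q in grid]
    F = np.array([penalized_triple(ind.objectives) for ind in inds])
    keep = _pareto_mask(F)
    members = [ind for ind, k in zip(inds, keep) if k]
    for m in members:
        m.rank = 0
    return ParetoFront(members=members)


def _pareto_mask(F: np.ndarray) -> np.ndarray:
    """Boolean mask of non-dominated rows (minimize all columns)."""
    n = len(F)
    keep = np.ones(n, dtype=bool)
    order = np.lexsort(F.T[::-1])  # sort by first column, then others
    F_sorted = F[order]
    for i in range(n):
        if not keep[order[i]]:
            continue
        fi = F_sorted[i]
        later = F_sorted[i + 1:]
        dominated = np.all(later >= fi, axis=1) & np.any(later > fi, axis=1)
        keep[order[i + 1:][dominated]] = False
    return keep


def hypervolume(points: np.ndarray, ref: np.ndarray) -> float:
    """Hypervolume (minimize orientation) dominated by ``points`` w.r.t ``ref``.

    Supports 2 and 3 objectives.  Points at or beyond the reference point
    contribute nothing.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ref = np.asarray(ref, dtype=float)
    points = points[np.all(points < ref, axis=1)]
    if len(points) == 0:
        return 0.0
    points = points[_pareto_mask(points)]
    if points.shape[1] == 2:
        return _hv2(points, ref)
    if points.shape[1] == 3:
        zs = np.unique(points[:, 2])
        hv = 0.0
        edges = np.append(zs, ref[2])
        for t, z in enumerate(zs):
            sub = points[points[:, 2] <= z][:, :2]
            sub = sub[_pareto_mask(sub)]
            hv += _hv2(sub, ref[:2]) * (edges[t + 1] - edges[t])
        return hv
    raise ValueError("hypervolume supports 2 or 3 objectives")


def _hv2(points: np.ndarray, ref: np.ndarray) -> float:
    pts = points[np.argsort(points[:, 0], kind="stable")]
    hv = 0.0
    prev_y = ref[1]
    for x, y in pts:
        if y < prev_y:
            hv += (ref[0] - x) * (prev_y - y)
            prev_y = y
    return hv
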