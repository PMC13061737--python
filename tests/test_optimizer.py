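"""NSGA-II machinery against exact oracles: sorting, crowding, hypervolume,
grid-enumeration equivalence, elitism, determinism, and penalty pressure."""

import numpy as np
import pytest

from dietopt.objectives import ObjectiveValues
from dietopt.optimizer import (
    Individual,
    NSGAConfig,
    brute_force_pareto,
    crowding_distance,
    dominates,
    evolve,
    hypervolume,
    non_dominated_sort,
    penalized_triple,
)
from dietopt.scenarios import ConstraintSet


def ov(cost, emis, nut, pen=0.0, viol=0.0):
    return ObjectiveValues(cost, emis, nut, penalty=pen, violation=viol)


def ind(cost, emis, nut, pen=0.0):
    return Individual(Q=None, objectives=ov(cost, emis, nut, pen))


# ---------------------------------------------------------------------------
# Dominance and sorting
# ---------------------------------------------------------------------------

def test_dominates_examples():
    assert dominates(ov(1, 1, 0.9), ov(2, 2, 0.5))
    assert not dominates(ov(1, 1, 0.9), ov(1, 1, 0.9))  # non-strict
    assert not dominates(ov(1, 3, 0.9), ov(2, 2, 0.9))  # trade-off
    assert not dominates(ov(2, 2, 0.5), ov(1, 1, 0.9))


def test_dominates_incorporates_penalty():
    # equal raw objectives, but a penalty makes the second strictly worse
    assert dominates(ov(1, 1, 0.9), ov(1, 1, 0.9, pen=0.1))


def test_sort_mutually_nondominated_single_front():
    pop = [ind(1, 3, 0.5), ind(2, 2, 0.5), ind(3, 1, 0.5)]
    fronts = non_dominated_sort(pop)
    assert len(fronts) == 1 and len(fronts[0]) == 3
    assert all(p.rank == 0 for p in pop)


def test_sort_chain_three_singletons():
    pop = [ind(3, 3, 0.1), ind(2, 2, 0.5), ind(1, 1, 0.9)]
    fronts = non_dominated_sort(pop)
    assert [len(f) for f in fronts] == [1, 1, 1]
    assert fronts[0][0].objectives.cost == 1


def test_sort_matches_naive_oracle(rng):
    """Random populations: fronts equal the O(n^2) peeling oracle."""
    def naive(F):
        def dom(a, b):
            return all(x <= y for x, y in zip(a, b)) and any(
                x < y for x, y in zip(a, b))
        remaining = list(range(len(F)))
        fronts = []
        while remaining:
            front = [i for i in remaining
                     if not any(dom(F[j], F[i]) for j in remaining if j != i)]
            fronts.append(sorted(front))
            remaining = [i for i in remaining if i not in front]
        return fronts

    for _ in range(5):
        pop = [ind(*rng.uniform(0, 1, 3)) for _ in range(50)]
        F = [penalized_triple(p.objectives) for p in pop]
        got = non_dominated_sort(pop)
        expected = naive(F)
        got_idx = [sorted(pop.index(p) for p in front) for front in got]
        assert got_idx == expected


def test_sort_rejects_unevaluated():
    with pytest.raises(ValueError, match="unevaluated"):
        non_dominated_sort([Individual(Q=None, objectives=None)])


# ---------------------------------------------------------------------------
# Crowding distance
# ---------------------------------------------------------------------------

def test_crowding_small_fronts_all_infinite():
    assert np.all(np.isinf(crowding_distance([ind(1, 1, 1)])))
    assert np.all(np.isinf(crowding_distance([ind(1, 2, 1), ind(2, 1, 1)])))


def test_crowding_collinear_equal_spacing():
    front = [ind(0, 5, 0.5), ind(1, 4, 0.5), ind(2, 3, 0.5)]
    d = crowding_distance(front)
    assert np.isinf(d[0]) and np.isinf(d[2])
    assert np.isfinite(d[1])


def test_crowding_matches_hand_computation_n4():
    # single varying axis: cost = 0, 1, 3, 6; other axes constant
    front = [ind(0, 1, 0.5), ind(1, 1, 0.5), ind(3, 1, 0.5), ind(6, 1, 0.5)]
    d = crowding_distance(front)
    assert np.isinf(d[0]) and np.isinf(d[3])
    assert d[1] == pytest.approx((3 - 0) / 6)
    assert d[2] == pytest.approx((6 - 1) / 6)


def test_crowding_permutation_invariant(rng):
    front = [ind(*rng.uniform(0, 1, 3)) for _ in range(8)]
    d1 = crowding_distance(front)
    perm = rng.permutation(8)
    d2 = crowding_distance([front[i] for i in perm])
    assert np.allclose(d1[perm], d2)


# ---------------------------------------------------------------------------
# Hypervolume
# ---------------------------------------------------------------------------

def test_hypervolume_2d_manual():
    assert hypervolume([[1.0, 1.0]], [2.0, 2.0]) == pytest.approx(1.0)
    assert hypervolume([[0, 2], [1, 1]], [2, 3]) == pytest.approx(3.0)
    # dominated point contributes nothing
    assert hypervolume([[0, 2], [1, 1], [1.5, 2.5]], [2, 3]) == pytest.approx(3.0)


def test_hypervolume_3d_manual():
    assert hypervolume([[0, 0, 0]], [1, 1, 1]) == pytest.approx(1.0)
    # union of two unit-height boxes overlapping in a 1x1 column
    assert hypervolume([[0, 1, 0], [1, 0, 0]], [2, 2, 1]) == pytest.approx(3.0)


def test_hypervolume_beyond_reference_is_zero():
    assert hypervolume([[3.0, 3.0]], [2.0, 2.0]) == 0.0


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _const_evaluator(q, scale=1.0):
    return ov(float(q[0]), float(q[1]) if len(q) > 1 else 1.0, 0.5)


def test_brute_force_single_and_dominating_pair():
    front = brute_force_pareto(np.array([[1.0, 1.0]]), _const_evaluator)
    assert len(front.members) == 1
    front = brute_force_pareto(np.array([[1.0, 1.0], [2.0, 2.0]]),
                               _const_evaluator)
    assert len(front.members) == 1
    assert front.members[0].objectives.cost == 1.0


def test_brute_force_shuffle_invariant(rng):
    grid = rng.uniform(0, 1, size=(1000, 2))
    f1 = brute_force_pareto(grid, _const_evaluator)
    f2 = brute_force_pareto(grid[rng.permutation(1000)], _const_evaluator)
    s1 = sorted(penalized_triple(m.objectives) for m in f1.members)
    s2 = sorted(penalized_triple(m.objectives) for m in f2.members)
    assert s1 == s2


def test_brute_force_rejects_huge_grid():
    with pytest.raises(ValueError, match="exceeds"):
        brute_force_pareto(np.zeros((10, 2)), _const_evaluator, max_points=5)


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

def _box_constraints(hi=100.0):
    return ConstraintSet(bounds={"beef": (0.0, hi), "poultry": (0.0, hi)},
                         energy_band=None, total_protein_cap=None,
                         total_protein_target=None, rda_active={})


def toy_evaluator(q, scale):
    """Two-commodity diet toy: dirty expensive beef vs clean cheap poultry,
    with a B12 requirement both can meet (beef 2.5, poultry 2.0 ug/100 g,
    RDA 2.4 ug).  Penalty scale frozen so the oracle sees the same landscape.
    """
    cost = (3.0 * q[0] + 2.0 * q[1]) / 1000.0
    emis = (100.0 * q[0] + 4.0 * q[1]) / 1000.0
    supply = (2.5 * q[0] + 2.0 * q[1]) / 100.0
    d = max(0.0, 2.4 - supply)
    pen = 10.0 * (d / 2.4) ** 2
    return ov(cost, emis, min(supply / 2.4, 1.0), pen=pen)


def test_evolve_rejects_infeasible_bounds():
    cons = ConstraintSet(bounds={"x": (5.0, 1.0)}, energy_band=None,
                         total_protein_cap=None, total_protein_target=None,
                         rda_active={})
    with pytest.raises(ValueError, match="lo > hi"):
        evolve(None, NSGAConfig(population_size=4, generations=1, seed=0),
               _const_evaluator, cons)


def test_evolve_single_objective_converges_to_corner():
    """With only cost varying, the front collapses to the box corner."""
    def evaluator(q, scale):
        return ov(float(q[0]) / 100.0, 1.0, 0.5)

    cons = _box_constraints()
    front = evolve(None, NSGAConfig(population_size=24, generations=30, seed=3),
                   evaluator, cons)
    best = min(m.objectives.cost for m in front.members)
    assert best < 0.01  # q0 within 1 g of the analytic optimum 0


def test_evolve_deterministic_under_fixed_seed():
    cons = _box_constraints()
    cfg = NSGAConfig(population_size=20, generations=15, seed=42)
    f1 = evolve(None, cfg, toy_evaluator, cons)
    f2 = evolve(None, cfg, toy_evaluator, cons)
    a1 = sorted(map(tuple, f1.objective_array()))
    a2 = sorted(map(tuple, f2.objective_array()))
    assert a1 == a2


def test_evolve_elitism_and_hypervolume_monotone():
    cons = _box_constraints()
    front = evolve(None, NSGAConfig(population_size=30, generations=25, seed=9),
                   toy_evaluator, cons)
    best_cost = [h["best"]["cost"] for h in front.history]
    best_emis = [h["best"]["emissions"] for h in front.history]
    best_nut = [h["best"]["nutrition"] for h in front.history]
    assert all(b <= a + 1e-12 for a, b in zip(best_cost, best_cost[1:]))
    assert all(b <= a + 1e-12 for a, b in zip(best_emis, best_emis[1:]))
    assert all(b >= a - 1e-12 for a, b in zip(best_nut, best_nut[1:]))
    ref = front.objective_array().max(axis=0) + 1.0
    hvs = [hypervolume(h["archive_objectives"], ref) for h in front.history
           if h["archive_objectives"] is not None]
    assert all(b >= a - 1e-12 for a, b in zip(hvs, hvs[1:]))


def test_evolve_matches_grid_oracle():
    """On the 2-commodity toy, the evolved front attains >= 95% of the
    exhaustive 1 g-grid front's hypervolume and every member lies within
    grid resolution of an oracle point in decision space."""
    cons = _box_constraints()
    xs = np.arange(0.0, 101.0, 1.0)
    grid = np.array([[a, b] for a in xs for b in xs])
    oracle = brute_force_pareto(grid, lambda q, s: toy_evaluator(q, s))
    front = evolve(None, NSGAConfig(population_size=80, generations=60, seed=7),
                   toy_evaluator, cons)

    F_oracle = oracle.objective_array()
    F_nsga = front.objective_array()
    ref = F_oracle.max(axis=0) + 0.1 * np.abs(F_oracle.max(axis=0)) + 0.1
    hv_oracle = hypervolume(F_oracle, ref)
    hv_nsga = hypervolume(F_nsga, ref)
    assert hv_nsga >= 0.95 * hv_oracle

    oracle_q = np.array([[m.Q.asf["x0"], m.Q.asf["x1"]]
                         for m in oracle.members])
    nsga_q = np.array([[m.Q.asf["beef"], m.Q.asf["poultry"]]
                       for m in front.members])
    for q in nsga_q:
        dists = np.max(np.abs(oracle_q - q), axis=1)
        assert dists.min() <= 2.0  # within grid resolution (1 g) x safety 2


def test_penalty_pressure_forces_required_commodity():
    """A nutrient only one (costless, clean) commodity supplies: every front
    member carries it at a deficit-free level."""
    rda = 2.4

    def evaluator(q, scale):
        cost = 2.0 * q[0] / 1000.0          # q1 (supplement) is free
        emis = 4.0 * q[0] / 1000.0
        supply = 100.0 * q[1] / 100.0        # only the supplement has B12
        d = max(0.0, rda - supply)
        pen = scale * (d / rda) ** 2
        return ov(cost, emis, min(supply / rda, 1.0), pen=pen)

    cons = ConstraintSet(bounds={"filler": (0.0, 100.0), "supp": (0.0, 100.0)},
                         energy_band=None, total_protein_cap=None,
                         total_protein_target=None, rda_active={})
    front = evolve(None, NSGAConfig(population_size=30, generations=40, seed=1),
                   evaluator, cons)
    for m in front.members:
        supply = m.Q.asf["supp"]
        assert supply >= rda - 1e-6
        assert m.objectives.penalty == 0.0
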