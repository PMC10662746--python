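"""Small parsimony solvers: relaxations, exact ILP, repair, decompositions."""

import numpy as np
import pytest

from zcnt.parsimony import (
    AncestralLabeling,
    brute_force_small_parsimony,
    canonical_event_decomposition,
    cnt_violation_stats,
    exact_small_parsimony_ilp,
    lp_relaxation_small_parsimony,
    parsimony_score,
    repair_balancing,
    two_approx_small_parsimony,
    unbalanced_small_parsimony,
    vertex_discrepancy,
    _leaf_deltas,
)
from zcnt.distance import zcnt_distance
from zcnt.profiles import ChromLayout, CopyNumberMatrix, default_bins, delta_transform
from zcnt.simulate import SimulationConfig, simulate
from zcnt.tree import Phylogeny

SOLVERS = [
    unbalanced_small_parsimony,
    lp_relaxation_small_parsimony,
    exact_small_parsimony_ilp,
    two_approx_small_parsimony,
]


def _sankoff_unbalanced(tree, M):
    """Independent per-coordinate Sankoff DP over the integer leaf range."""
    deltas = _leaf_deltas(tree, M, 2)
    btree = tree.resolve_polytomies()
    L = M.layout.delta_length
    total = 0.0
    for j in range(L):
        vals = [int(d[j]) for d in deltas.values()]
        states = list(range(min(vals), max(vals) + 1))
        cost = {}
        for v in btree.postorder():
            kids = btree.children(v)
            if not kids:
                x = int(deltas[v][j])
                cost[v] = {s: abs(s - x) for s in states}
            else:
                cost[v] = {
                    s: sum(
                        min(abs(s - t) + cost[c][t] for t in states) for c in kids
                    )
                    for s in states
                }
        total += min(cost[btree.root].values())
    return total


@pytest.mark.parametrize("solver", SOLVERS)
def test_identical_leaves_cost_zero(matrix_factory, solver):
    M = matrix_factory([[2, 3, 1, 2]] * 4)
    tree = Phylogeny.from_newick("((cell_0,cell_1),(cell_2,cell_3));")
    res = solver(tree, M)
    assert res.score_l1 == 0
    shared = delta_transform(M.values[0], M.layout)
    for v, lab in res.labeling.to_delta().labels.items():
        assert np.allclose(lab, shared)


@pytest.mark.parametrize(
    "solver, expected_l1",
    [
        (unbalanced_small_parsimony, 2),
        (lp_relaxation_small_parsimony, 2),
        (exact_small_parsimony_ilp, 2),
        (two_approx_small_parsimony, 2),
    ],
)
def test_two_leaf_tree_equals_pairwise_distance(matrix_factory, solver, expected_l1):
    M = matrix_factory([[2, 2, 2, 2], [2, 3, 3, 2]], cells=["a", "b"])
    tree = Phylogeny.from_newick("(a,b);")
    res = solver(tree, M)
    assert res.score_l1 == pytest.approx(expected_l1)
    assert res.score_events == pytest.approx(expected_l1 / 2)


def test_cherry_median_is_an_endpoint(matrix_factory):
    """With two leaves the optimal balanced ancestor is an input profile."""
    M = matrix_factory([[2, 2], [4, 2]], cells=["a", "b"])
    tree = Phylogeny.from_newick("(a,b);")
    res = exact_small_parsimony_ilp(tree, M)
    assert res.score_events == 2
    assert res.score_l1 == 2 * zcnt_distance(M.profile("a"), M.profile("b"))


def test_unbalanced_matches_independent_sankoff(rng):
    layout = ChromLayout(["chr1"], [3])
    bins = default_bins(layout)
    for trial in range(8):
        vals = rng.integers(0, 3, size=(4, 3))
        M = CopyNumberMatrix([f"cell_{i}" for i in range(4)], vals, bins)
        tree = Phylogeny.from_newick(
            ["((cell_0,cell_1),(cell_2,cell_3));", "(((cell_0,cell_1),cell_2),cell_3);"][trial % 2]
        )
        assert unbalanced_small_parsimony(tree, M).score_l1 == _sankoff_unbalanced(tree, M)


def test_ilp_matches_exhaustive_enumeration(rng):
    layout = ChromLayout(["chr1"], [3])
    bins = default_bins(layout)
    newicks = {
        2: "(cell_0,cell_1);",
        3: "((cell_0,cell_1),cell_2);",
        4: "((cell_0,cell_1),(cell_2,cell_3));",
    }
    for trial in range(9):
        n = [2, 3, 4][trial % 3]
        vals = rng.integers(0, 3, size=(n, 3))
        M = CopyNumberMatrix([f"cell_{i}" for i in range(n)], vals, bins)
        tree = Phylogeny.from_newick(newicks[n])
        ilp = exact_small_parsimony_ilp(tree, M).score_l1
        assert ilp == brute_force_small_parsimony(tree, M, box=4)


def test_two_leaf_ilp_exhaustive_over_all_profiles():
    """For every ordered pair of m=3, entries<=2 leaves, the exact balanced
    optimum equals the closed-form pairwise L1 delta distance."""
    from zcnt.simulate import enumerate_profiles

    layout = ChromLayout(["chr1"], [3])
    profiles = enumerate_profiles(3, 2)
    deltas = delta_transform(profiles, layout)
    tree = Phylogeny.from_newick("(a,b);")
    bins = default_bins(layout)
    rng = np.random.default_rng(1)
    idx = rng.integers(len(profiles), size=(40, 2))
    for i, j in idx:
        M = CopyNumberMatrix(["a", "b"], profiles[[i, j]], bins)
        expected = np.abs(deltas[i] - deltas[j]).sum()
        assert exact_small_parsimony_ilp(tree, M).score_l1 == expected


def test_relaxation_sandwich_on_simulated_instances():
    for seed in range(5):
        sim = simulate(SimulationConfig(n_cells=6, n_bins=12,
                                        events_per_edge_mean=2.0, seed=seed))
        tree, M = sim.tree, sim.matrix
        unb = unbalanced_small_parsimony(tree, M).score_l1
        lp = lp_relaxation_small_parsimony(tree, M).score_l1
        ilp = exact_small_parsimony_ilp(tree, M).score_l1
        rep = two_approx_small_parsimony(tree, M).score_l1
        assert unb <= lp + 1e-6 <= ilp + 2e-6 <= rep + 3e-6
        assert rep <= 2 * unb + 1e-9


def test_discrepancy_and_repair(chr1_layout):
    layeled = AncestralLabeling(
        {"u": np.array([1, 0, 0, 0, 0]), "leaf": np.array([0, 1, 0, -1, 0])},
        chr1_layout,
        "delta",
    )
    disc = vertex_discrepancy(layeled)
    assert disc["u"]["chr1"] == 1
    assert disc["leaf"]["chr1"] == 0
    tree = Phylogeny.from_edges([("u", "leaf")], "u")
    fixed = repair_balancing(tree, layeled)
    assert fixed.labels["u"].tolist() == [1, 0, 0, 0, -1]
    assert fixed.labels["leaf"].tolist() == [0, 1, 0, -1, 0]
    assert fixed.is_balanced()
    # an already balanced labeling is unchanged
    again = repair_balancing(tree, fixed)
    assert all(np.array_equal(again.labels[v], fixed.labels[v]) for v in fixed.labels)


def test_repair_cost_bound_on_random_instances():
    """Repaired cost <= input cost + sum of per-edge discrepancy jumps."""
    for seed in range(5):
        sim = simulate(SimulationConfig(n_cells=8, n_bins=15,
                                        events_per_edge_mean=2.5, seed=seed + 50))
        tree, M = sim.tree, sim.matrix
        unb = unbalanced_small_parsimony(tree, M)
        disc = {
            v: sum(per.values())
            for v, per in vertex_discrepancy(unb.labeling).items()
        }
        edge_jumps = sum(abs(disc[u] - disc[v]) for u, v in tree.edges())
        repaired = repair_balancing(tree, unb.labeling)
        rep_score = parsimony_score(tree, repaired).score_l1
        assert rep_score <= unb.score_l1 + edge_jumps + 1e-9


def test_lower_bound_by_total_discrepancy():
    """Any leaf-consistent labeling costs at least its total |discrepancy|."""
    for seed in range(5):
        sim = simulate(SimulationConfig(n_cells=6, n_bins=10,
                                        events_per_edge_mean=2.0, seed=seed + 100))
        res = unbalanced_small_parsimony(sim.tree, sim.matrix)
        score = parsimony_score(sim.tree, res.labeling)
        assert score.score_l1 >= score.lower_bound_discrepancy - 1e-9


def test_polytomy_resolution_never_increases_score(matrix_factory, rng):
    """Refining a polytomy adds free internal vertices, so any resolution
    scores no worse than the multifurcating tree itself."""
    vals = rng.integers(0, 4, size=(5, 6))
    M = matrix_factory(vals)
    star = Phylogeny.from_edges([("r", f"cell_{i}") for i in range(5)], "r")
    star_score = unbalanced_small_parsimony(star, M).score_l1
    base_order = [f"cell_{i}" for i in range(5)]
    for k in range(4):
        order = list(np.roll(base_order, k))
        resolved = star.resolve_polytomies(order=order)
        assert unbalanced_small_parsimony(resolved, M).score_l1 <= star_score


def test_canonical_decomposition_examples(chr1_layout):
    layout = chr1_layout
    assert canonical_event_decomposition(
        np.array([2, 2, 2, 2]), np.array([2, 2, 2, 2]), layout
    ) == []
    evs = canonical_event_decomposition(
        np.array([2, 2, 2, 2]), np.array([2, 3, 3, 2]), layout
    )
    assert [(e.start, e.end, e.sign) for e in evs] == [(1, 2, +1)]
    layout2 = ChromLayout(["chr1"], [2])
    evs = canonical_event_decomposition(np.array([2, 2]), np.array([1, 3]), layout2)
    assert len(evs) == 2
    assert sorted((e.start, e.end, e.sign) for e in evs) == [(0, 0, -1), (1, 1, +1)]
    # amplifications are scheduled first
    signs = [e.sign for e in evs]
    assert signs == sorted(signs, reverse=True)


def test_decomposition_length_and_replay(rng):
    """Event count equals the distance and replaying yields the child."""
    from zcnt.profiles import apply_zcnt_event, CopyNumberProfile

    layout = ChromLayout(["chr1", "chr2"], [5, 4])
    bins = default_bins(layout)
    for _ in range(60):
        parent = rng.integers(0, 5, size=9)
        child = rng.integers(0, 5, size=9)
        evs = canonical_event_decomposition(parent, child, layout)
        p = CopyNumberProfile(parent, bins)
        c = CopyNumberProfile(child, bins)
        assert len(evs) == zcnt_distance(p, c)
        cur = p
        for ev in evs:
            cur = apply_zcnt_event(cur, ev)
        assert np.array_equal(cur.values, child)


def test_violation_statistics():
    layout3 = ChromLayout(["chr1"], [3])
    tree = Phylogeny.from_edges([("anc", "a"), ("anc", "b")], "anc")
    lab = AncestralLabeling(
        {"anc": np.array([1, -1, 2]), "a": np.array([1, 0, 2]), "b": np.array([1, 0, 2])},
        layout3,
        "copy_number",
    )
    stats = cnt_violation_stats(tree, lab)
    assert stats.negative_stretches == 1
    assert stats.min_entry == -1
    # amplification over a zero locus is counted
    tree2 = Phylogeny.from_edges([("p", "c"), ("p", "d")], "p")
    lab2 = AncestralLabeling(
        {"p": np.array([2, 0, 2]), "c": np.array([2, 1, 2]), "d": np.array([2, 0, 2])},
        layout3,
        "copy_number",
    )
    stats2 = cnt_violation_stats(tree2, lab2)
    assert stats2.zero_amplifications == 1
    assert stats2.violating_events == 1
    # a fully CNT-consistent labeling reports all zeros
    lab3 = AncestralLabeling(
        {"p": np.array([2, 2, 2]), "c": np.array([2, 3, 2]), "d": np.array([2, 2, 2])},
        layout3,
        "copy_number",
    )
    stats3 = cnt_violation_stats(tree2, lab3)
    assert stats3.negative_stretches == 0
    assert stats3.zero_amplifications == 0
    assert stats3.violating_score_fraction == 0.0


def test_score_convention():
    sim = simulate(SimulationConfig(n_cells=5, n_bins=8, events_per_edge_mean=1.5, seed=9))
    res = exact_small_parsimony_ilp(sim.tree, sim.matrix)
    assert res.score_l1 == 2 * res.score_events
    recomputed = parsimony_score(sim.tree, res.labeling)
    assert recomputed.score_l1 == res.score_l1


def test_true_labeling_upper_bound():
    """Under ZCNT evolution each event moves the delta L1 by at most two, so
    the true labeling's score (in events) is at most the simulated count."""
    sim = simulate(SimulationConfig(n_cells=6, n_bins=10, events_per_edge_mean=2.0,
                                    semantics="ZCNT", seed=3))
    lab = AncestralLabeling(dict(sim.profiles), sim.matrix.layout, "copy_number")
    score = parsimony_score(sim.tree, lab)
    assert score.score_events <= len(sim.event_log)
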