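"""Solvers for the ZCNT small parsimony problem.

Given a rooted tree whose leaves carry copy number profiles (equivalently,
their delta profiles), the problem is to label every internal vertex with a
balanced integer vector minimizing the total L1 distance over edges; half
that sum is the minimum number of ZCNT events explaining the tree.

Four routes are provided:

* :func:`unbalanced_small_parsimony` -- drop the balancing condition.  The
  coordinates decouple and each is an L1 (Wagner-style) small parsimony
  problem solved exactly by bottom-up interval propagation in O(n m) time.
* :func:`lp_relaxation_small_parsimony` -- drop integrality instead and
  solve the resulting linear program (HiGHS).
* :func:`exact_small_parsimony_ilp` -- the exact integer program.
* :func:`two_approx_small_parsimony` -- unbalanced solution followed by
  :func:`repair_balancing`, a linear-time fix that restores balancing at
  every vertex while at most doubling the cost; since the unbalanced
  optimum lower-bounds the true optimum, this is a 2-approximation.

Scores are reported both as the raw L1 sum and in event units (half of it).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .profiles import (
    ChromLayout,
    CopyNumberMatrix,
    DIPLOID_BASELINE,
    EventRecord,
    delta_transform,
    inverse_delta_transform,
)
from .tree import Phylogeny

#: Name of the pseudo-leaf used to pin the root to the diploid profile.
DIPLOID_LEAF = "diploid"


@dataclass
class AncestralLabeling:
    """Vertex -> integer vector labels, in delta or copy-number space."""

    labels: dict
    layout: ChromLayout
    space: str = "delta"  # "delta" or "copy_number"
    baseline: int = DIPLOID_BASELINE

    def __post_init__(self) -> None:
        if self.space not in ("delta", "copy_number"):
            raise ValueError("space must be 'delta' or 'copy_number'")
        self.labels = {v: np.asarray(x) for v, x in self.labels.items()}

    def to_copy_number(self) -> "AncestralLabeling":
        if self.space == "copy_number":
            return self
        labels = {
            v: inverse_delta_transform(x, self.layout, self.baseline)
            for v, x in self.labels.items()
        }
        return AncestralLabeling(labels, self.layout, "copy_number", self.baseline)

    def to_delta(self) -> "AncestralLabeling":
        if self.space == "delta":
            return self
        labels = {
            v: delta_transform(x, self.layout, self.baseline)
            for v, x in self.labels.items()
        }
        return AncestralLabeling(labels, self.layout, "delta", self.baseline)

    def is_balanced(self, tol: float = 1e-9) -> bool:
        lab = self.to_delta()
        return all(
            abs(float(x[lab.layout.delta_slice(c)].sum())) <= tol
            for x in lab.labels.values()
            for c in lab.layout.chroms
        )


@dataclass
class ParsimonyResult:
    """Score and ancestral labeling of one small parsimony solve."""

    score_l1: float
    labeling: AncestralLabeling
    method: str
    optimal: bool = True
    lower_bound_discrepancy: float = 0.0
    extras: dict = field(default_factory=dict)

    @property
    def score_events(self) -> float:
        return self.score_l1 / 2.0


def _leaf_deltas(tree: Phylogeny, M: CopyNumberMatrix, baseline: int) -> dict:
    """Delta vector for every constrained vertex.

    A vertex is constrained when it carries a cell's profile or is the
    diploid pseudo-leaf (which may sit at the root after re-rooting, hence
    the check is by name, not by degree).  Every degree-zero vertex must be
    constrained.
    """
    deltas = M.delta_matrix(baseline)
    index = {c: i for i, c in enumerate(M.cells)}
    out = {}
    for v in tree.graph:
        if v in index:
            out[v] = deltas[index[v]]
        elif v == DIPLOID_LEAF:
            out[v] = np.zeros(M.layout.delta_length, dtype=np.int64)
        elif tree.graph.out_degree(v) == 0:
            raise ValueError(f"leaf {v!r} has no row in the copy number matrix")
    return out


# ---------------------------------------------------------------------------
# Unbalanced relaxation: per-coordinate interval propagation
# ---------------------------------------------------------------------------

def _interval_pass(tree: Phylogeny, leaf_vals: Mapping) -> tuple[float, dict, dict, Phylogeny]:
    """Bottom-up interval (Wagner) pass on a binary resolution of ``tree``.

    Returns (total cost, lo, hi, binary tree); lo/hi map each vertex of the
    binary tree to the per-coordinate interval of minimizers of its subtree.
    """
    needs_resolution = any(tree.graph.out_degree(v) > 2 for v in tree.graph)
    btree = tree.resolve_polytomies() if needs_resolution else tree
    lo: dict = {}
    hi: dict = {}
    cost = 0.0
    for v in btree.postorder():
        kids = btree.children(v)
        if not kids:
            val = np.asarray(leaf_vals[v], dtype=np.int64)
            lo[v] = val
            hi[v] = val
        elif len(kids) == 1:
            lo[v], hi[v] = lo[kids[0]], hi[kids[0]]
        else:
            a, b = kids
            upper = np.maximum(lo[a], lo[b])
            lower = np.minimum(hi[a], hi[b])
            cost += float(np.maximum(upper - lower, 0).sum())
            lo[v] = np.minimum(upper, lower)
            hi[v] = np.maximum(upper, lower)
    return cost, lo, hi, btree


_BIG = 1e12


def _distance_transform(C: np.ndarray) -> np.ndarray:
    """min-plus convolution with |.|: D[s] = min_y C[y] + |s - y| (per column)."""
    D = C.copy()
    for s in range(1, D.shape[0]):
        np.minimum(D[s], D[s - 1] + 1.0, out=D[s])
    for s in range(D.shape[0] - 2, -1, -1):
        np.minimum(D[s], D[s + 1] + 1.0, out=D[s])
    return D


def unbalanced_small_parsimony(
    tree: Phylogeny, M: CopyNumberMatrix, baseline: int = DIPLOID_BASELINE
) -> ParsimonyResult:
    """Exact optimum of ZCNT small parsimony with the balancing condition dropped.

    With balancing gone the delta coordinates decouple, and each coordinate
    is an L1 small parsimony problem whose optimum uses only integer labels
    inside the leaf range.  A bottom-up pass computes, per vertex, the cost
    of its subtree as a function of the vertex's label over that integer
    range (children are absorbed by a min-plus distance transform, so
    arbitrary vertex degrees are exact); a top-down pass then picks labels,
    breaking ties toward the diploid delta (zero) at the root and toward the
    parent's value below, which keeps ancestral states as close to normal as
    optimality allows.
    """
    leaf_vals = _leaf_deltas(tree, M, baseline)
    layout = M.layout
    L = layout.delta_length
    fixed = {v: np.asarray(x, dtype=np.int64) for v, x in leaf_vals.items()}
    all_fixed = np.vstack(list(fixed.values()))
    lo, hi = int(all_fixed.min()), int(all_fixed.max())
    states = np.arange(lo, hi + 1)
    S = len(states)
    cost: dict = {}
    for v in tree.postorder():
        C = np.zeros((S, L))
        for c in tree.children(v):
            C += _distance_transform(cost[c])
        if v in fixed:
            C += np.where(states[:, None] == fixed[v][None, :], 0.0, _BIG)
        cost[v] = C
    root_cost = cost[tree.root]
    total = float(root_cost.min(axis=0).sum())
    # top-down label choice; epsilon terms steer ties without moving optima
    assign: dict = {}
    eps = 1.0 / (4.0 * S)
    root_pick = np.argmin(root_cost + eps * np.abs(states)[:, None], axis=0)
    assign[tree.root] = states[root_pick]
    for v in tree.preorder():
        if v == tree.root:
            continue
        parent_val = assign[tree.parent(v)]
        gap = np.abs(states[:, None] - parent_val[None, :])
        pick = np.argmin(cost[v] + gap * (1.0 + eps), axis=0)
        assign[v] = states[pick]
    labels = {
        v: fixed[v] if v in fixed else assign[v].astype(np.int64) for v in tree.graph
    }
    labeling = AncestralLabeling(labels, M.layout, "delta", baseline)
    check = parsimony_score(tree, labeling)
    assert abs(check.score_l1 - total) <= 1e-6, (check.score_l1, total)
    return ParsimonyResult(
        total,
        labeling,
        "unbalanced",
        lower_bound_discrepancy=check.lower_bound_discrepancy,
    )


def unbalanced_score(tree: Phylogeny, leaf_deltas: Mapping) -> float:
    """Cost-only fast path of the unbalanced relaxation (used by tree search)."""
    cost, _, _, _ = _interval_pass(tree, leaf_deltas)
    return cost


# ---------------------------------------------------------------------------
# LP / ILP
# ---------------------------------------------------------------------------

def _build_parsimony_program(tree, M, baseline, box_slack):
    """Shared LP/ILP assembly; returns solver inputs and index maps."""
    leaf_vals = _leaf_deltas(tree, M, baseline)
    layout = M.layout
    L = layout.delta_length
    internals = [v for v in tree.graph if tree.graph.out_degree(v) > 0]
    v_index = {v: i for i, v in enumerate(internals)}
    edges = tree.edges()
    n_x = len(internals) * L
    n_t = len(edges) * L
    leaf_mat = np.vstack(list(leaf_vals.values())) if leaf_vals else np.zeros((1, L))
    lo_box = leaf_mat.min(axis=0) - box_slack
    hi_box = leaf_mat.max(axis=0) + box_slack

    rows_a, cols_a, data_a, lb, ub = [], [], [], [], []
    row = 0

    def x_col(v, j):
        return v_index[v] * L + j

    def t_col(e, j):
        return n_x + e * L + j

    # |x_u - x_v| <= t_e, coordinate-wise, with leaves substituted as constants.
    for e, (u, v) in enumerate(edges):
        u_int, v_int = u in v_index, v in v_index
        for j in range(L):
            for sign in (+1, -1):
                rhs = 0.0
                if u_int:
                    rows_a.append(row); cols_a.append(x_col(u, j)); data_a.append(sign)
                else:
                    rhs -= sign * leaf_vals[u][j]
                if v_int:
                    rows_a.append(row); cols_a.append(x_col(v, j)); data_a.append(-sign)
                else:
                    rhs += sign * leaf_vals[v][j]
                rows_a.append(row); cols_a.append(t_col(e, j)); data_a.append(-1.0)
                lb.append(-np.inf)
                ub.append(rhs)
                row += 1
    # Balancing: per internal vertex, per chromosome, sum of the segment = 0.
    for v in internals:
        for c in layout.chroms:
            sl = layout.delta_slice(c)
            for j in range(sl.start, sl.stop):
                rows_a.append(row); cols_a.append(x_col(v, j)); data_a.append(1.0)
            lb.append(0.0)
            ub.append(0.0)
            row += 1

    A = sparse.csr_matrix((data_a, (rows_a, cols_a)), shape=(row, n_x + n_t))
    cost = np.concatenate([np.zeros(n_x), np.ones(n_t)])
    bounds_lo = np.concatenate([np.tile(lo_box, len(internals)), np.zeros(n_t)])
    bounds_hi = np.concatenate([np.tile(hi_box, len(internals)), np.full(n_t, np.inf)])
    return A, np.array(lb), np.array(ub), cost, bounds_lo, bounds_hi, internals, L, n_x


def _solve_parsimony_program(tree, M, baseline, *, integer: bool) -> ParsimonyResult:
    unb = unbalanced_small_parsimony(tree, M, baseline)
    disc = _per_vertex_abs_discrepancy(unb.labeling)
    slack = max(2.0, max(disc.values(), default=0.0))
    for _ in range(6):
        (A, lb, ub, cost, blo, bhi, internals, L, n_x) = _build_parsimony_program(
            tree, M, baseline, slack
        )
        integrality = np.zeros(len(cost))
        if integer:
            integrality[:n_x] = 1
        res = milp(
            c=cost,
            constraints=LinearConstraint(A, lb, ub),
            bounds=Bounds(blo, bhi),
            integrality=integrality,
        )
        if res.status != 0 or res.x is None:
            raise RuntimeError(f"LP/ILP solver failed: status={res.status} {res.message}")
        x = res.x[:n_x].reshape(len(internals), L)
        at_bound = np.any(x <= blo[:n_x].reshape(x.shape) + 1e-6) or np.any(
            x >= bhi[:n_x].reshape(x.shape) - 1e-6
        )
        if not at_bound:
            break
        slack *= 2  # widen the labeling box and re-solve
    labels = {}
    leaf_vals = _leaf_deltas(tree, M, baseline)
    for v in tree.graph:
        if v in leaf_vals and tree.graph.out_degree(v) == 0:
            labels[v] = np.asarray(leaf_vals[v], dtype=np.int64)
        else:
            xi = x[internals.index(v)]
            labels[v] = np.round(xi).astype(np.int64) if integer else xi
    labeling = AncestralLabeling(labels, M.layout, "delta", baseline)
    if integer:
        score = float(np.round(res.fun))
        return ParsimonyResult(score, labeling, "ilp", optimal=res.status == 0)
    return ParsimonyResult(float(res.fun), labeling, "lp", extras={"fractional": True})


def lp_relaxation_small_parsimony(
    tree: Phylogeny, M: CopyNumberMatrix, baseline: int = DIPLOID_BASELINE
) -> ParsimonyResult:
    """Balanced small parsimony with integrality dropped (linear program).

    The reported score is the fractional LP optimum; the attached labeling
    keeps the fractional vertex labels.
    """
    return _solve_parsimony_program(tree, M, baseline, integer=False)


def exact_small_parsimony_ilp(
    tree: Phylogeny, M: CopyNumberMatrix, baseline: int = DIPLOID_BASELINE
) -> ParsimonyResult:
    """Exact balanced, integer small parsimony via mixed-integer programming."""
    return _solve_parsimony_program(tree, M, baseline, integer=True)


# ---------------------------------------------------------------------------
# Discrepancy, repair, 2-approximation
# ---------------------------------------------------------------------------

def vertex_discrepancy(labeling: AncestralLabeling) -> dict:
    """Per-vertex, per-chromosome sums of delta entries (0 iff balanced)."""
    lab = labeling.to_delta()
    return {
        v: {c: float(x[lab.layout.delta_slice(c)].sum()) for c in lab.layout.chroms}
        for v, x in lab.labels.items()
    }


def _per_vertex_abs_discrepancy(labeling: AncestralLabeling) -> dict:
    return {
        v: sum(abs(d) for d in per_chrom.values())
        for v, per_chrom in vertex_discrepancy(labeling).items()
    }


def repair_balancing(tree: Phylogeny, labeling: AncestralLabeling) -> AncestralLabeling:
    """Restore the balancing condition by absorbing each vertex's discrepancy
    into the right-boundary (telomeric) delta coordinate of each chromosome.

    Leaves, whose labels are delta maps of observed profiles, are already
    balanced and unchanged.  Per edge (u, v) only that one coordinate moves,
    so the cost increase is at most |disc(u) - disc(v)| <= ||l(u) - l(v)||_1
    per chromosome, hence the repaired cost is at most twice the input cost.
    """
    lab = labeling.to_delta()
    disc = vertex_discrepancy(lab)
    labels = {}
    for v, x in lab.labels.items():
        x = np.asarray(x)
        integral = x.dtype.kind in "iu"
        y = x.copy() if integral else x.astype(float).copy()
        for c in lab.layout.chroms:
            sl = lab.layout.delta_slice(c)
            d = disc[v][c]
            if d != 0:
                y[sl.stop - 1] -= int(round(d)) if integral else d
        labels[v] = y
    return AncestralLabeling(labels, lab.layout, "delta", lab.baseline)


def two_approx_small_parsimony(
    tree: Phylogeny, M: CopyNumberMatrix, baseline: int = DIPLOID_BASELINE
) -> ParsimonyResult:
    """Balanced labeling within a factor 2 of optimal, in O(n m) time."""
    unb = unbalanced_small_parsimony(tree, M, baseline)
    repaired = repair_balancing(tree, unb.labeling)
    result = parsimony_score(tree, repaired)
    return ParsimonyResult(
        result.score_l1,
        repaired,
        "two-approx",
        extras={"unbalanced_score_l1": unb.score_l1},
    )


def parsimony_score(tree: Phylogeny, labeling: AncestralLabeling) -> ParsimonyResult:
    """Total per-edge L1 distance of a labeling, plus the discrepancy bound.

    Any labeling agreeing with the leaves has cost at least the total
    absolute vertex discrepancy, which is reported alongside the score.
    """
    lab = labeling.to_delta()
    missing = [v for v in tree.graph if v not in lab.labels]
    if missing:
        raise ValueError(f"labeling missing vertices: {missing[:3]}")
    score = 0.0
    for u, v in tree.edges():
        score += float(np.abs(np.asarray(lab.labels[u], dtype=float) - np.asarray(lab.labels[v], dtype=float)).sum())
    lower = sum(_per_vertex_abs_discrepancy(lab).values())
    return ParsimonyResult(score, labeling, "score", lower_bound_discrepancy=lower)


# ---------------------------------------------------------------------------
# Canonical event decomposition and CNT-violation statistics
# ---------------------------------------------------------------------------

def canonical_event_decomposition(
    parent: np.ndarray,
    child: np.ndarray,
    layout: ChromLayout,
    baseline: int = DIPLOID_BASELINE,
) -> list[EventRecord]:
    """A minimum-length ZCNT event sequence transforming parent into child.

    Per chromosome, the delta difference w is expanded into unit charges;
    positive and negative charges are paired left to right, each pair
    becoming one interval event between its two boundaries.  The number of
    events equals the ZCNT distance, and amplifications are scheduled before
    deletions so that no intermediate profile dips below the endpoints'
    range unnecessarily.
    """
    parent = np.asarray(parent, dtype=np.int64)
    child = np.asarray(child, dtype=np.int64)
    if parent.shape != child.shape:
        raise ValueError("parent and child must share bins")
    dp = delta_transform(parent, layout, baseline)
    dc = delta_transform(child, layout, baseline)
    amps: list[EventRecord] = []
    dels: list[EventRecord] = []
    for c in layout.chroms:
        w = (dc - dp)[layout.delta_slice(c)]
        pos = np.repeat(np.nonzero(w > 0)[0], w[w > 0])
        neg = np.repeat(np.nonzero(w < 0)[0], -w[w < 0])
        for i, j in zip(pos, neg):
            if i < j:
                amps.append(EventRecord(c, int(i), int(j) - 1, +1))
            else:
                dels.append(EventRecord(c, int(j), int(i) - 1, -1))
    return amps + dels


@dataclass
class ViolationStats:
    """How far an ancestral labeling strays from the zero-skipping CNT model."""

    n_edges: int
    negative_stretches: int
    min_entry: int
    zero_amplifications: int
    violating_events: int
    total_events: float

    @property
    def negative_stretches_per_edge(self) -> float:
        return self.negative_stretches / self.n_edges

    @property
    def zero_amplifications_per_edge(self) -> float:
        return self.zero_amplifications / self.n_edges

    @property
    def violating_score_fraction(self) -> float:
        return 0.0 if self.total_events == 0 else self.violating_events / self.total_events


def cnt_violation_stats(
    tree: Phylogeny,
    labeling: AncestralLabeling,
    baseline: int = DIPLOID_BASELINE,
) -> ViolationStats:
    """Count CNT-model violations in a (copy-number space) ancestral labeling.

    Reported: maximal runs of negative entries in ancestral profiles
    (per chromosome); the minimum ancestral entry; amplification events of
    the canonical per-edge decomposition that cover a locus currently at or
    below zero; and the fraction of all events that violate CNT semantics
    (amplifying, or deleting, a locus at or below zero at application time).
    """
    lab = labeling.to_copy_number()
    layout = lab.layout
    leaves = set(tree.leaves())
    n_edges = len(tree.edges())
    neg_stretches = 0
    min_entry = 0
    for v, x in lab.labels.items():
        if v in leaves:
            continue
        x = np.asarray(x)
        min_entry = min(min_entry, int(x.min()))
        for c in layout.chroms:
            seg = x[layout.bin_slice(c)] < 0
            neg_stretches += int(np.diff(np.concatenate([[0], seg.view(np.int8)])).clip(0).sum())
    zero_amps = 0
    violating = 0
    total_events = 0
    for u, v in tree.edges():
        cur = np.asarray(lab.labels[u], dtype=np.int64).copy()
        events = canonical_event_decomposition(cur, np.asarray(lab.labels[v]), layout,
                                               lab.baseline)
        total_events += len(events)
        for ev in events:
            sl = layout.bin_slice(ev.chrom)
            window = cur[sl][ev.start : ev.end + 1]
            touches_nonpositive = bool((window <= 0).any())
            if touches_nonpositive:
                violating += 1
                if ev.sign > 0:
                    zero_amps += 1
            cur[sl][ev.start : ev.end + 1] += ev.sign
    return ViolationStats(
        n_edges=n_edges,
        negative_stretches=neg_stretches,
        min_entry=min_entry,
        zero_amplifications=zero_amps,
        violating_events=violating,
        total_events=total_events,
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle (tiny instances only)
# ---------------------------------------------------------------------------

def brute_force_small_parsimony(
    tree: Phylogeny,
    M: CopyNumberMatrix,
    box: int = 4,
    baseline: int = DIPLOID_BASELINE,
) -> float:
    """Exhaustive optimum over balanced integer labelings with entries in
    [-box, box]; tree DP over the full enumerated label set.

    Independent of the interval/LP solvers; intended for tiny instances.
    """
    candidates = _enumerate_balanced(layout=M.layout, box=box)
    leaf_vals = _leaf_deltas(tree, M, baseline)
    for val in leaf_vals.values():
        if np.abs(val).max() > box:
            raise ValueError("leaf delta outside the enumeration box")
    # msg[v][x] = cost of v's subtree as a function of v's *parent* label x:
    # for a leaf that is ||x - leaf||_1; for an internal vertex it is
    # min over v's own label y of ||x - y||_1 + (children messages at y).
    msg: dict = {}
    own: dict = {}
    for v in tree.postorder():
        kids = tree.children(v)
        if not kids:
            val = np.asarray(leaf_vals[v], dtype=np.int64)
            msg[v] = np.abs(candidates - val[None, :]).sum(axis=1).astype(float)
            continue
        own[v] = np.sum([msg[c] for c in kids], axis=0)
        if v != tree.root:
            msg[v] = _min_plus_l1(candidates, own[v])
    return float(own[tree.root].min())


def _enumerate_balanced(layout: ChromLayout, box: int) -> np.ndarray:
    per_chrom = []
    for c in layout.chroms:
        ln = layout.delta_slice(c).stop - layout.delta_slice(c).start
        vecs = [
            v
            for v in itertools.product(range(-box, box + 1), repeat=ln)
            if sum(v) == 0
        ]
        per_chrom.append(np.array(vecs, dtype=np.int64))
    combos = per_chrom[0]
    for nxt in per_chrom[1:]:
        combos = np.concatenate(
            [
                np.repeat(combos, len(nxt), axis=0),
                np.tile(nxt, (len(combos), 1)),
            ],
            axis=1,
        )
    return combos


def _min_plus_l1(candidates: np.ndarray, child_cost: np.ndarray) -> np.ndarray:
    """For each candidate x: min_y ||x - y||_1 + child_cost[y] over candidates y."""
    out = np.empty(len(candidates))
    chunk = 512
    for i in range(0, len(candidates), chunk):
        block = candidates[i : i + chunk]
        d = np.abs(block[:, None, :] - candidates[None, :, :]).sum(axis=2)
        out[i : i + chunk] = (d + child_cost[None, :]).min(axis=1)
    return out
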