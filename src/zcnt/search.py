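"""Large parsimony by neighbor joining plus NNI hill climbing.

The pipeline builds a starting topology by neighbor joining on pairwise
ZCNT distances, then hill-climbs with nearest-neighbor-interchange (NNI)
moves scored by the fast unbalanced small-parsimony relaxation (whose
ranking of topologies tracks the balanced score closely), escaping local
optima with random NNI perturbation walks.  The final tree is rooted at a
diploid pseudo-leaf and labeled with the balanced 2-approximation (or the
exact ILP on request).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix, zcnt_distance_matrix
from .parsimony import (
    DIPLOID_LEAF,
    ParsimonyResult,
    _leaf_deltas,
    exact_small_parsimony_ilp,
    two_approx_small_parsimony,
    unbalanced_score,
)
from .profiles import CopyNumberMatrix, DIPLOID_BASELINE
from .tree import Phylogeny, TreeError


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the stochastic NNI search.

    ``perturbation_strength`` is the random-walk length after each converged
    climb, as a fraction of the leaf count; ``max_rounds`` bounds the number
    of perturb-and-reclimb rounds.  ``scorer`` chooses the objective used
    during the search; the final labeling is always balanced.
    """

    seed: int = 0
    max_rounds: int = 50
    perturbation_strength: float = 0.2
    improvement: str = "best"  # or "first"
    root_at_diploid: bool = True
    scorer: str = "unbalanced"  # or "two-approx"
    final_scorer: str = "two-approx"  # or "ilp"

    def __post_init__(self) -> None:
        if not 0.0 <= self.perturbation_strength <= 1.0:
            raise ValueError("perturbation_strength must be in [0, 1]")
        if self.max_rounds < 0:
            raise ValueError("max_rounds must be >= 0")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(D: DistanceMatrix) -> Phylogeny:
    """Saitou-Nei neighbor joining with deterministic lowest-index tie-breaking.

    Returns the unrooted topology represented as a tree rooted at the final
    (degree-three) join vertex.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    mat = D.values.copy().astype(float)
    if (np.diag(mat) != 0).any() or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    active = list(range(n))
    nodes: dict[int, object] = {i: lab for i, lab in enumerate(D.labels)}
    edges: list[tuple] = []
    counter = itertools.count()
    big = mat
    while len(active) > 3:
        k = len(active)
        sub = big[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)  # ties: lowest (i, j) index pair wins
        i, j = divmod(flat, k)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        new = n + next(counter)
        name = f"_n{new}"
        nodes[new] = name
        d_ab = big[a, b]
        edges.append((name, nodes[a]))
        edges.append((name, nodes[b]))
        # extend the working matrix with the new vertex's distances
        col = 0.5 * (big[a, :] + big[b, :] - d_ab)
        big = np.pad(big, ((0, 1), (0, 1)))
        big[new, : new] = col[:new]
        big[: new, new] = col[:new]
        active = [x for x in active if x not in (a, b)] + [new]
    root = f"_n{n + next(counter)}"
    for x in active:
        edges.append((root, nodes[x]))
    return Phylogeny.from_edges(edges, root)


# ---------------------------------------------------------------------------
# NNI neighborhood
# ---------------------------------------------------------------------------

def internal_edges(tree: Phylogeny) -> list[tuple]:
    """Edges corresponding to internal edges of the unrooted topology."""
    out = []
    root_kids = tree.children(tree.root)
    two_child_root = len(root_kids) == 2
    for u, v in tree.edges():
        if tree.graph.out_degree(v) == 0:
            continue
        if u == tree.root and two_child_root:
            # the two root edges project to a single unrooted edge
            other = root_kids[1] if v == root_kids[0] else root_kids[0]
            if tree.graph.out_degree(other) == 0:
                continue  # pendant edge once the root is suppressed
            if v != root_kids[0]:
                continue  # count the through-root edge once
        out.append((u, v))
    return out


def nni_neighbors(tree: Phylogeny, edge: tuple) -> list[Phylogeny]:
    """The two topologies obtained by an NNI across an internal edge."""
    u, v = edge
    if edge not in set(internal_edges(tree)):
        raise TreeError(f"{edge} is not an internal edge")
    a, b = tree.children(v)
    u_kids = [w for w in tree.children(u) if w != v]
    if u == tree.root and len(tree.children(u)) == 2:
        # the unrooted edge runs through the degree-two root: the opposite
        # side's subtrees are the children of the other root child
        w = tree.children(u_kids[0])[0]
    else:
        w = u_kids[0]
    return [_swap(tree, a, w), _swap(tree, b, w)]


def _swap(tree: Phylogeny, x, y) -> Phylogeny:
    g = tree.graph.copy()
    px, py = tree.parent(x), tree.parent(y)
    g.remove_edge(px, x)
    g.remove_edge(py, y)
    g.add_edge(px, y)
    g.add_edge(py, x)
    return Phylogeny(g, tree.root)


# ---------------------------------------------------------------------------
# Hill climbing with stochastic perturbation restarts
# ---------------------------------------------------------------------------

def _score_fn(M: CopyNumberMatrix, cfg: SearchConfig, baseline: int):
    if cfg.scorer == "unbalanced":
        def score(tree, _cache={}):
            leaf_vals = _leaf_deltas(tree, M, baseline)
            return unbalanced_score(tree, leaf_vals)
        return score
    if cfg.scorer == "two-approx":
        return lambda tree: two_approx_small_parsimony(tree, M, baseline).score_l1
    raise ValueError(f"unknown scorer {cfg.scorer!r}")


def _climb(tree: Phylogeny, score, cfg: SearchConfig) -> tuple[Phylogeny, float, list[float]]:
    current = tree
    cur_score = score(current)
    trace = [cur_score]
    while True:
        best_tree, best_score = None, cur_score
        for edge in internal_edges(current):
            for cand in nni_neighbors(current, edge):
                s = score(cand)
                if s < best_score - 1e-9:
                    best_tree, best_score = cand, s
                    if cfg.improvement == "first":
                        break
            if best_tree is not None and cfg.improvement == "first":
                break
        if best_tree is None:
            return current, cur_score, trace
        current, cur_score = best_tree, best_score
        trace.append(cur_score)


def _random_walk(tree: Phylogeny, steps: int, rng: np.random.Generator) -> Phylogeny:
    current = tree
    for _ in range(steps):
        edges = internal_edges(current)
        if not edges:
            break
        edge = edges[rng.integers(len(edges))]
        current = nni_neighbors(current, edge)[int(rng.integers(2))]
    return current


def hill_climb(
    tree: Phylogeny,
    M: CopyNumberMatrix,
    cfg: SearchConfig = SearchConfig(),
    baseline: int = DIPLOID_BASELINE,
) -> tuple[Phylogeny, list[float]]:
    """Best-improvement NNI search from a starting tree.

    After each converged climb the tree is perturbed by a random NNI walk of
    length ``ceil(perturbation_strength * n_leaves)`` and re-climbed, keeping
    the best tree seen.  The returned trace lists the accepted (best-so-far)
    scores and is non-increasing.  Fully reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    score = _score_fn(M, cfg, baseline)
    best, best_score, trace = _climb(tree, score, cfg)
    steps = math.ceil(cfg.perturbation_strength * best.n_leaves())
    for _ in range(cfg.max_rounds):
        if steps == 0:
            break
        start = _random_walk(best, steps, rng)
        cand, cand_score, cand_trace = _climb(start, score, cfg)
        if cand_score < best_score - 1e-9:
            best, best_score = cand, cand_score
            trace.append(cand_score)
    # report the monotone envelope of accepted states
    mono = []
    cur = math.inf
    for s in trace:
        cur = min(cur, s)
        mono.append(cur)
    return best, mono


@dataclass
class InferenceResult:
    """Everything the large-parsimony pipeline produces."""

    tree: Phylogeny
    labeling: object
    parsimony: ParsimonyResult
    nj_tree: Phylogeny
    score_trace: list[float] = field(default_factory=list)


def infer(
    M: CopyNumberMatrix,
    cfg: SearchConfig = SearchConfig(),
    baseline: int = DIPLOID_BASELINE,
) -> InferenceResult:
    """Distance matrix -> NJ -> NNI hill climb -> rooted, labeled phylogeny.

    With ``root_at_diploid`` a pseudo-cell with an all-diploid profile joins
    the search and becomes the root of the returned tree, so the root label
    is the normal genome; it is dropped by the evaluation metrics.
    """
    if M.n_cells < 3:
        raise ValueError("need at least three cells to infer a phylogeny")
    work = M
    if cfg.root_at_diploid:
        if DIPLOID_LEAF in M.cells:
            raise ValueError(f"cell name {DIPLOID_LEAF!r} is reserved for the root")
        work = M.with_cell(DIPLOID_LEAF, np.full(M.n_bins, baseline))
    D = zcnt_distance_matrix(work, baseline)
    start = nj_tree(D)
    best, trace = hill_climb(start, work, cfg, baseline)
    final = best.reroot_at_leaf(DIPLOID_LEAF) if cfg.root_at_diploid else best
    if cfg.final_scorer == "ilp":
        result = exact_small_parsimony_ilp(final, work, baseline)
    else:
        result = two_approx_small_parsimony(final, work, baseline)
    return InferenceResult(
        tree=final,
        labeling=result.labeling,
        parsimony=result,
        nj_tree=start,
        score_trace=trace,
    )
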