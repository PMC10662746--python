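"""Tree comparison and concordance statistics.

Robinson-Foulds distances between inferred and reference topologies,
sibling dissimilarity (how different are the profiles of leaves that the
tree places next to each other), and clonal discordance (how many clone
label changes a tree forces, computed by Hartigan's multi-state parsimony,
which is exact on multifurcating trees).  A pseudo-leaf named ``diploid``
(the root marker used by the search) is dropped before any comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .parsimony import DIPLOID_LEAF
from .profiles import CopyNumberMatrix
from .tree import Phylogeny


def _strip_diploid(tree: Phylogeny) -> Phylogeny:
    if DIPLOID_LEAF in tree.leaf_set():
        return tree.drop_leaf(DIPLOID_LEAF)
    return tree


def rf_distance(t1: Phylogeny, t2: Phylogeny, normalized: bool = False) -> float:
    """Robinson-Foulds distance on unrooted, non-trivial splits.

    The normalized form divides by the total number of non-trivial splits in
    both trees, which stays meaningful for multifurcating (partially
    unresolved) trees; it is 0 for identical topologies and 1 for trees
    sharing no non-trivial split.
    """
    t1, t2 = _strip_diploid(t1), _strip_diploid(t2)
    if t1.leaf_set() != t2.leaf_set():
        raise ValueError("trees must share the same leaf set")
    s1, s2 = t1.nontrivial_splits(), t2.nontrivial_splits()
    raw = len(s1 ^ s2)
    if not normalized:
        return float(raw)
    denom = len(s1) + len(s2)
    return 0.0 if denom == 0 else raw / denom


@dataclass
class SiblingDissimilarity:
    """Mean and per-pair normalized Hamming distances between sibling leaves."""

    per_pair: list
    mean: float
    n_pairs: int


def sibling_dissimilarity(tree: Phylogeny, M: CopyNumberMatrix) -> SiblingDissimilarity:
    """Normalized Hamming distance between profiles of sibling leaf pairs.

    All unordered leaf-child pairs of every vertex are used, so polytomies
    contribute every pair.  Raises if the tree has no sibling leaf pair.
    """
    tree = _strip_diploid(tree)
    index = {c: i for i, c in enumerate(M.cells)}
    values = []
    m = M.n_bins
    for v in tree.internal_vertices():
        leaf_kids = [c for c in tree.children(v) if tree.graph.out_degree(c) == 0]
        for a, b in combinations(leaf_kids, 2):
            ham = int((M.values[index[a]] != M.values[index[b]]).sum())
            values.append(ham / m)
    if not values:
        raise ValueError("tree has no pair of sibling leaves")
    return SiblingDissimilarity(values, float(np.mean(values)), len(values))


def read_clone_labels(path) -> dict:
    """Read a two-column (cell, clone) TSV/CSV into a mapping."""
    sep = "\t"
    with open(path, "r", encoding="utf-8") as fh:
        if fh.readline().count(",") > 0:
            sep = ","
    df = pd.read_csv(path, sep=sep)
    cell_col, clone_col = df.columns[:2]
    return dict(zip(df[cell_col].astype(str), df[clone_col].astype(str)))


def clonal_discordance(tree: Phylogeny, clones: Mapping) -> int:
    """Minimum number of clone-label changes over the tree's edges.

    Single multi-state character parsimony via Hartigan's algorithm (valid
    for arbitrary vertex degrees).  When every clone forms a clade, the
    score attains its minimum of k - 1 for k distinct labels.
    """
    tree = _strip_diploid(tree)
    missing = [leaf for leaf in tree.leaves() if leaf not in clones]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing[:3]}")
    cost = 0
    top: dict = {}
    for v in tree.postorder():
        kids = tree.children(v)
        if not kids:
            top[v] = {clones[v]}
            continue
        counts: dict = {}
        for c in kids:
            for label in top[c]:
                counts[label] = counts.get(label, 0) + 1
        best = max(counts.values())
        top[v] = {label for label, k in counts.items() if k == best}
        cost += len(kids) - best
    return cost


def brute_force_discordance(tree: Phylogeny, clones: Mapping) -> int:
    """Exhaustive minimum over all internal label assignments (tiny trees)."""
    tree = _strip_diploid(tree)
    labels = sorted(set(clones[leaf] for leaf in tree.leaves()))
    internals = tree.internal_vertices()
    if len(labels) ** len(internals) > 500_000:
        raise ValueError("brute force guard exceeded")
    from itertools import product

    best = None
    for combo in product(labels, repeat=len(internals)):
        assign = dict(zip(internals, combo))
        assign.update({leaf: clones[leaf] for leaf in tree.leaves()})
        changes = sum(1 for u, v in tree.edges() if assign[u] != assign[v])
        best = changes if best is None else min(best, changes)
    return int(best)
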