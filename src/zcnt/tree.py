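"""Rooted phylogeny container used by parsimony solvers and tree search.

Trees are stored as networkx DiGraphs with edges oriented away from the
root.  Leaves are named by cell identifiers; internal vertices get fresh
string names.  An *unrooted* binary topology is represented by rooting at an
internal vertex of degree three, which is the representation the NNI search
operates on.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Sequence

import dendropy
import networkx as nx


class TreeError(ValueError):
    """Malformed tree or invalid tree operation."""


class Phylogeny:
    """A rooted tree with named leaves."""

    def __init__(self, graph: nx.DiGraph, root):
        if root not in graph:
            raise TreeError("root is not a vertex of the tree")
        if not nx.is_arborescence(graph):
            raise TreeError("graph must be a rooted tree (arborescence)")
        if next(iter(nx.topological_sort(graph))) != root:
            raise TreeError("declared root has a parent")
        self.graph = graph
        self.root = root

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"unparseable newick: {exc}") from exc
        graph = nx.DiGraph()
        counter = itertools.count()
        names: dict[dendropy.Node, str] = {}

        def name_of(node: dendropy.Node) -> str:
            if node not in names:
                if node.is_leaf():
                    if node.taxon is None or not node.taxon.label:
                        raise TreeError("newick leaf without a label")
                    names[node] = node.taxon.label
                elif node.label:  # keep named internal vertices (e.g. the root)
                    names[node] = node.label
                else:
                    names[node] = f"_v{next(counter)}"
            return names[node]

        for node in dtree.preorder_node_iter():
            graph.add_node(name_of(node))
            for child in node.child_nodes():
                graph.add_edge(name_of(node), name_of(child))
        tree = cls(graph, name_of(dtree.seed_node))
        if len(set(tree.leaves())) != len(tree.leaves()):
            raise TreeError("duplicate leaf labels in newick")
        return tree

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], root) -> "Phylogeny":
        g = nx.DiGraph()
        g.add_node(root)
        g.add_edges_from(edges)
        return cls(g, root)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.graph.copy(), self.root)

    # -- basic queries -----------------------------------------------------

    def leaves(self) -> list:
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    def leaf_set(self) -> frozenset:
        return frozenset(self.leaves())

    def internal_vertices(self) -> list:
        return [v for v in self.graph if self.graph.out_degree(v) > 0]

    def children(self, v) -> list:
        return list(self.graph.successors(v))

    def parent(self, v):
        preds = list(self.graph.predecessors(v))
        return preds[0] if preds else None

    def edges(self) -> list[tuple]:
        return list(self.graph.edges())

    def n_leaves(self) -> int:
        return len(self.leaves())

    def postorder(self) -> Iterator:
        return nx.dfs_postorder_nodes(self.graph, self.root)

    def preorder(self) -> Iterator:
        return nx.dfs_preorder_nodes(self.graph, self.root)

    def is_binary(self) -> bool:
        return all(
            self.graph.out_degree(v) in (0, 2) or (v == self.root and self.graph.out_degree(v) in (1, 2, 3))
            for v in self.graph
        ) and all(
            self.graph.out_degree(v) in (0, 2) for v in self.graph if v != self.root
        )

    # -- transformations ---------------------------------------------------

    def resolve_polytomies(self, order: Sequence | None = None) -> "Phylogeny":
        """Return a binary tree refining this one.

        Vertices with more than two children are resolved into a caterpillar
        of fresh degree-two vertices; a root with a single child is kept.
        Resolution is deterministic: children are processed in graph order
        (or the supplied order).
        """
        g = self.graph.copy()
        counter = itertools.count()
        fresh = lambda: f"_r{next(counter)}"  # noqa: E731
        for v in list(self.postorder()):
            kids = list(g.successors(v))
            if order is not None:
                rank = {x: i for i, x in enumerate(order)}
                kids = sorted(kids, key=lambda x: rank.get(x, len(rank)))
            while len(kids) > 2:
                a, b = kids[0], kids[1]
                w = fresh()
                while w in g:
                    w = fresh()
                g.add_node(w)
                g.remove_edge(v, a)
                g.remove_edge(v, b)
                g.add_edge(v, w)
                g.add_edge(w, a)
                g.add_edge(w, b)
                kids = [w] + kids[2:]
        return Phylogeny(g, self.root)

    def reroot_at_leaf(self, leaf) -> "Phylogeny":
        """Re-root the topology so that ``leaf`` becomes the (pendant) root."""
        if leaf not in self.graph or self.graph.out_degree(leaf) != 0:
            raise TreeError(f"{leaf!r} is not a leaf")
        und = self.graph.to_undirected(as_view=False)
        g = nx.DiGraph()
        g.add_node(leaf)
        for u, v in nx.bfs_edges(und, leaf):
            g.add_edge(u, v)
        # Suppress any degree-two former root left over from re-orientation.
        for v in list(g.nodes):
            if v != leaf and g.out_degree(v) == 1 and g.in_degree(v) == 1:
                (p,) = g.predecessors(v)
                (c,) = g.successors(v)
                g.remove_node(v)
                g.add_edge(p, c)
        return Phylogeny(g, leaf)

    def drop_leaf(self, leaf) -> "Phylogeny":
        """Remove a leaf and suppress the resulting degree-two vertex."""
        if self.graph.out_degree(leaf) != 0:
            raise TreeError(f"{leaf!r} is not a leaf")
        g = self.graph.copy()
        parent = self.parent(leaf)
        g.remove_node(leaf)
        root = self.root
        if parent is not None:
            kids = list(g.successors(parent))
            gp = next(iter(g.predecessors(parent)), None)
            if len(kids) == 1 and gp is not None:
                g.remove_node(parent)
                g.add_edge(gp, kids[0])
            elif len(kids) == 1 and gp is None:
                g.remove_node(parent)
                root = kids[0]
        return Phylogeny(g, root)

    # -- split-based comparison helpers -------------------------------------

    def nontrivial_splits(self, leaf_subset: frozenset | None = None) -> set[frozenset]:
        """Unrooted non-trivial bipartitions, each encoded canonically.

        Each internal edge induces a bipartition of the leaves; the side not
        containing the reference leaf (the lexicographically smallest) is
        stored.  Trivial splits (singleton or full set) are excluded.
        """
        leaves = self.leaf_set() if leaf_subset is None else leaf_subset
        ref = min(leaves)
        splits: set[frozenset] = set()
        below: dict[object, frozenset] = {}
        for v in self.postorder():
            if self.graph.out_degree(v) == 0:
                below[v] = frozenset([v]) & leaves
            else:
                below[v] = frozenset().union(*(below[c] for c in self.children(v)))
        for _, v in self.graph.edges():
            clade = below[v]
            side = leaves - clade if ref in clade else clade
            if 1 < len(side) < len(leaves) - 1:
                splits.add(side)
        return splits

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def render(v) -> str:
            kids = self.children(v)
            if not kids:
                return _quote(str(v))
            label = "" if str(v).startswith("_") else _quote(str(v))
            return "(" + ",".join(render(c) for c in kids) + ")" + label

        return render(self.root) + ";"

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick", preserve_underscores=True
        )

    def __repr__(self) -> str:
        return f"Phylogeny(n_leaves={self.n_leaves()}, root={self.root!r})"


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),;:'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(path) -> Phylogeny:
    """Read a rooted tree from a newick file."""
    with open(path, "r", encoding="utf-8") as fh:
        return Phylogeny.from_newick(fh.read())


def write_newick(tree: Phylogeny, path) -> None:
    """Write a tree to a newick file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")
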