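"""Model / Results interface over the ZCNT parsimony machinery.

``CopyNumberTreeModel`` is constructed from a copy number matrix (and,
optionally, a fixed tree topology); ``fit()`` performs ancestral-state
inference -- and, when no tree is given, tree search -- and returns a
``CopyNumberTreeResults`` carrying the tree, the ancestral labeling, the
parsimony scores, CNT-violation diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import parsimony as _parsimony
from .evaluate import rf_distance
from .io import read_copy_number_table
from .parsimony import (
    AncestralLabeling,
    ParsimonyResult,
    cnt_violation_stats,
)
from .profiles import CopyNumberMatrix, DIPLOID_BASELINE
from .search import InferenceResult, SearchConfig, infer
from .tree import Phylogeny

_SMALL_PARSIMONY = {
    "unbalanced": _parsimony.unbalanced_small_parsimony,
    "lp": _parsimony.lp_relaxation_small_parsimony,
    "ilp": _parsimony.exact_small_parsimony_ilp,
    "two-approx": _parsimony.two_approx_small_parsimony,
}


class CopyNumberTreeModel:
    """ZCNT parsimony model for tumor copy number evolution.

    Parameters
    ----------
    matrix
        Copy number matrix (cells x bins).
    tree
        Optional fixed topology whose leaves are the matrix's cells.  When
        omitted, ``fit`` searches for a topology (large parsimony).
    baseline
        Copy number of the normal genome used to pad chromosome ends in the
        delta map (default 2, diploid).
    """

    def __init__(
        self,
        matrix: CopyNumberMatrix,
        tree: Phylogeny | None = None,
        baseline: int = DIPLOID_BASELINE,
    ):
        self.matrix = matrix
        self.tree = tree
        self.baseline = baseline
        if tree is not None:
            missing = [
                leaf
                for leaf in tree.leaves()
                if leaf not in matrix.cells and leaf != _parsimony.DIPLOID_LEAF
            ]
            if missing:
                raise ValueError(f"tree leaves without profiles: {missing[:3]}")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, bins: pd.DataFrame, tree: Phylogeny | None = None, **kw
    ) -> "CopyNumberTreeModel":
        """Build from a cells-x-bins DataFrame plus bin metadata."""
        matrix = CopyNumberMatrix(
            [str(c) for c in df.index], df.to_numpy(), bins
        )
        return cls(matrix, tree, **kw)

    @classmethod
    def from_table(cls, path, tree: Phylogeny | None = None, **kw) -> "CopyNumberTreeModel":
        """Build from a long- or wide-format copy number table on disk."""
        return cls(read_copy_number_table(path), tree, **kw)

    def fit(
        self,
        method: str = "two-approx",
        search: SearchConfig | None = None,
    ) -> "CopyNumberTreeResults":
        """Infer ancestral profiles (and, if needed, the topology).

        ``method`` selects the small parsimony solver: ``unbalanced``,
        ``lp``, ``ilp``, or ``two-approx``.  With no fixed tree, a
        ``SearchConfig`` drives the NJ + NNI search and ``method`` is used
        for the final labeling (``ilp`` or ``two-approx``).
        """
        if self.tree is not None:
            solver = _SMALL_PARSIMONY[method]
            result = solver(self.tree, self.matrix, self.baseline)
            return CopyNumberTreeResults(self, self.tree, result, None)
        cfg = search or SearchConfig()
        if method in ("ilp", "two-approx"):
            cfg = replace(cfg, final_scorer="ilp" if method == "ilp" else "two-approx")
        inference = infer(self.matrix, cfg, self.baseline)
        return CopyNumberTreeResults(self, inference.tree, inference.parsimony, inference)


class CopyNumberTreeResults:
    """Fitted tree, ancestral labeling, scores, and diagnostics."""

    def __init__(
        self,
        model: CopyNumberTreeModel,
        tree: Phylogeny,
        parsimony: ParsimonyResult,
        inference: InferenceResult | None = None,
    ):
        self.model = model
        self.tree = tree
        self.parsimony = parsimony
        self.inference = inference

    @property
    def labeling(self) -> AncestralLabeling:
        return self.parsimony.labeling

    @property
    def score_l1(self) -> float:
        return self.parsimony.score_l1

    @property
    def score_events(self) -> float:
        return self.parsimony.score_events

    @property
    def method(self) -> str:
        return self.parsimony.method

    def ancestral_profiles(self) -> pd.DataFrame:
        """Copy-number-space labels of internal vertices, one row per vertex."""
        lab = self.labeling.to_copy_number()
        leaves = set(self.tree.leaves())
        rows = {
            str(v): np.asarray(x)
            for v, x in lab.labels.items()
            if v not in leaves
        }
        cols = [
            f"{r.chrom}:{r.start}-{r.end}"
            for r in self.model.matrix.bins.itertuples(index=False)
        ]
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    def violation_stats(self):
        """CNT-model violation diagnostics of the fitted labeling."""
        return cnt_violation_stats(self.tree, self.labeling, self.model.baseline)

    def rf_to(self, other: Phylogeny, normalized: bool = True) -> float:
        """Robinson-Foulds distance from the fitted tree to a reference."""
        return rf_distance(self.tree, other, normalized=normalized)

    def simulate_trace_frame(self) -> pd.DataFrame:
        """Accepted-score trace of the tree search (empty for fixed trees)."""
        trace = self.inference.score_trace if self.inference else []
        return pd.DataFrame({"step": range(len(trace)), "score_l1": trace})

    def plot_score_trace(self, ax=None):
        """Plot the accepted-score trace of the tree search."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.simulate_trace_frame()
        ax.step(frame["step"], frame["score_l1"], where="post")
        ax.set_xlabel("accepted move")
        ax.set_ylabel("unbalanced parsimony score (L1)")
        return ax

    def summary(self) -> str:
        """Human-readable summary of the fit."""
        stats = self.violation_stats()
        n_int = len(self.tree.internal_vertices())
        lines = [
            "ZCNT copy number parsimony results",
            "=" * 42,
            f"cells                 {self.model.matrix.n_cells:>10d}",
            f"bins                  {self.model.matrix.n_bins:>10d}",
            f"chromosomes           {len(self.model.matrix.layout.chroms):>10d}",
            f"tree leaves           {self.tree.n_leaves():>10d}",
            f"internal vertices     {n_int:>10d}",
            f"method                {self.method:>10s}",
            f"parsimony score (L1)  {self.score_l1:>10.1f}",
            f"parsimony score (events) {self.score_events:>7.1f}",
            f"min ancestral copy nr {stats.min_entry:>10d}",
            f"neg. stretches / edge {stats.negative_stretches_per_edge:>10.4f}",
            f"zero-amps / edge      {stats.zero_amplifications_per_edge:>10.4f}",
            f"violating event frac. {stats.violating_score_fraction:>10.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"CopyNumberTreeResults(method={self.method!r}, "
            f"score_events={self.score_events:g})"
        )
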