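"""ZCNT distances, pairwise matrices, and brute-force event-count oracles.

The ZCNT distance between two copy number profiles has a closed form: half
the L1 norm of the difference of their delta profiles, summed over
chromosomes.  Because the difference of two balanced vectors is balanced and
a balanced integer vector has even L1 norm, the distance is always a
non-negative integer, and it is a metric.

The CNT distance (where events skip zero-copy loci) has no such closed form
and is not even symmetric; at toy scale it is computed here by breadth-first
search over profile space, which also serves as an independent oracle for
the ZCNT closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .profiles import CopyNumberProfile, CopyNumberMatrix, DIPLOID_BASELINE

INFEASIBLE = float("inf")

_ORACLE_MAX_BINS = 6
_ORACLE_MAX_COPY = 5
_ORACLE_MAX_EVENTS = 12


class OracleScaleError(ValueError):
    """BFS oracle invoked beyond its guarded toy scale."""


def zcnt_distance(p: CopyNumberProfile, p2: CopyNumberProfile,
                  baseline: int = DIPLOID_BASELINE) -> int:
    """Closed-form ZCNT distance: half the L1 delta difference."""
    if p.layout != p2.layout:
        raise ValueError("profiles must share the same bin structure")
    d1 = p.delta(baseline).concat(p.layout)
    d2 = p2.delta(baseline).concat(p.layout)
    return int(np.abs(d1 - d2).sum() // 2)


def zcnt_distance_matrix(M: CopyNumberMatrix, baseline: int = DIPLOID_BASELINE) -> "DistanceMatrix":
    """All-pairs ZCNT distance matrix of a copy number matrix."""
    if M.n_cells < 2:
        raise ValueError("need at least two cells for a distance matrix")
    deltas = M.delta_matrix(baseline)
    values = squareform(pdist(deltas, metric="cityblock")) / 2.0
    return DistanceMatrix(list(M.cells), values)


class DistanceMatrix:
    """Symmetric pairwise distances with cell labels."""

    def __init__(self, labels, values):
        self.labels = [str(x) for x in labels]
        self.values = np.asarray(values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must have a zero diagonal")

    def __getitem__(self, pair):
        i, j = pair
        if not isinstance(i, int):
            i = self.labels.index(i)
        if not isinstance(j, int):
            j = self.labels.index(j)
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="cell_id")

    def to_phylip(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + "  ".join(f"{x:.6g}" for x in row) + "\n")

    def __repr__(self) -> str:
        return f"DistanceMatrix(n={len(self.labels)})"


# ---------------------------------------------------------------------------
# BFS oracles over toy profile spaces
# ---------------------------------------------------------------------------

class _EventGraph:
    """All profiles in an integer box, with interval-event adjacency.

    States are integer vectors in ``[lo, hi]^m`` (single chromosome),
    linearised by mixed-radix encoding.  ``neighbors[s, e]`` is the state
    reached from ``s`` by event ``e`` (the state itself if the event is a
    no-op or would leave the box).  Shared by the CNT and ZCNT oracles and
    by the exhaustive acceptance checks.
    """

    def __init__(self, m: int, lo: int, hi: int, semantics: str):
        if semantics not in ("CNT", "ZCNT"):
            raise ValueError("semantics must be 'CNT' or 'ZCNT'")
        self.m, self.lo, self.hi = m, lo, hi
        width = hi - lo + 1
        if width ** m > 2_000_000:
            raise OracleScaleError("oracle state space too large")
        grids = np.meshgrid(*([np.arange(lo, hi + 1)] * m), indexing="ij")
        self.states = np.stack([g.ravel() for g in grids], axis=1)  # (S, m)
        events = [
            (s, t, b)
            for s in range(m)
            for t in range(s, m)
            for b in (+1, -1)
        ]
        self.events = events
        S = self.states.shape[0]
        nbr = np.empty((S, len(events)), dtype=np.int64)
        radix = width ** np.arange(m - 1, -1, -1)
        codes = (self.states - lo) @ radix
        order = np.argsort(codes)
        assert np.array_equal(codes[order], np.arange(S))
        for e, (s, t, b) in enumerate(events):
            nxt = self.states.copy()
            if semantics == "ZCNT":
                nxt[:, s : t + 1] += b
            else:
                window = nxt[:, s : t + 1]
                window += b * (window != 0)
            ok = ((nxt >= lo) & (nxt <= hi)).all(axis=1)
            nxt_codes = np.where(ok, (np.clip(nxt, lo, hi) - lo) @ radix, codes)
            nbr[:, e] = nxt_codes
        self.neighbors = nbr
        self._radix = radix

    def encode(self, profile: np.ndarray) -> int:
        profile = np.asarray(profile, dtype=np.int64)
        if (profile < self.lo).any() or (profile > self.hi).any():
            raise OracleScaleError("profile outside oracle box")
        return int((profile - self.lo) @ self._radix)

    def bfs_from(self, source: np.ndarray, max_depth: int) -> np.ndarray:
        """Distances (in events) from a source to every state; -1 = unreached."""
        S = self.neighbors.shape[0]
        dist = np.full(S, -1, dtype=np.int32)
        frontier = np.array([self.encode(source)])
        dist[frontier] = 0
        depth = 0
        while len(frontier) and depth < max_depth:
            depth += 1
            nxt = np.unique(self.neighbors[frontier].ravel())
            nxt = nxt[dist[nxt] < 0]
            dist[nxt] = depth
            frontier = nxt
        return dist


def bfs_min_events(
    p: CopyNumberProfile | np.ndarray,
    p2: CopyNumberProfile | np.ndarray,
    semantics: str = "ZCNT",
    max_events: int = _ORACLE_MAX_EVENTS,
) -> float:
    """Minimum event count from ``p`` to ``p2`` by breadth-first search.

    Guarded to toy scale (<= 6 bins, copy numbers <= 5, <= 12 events); returns
    ``math.inf`` when no transformation of at most ``max_events`` events
    exists (for CNT this includes genuinely infeasible pairs, e.g. regaining
    a lost locus).
    """
    u = p.values if isinstance(p, CopyNumberProfile) else np.asarray(p, dtype=np.int64)
    v = p2.values if isinstance(p2, CopyNumberProfile) else np.asarray(p2, dtype=np.int64)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("profiles must be vectors of equal length")
    m = len(u)
    top = int(max(u.max(), v.max()))
    if m > _ORACLE_MAX_BINS or top > _ORACLE_MAX_COPY or max_events > _ORACLE_MAX_EVENTS:
        raise OracleScaleError(
            f"oracle scale exceeded (m <= {_ORACLE_MAX_BINS}, entries <= "
            f"{_ORACLE_MAX_COPY}, max_events <= {_ORACLE_MAX_EVENTS})"
        )
    if semantics == "CNT":
        lo, hi = 0, top + max_events
    else:
        lo, hi = int(min(u.min(), v.min(), 0)) - max_events, top + max_events
    graph = _EventGraph(m, lo, hi, semantics)
    dist = graph.bfs_from(u, max_events)
    d = dist[graph.encode(v)]
    return INFEASIBLE if d < 0 else int(d)


# ---------------------------------------------------------------------------
# CNT vs ZCNT comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class ComparisonSummary:
    """Per-pair relative differences between CNT and ZCNT distances."""

    relative_differences: list = field(default_factory=list)
    symmetrized_cnt: list = field(default_factory=list)
    zcnt: list = field(default_factory=list)
    n_skipped_zero_zcnt: int = 0
    n_skipped_infeasible: int = 0

    @property
    def median(self) -> float:
        return float(np.median(self.relative_differences))

    @property
    def quartiles(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.relative_differences, [25, 75])
        return float(q1), float(q3)


def cnt_zcnt_comparison(pairs, cnt_distances=None, max_events: int = _ORACLE_MAX_EVENTS) -> ComparisonSummary:
    """Compare CNT and ZCNT distances over profile pairs.

    For each pair (u, v) the relative difference |d_CNT / d_ZCNT - 1| is
    computed with the symmetrized CNT distance sigma'(u, v) =
    (sigma(u, v) + sigma(v, u)) / 2.  CNT distances are either supplied
    (one value per pair, already symmetrized) or computed by the toy BFS
    oracle in both directions.  Pairs with zero ZCNT distance or infeasible
    CNT transformation are skipped and counted.
    """
    summary = ComparisonSummary()
    for k, (u, v) in enumerate(pairs):
        d_z = zcnt_distance(u, v)
        if d_z == 0:
            summary.n_skipped_zero_zcnt += 1
            continue
        if cnt_distances is not None:
            sym = float(cnt_distances[k])
            if not np.isfinite(sym):
                summary.n_skipped_infeasible += 1
                continue
        else:
            fwd = bfs_min_events(u, v, "CNT", max_events)
            bwd = bfs_min_events(v, u, "CNT", max_events)
            if not (np.isfinite(fwd) and np.isfinite(bwd)):
                summary.n_skipped_infeasible += 1
                continue
            sym = (fwd + bwd) / 2.0
        summary.relative_differences.append(abs(sym / d_z - 1.0))
        summary.symmetrized_cnt.append(sym)
        summary.zcnt.append(d_z)
    if not summary.relative_differences:
        raise ValueError("all pairs were skipped; empty comparison summary")
    return summary
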