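"""Ground-truth simulator for copy number phylogenies.

Random binary topologies are built by iterative pair-joining; evolution
starts from an all-diploid root and draws a Poisson number of interval
events per edge, applied with CNT semantics by default so that simulated
data never violates the biological zero-skipping constraint (ZCNT semantics
is available for model-internal experiments).  The full event log and all
ancestral profiles are retained, so every simulation carries its own ground
truth for replay and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import (
    ChromLayout,
    CopyNumberMatrix,
    DIPLOID_BASELINE,
    EventRecord,
    default_bins,
)
from .tree import Phylogeny


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one simulated copy number phylogeny.

    ``events_per_edge_mean`` is the Poisson rate of interval events per tree
    edge; ``amplification_probability`` the chance an event is a gain.
    Interval endpoints are uniform over bins by default; the geometric
    option draws a focal event length instead.  ``max_copy_cap`` (if set)
    rejects events that would push any locus above the cap.
    """

    n_cells: int = 10
    n_bins: int = 30
    n_chromosomes: int = 1
    events_per_edge_mean: float = 3.0
    amplification_probability: float = 0.5
    length_distribution: str = "uniform"  # or "geometric"
    geometric_length_mean: float = 5.0
    max_copy_cap: int | None = None
    semantics: str = "CNT"  # or "ZCNT"
    baseline: int = DIPLOID_BASELINE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.events_per_edge_mean < 0:
            raise ValueError("event rate must be non-negative")
        if not 0.0 <= self.amplification_probability <= 1.0:
            raise ValueError("amplification probability must be in [0, 1]")
        if self.semantics not in ("CNT", "ZCNT"):
            raise ValueError("semantics must be 'CNT' or 'ZCNT'")


@dataclass
class SimulationResult:
    """Matrix, true tree, true ancestral profiles, and the event log."""

    matrix: CopyNumberMatrix
    tree: Phylogeny
    profiles: dict  # vertex -> copy-number vector (np.ndarray)
    event_log: list = field(default_factory=list)  # (edge, EventRecord)
    config: SimulationConfig | None = None


def simulate_topology(n: int, seed: int | np.random.Generator = 0) -> Phylogeny:
    """Random rooted binary tree over leaves cell_0..cell_{n-1}."""
    if n < 2:
        raise ValueError("need at least two leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lineages = [f"cell_{i}" for i in range(n)]
    edges = []
    counter = 0
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        parent = f"anc_{counter}"
        counter += 1
        edges.append((parent, lineages[i]))
        edges.append((parent, lineages[j]))
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)] + [parent]
    return Phylogeny.from_edges(edges, lineages[0])


def _draw_event(layout: ChromLayout, cfg: SimulationConfig, rng) -> EventRecord:
    chrom = layout.chroms[int(rng.integers(len(layout.chroms)))]
    m_c = layout.bin_slice(chrom).stop - layout.bin_slice(chrom).start
    if cfg.length_distribution == "geometric":
        length = min(int(rng.geometric(1.0 / max(cfg.geometric_length_mean, 1.0))), m_c)
        s = int(rng.integers(m_c - length + 1))
        t = s + length - 1
    else:
        s, t = sorted(int(x) for x in rng.integers(m_c, size=2))
    b = +1 if rng.random() < cfg.amplification_probability else -1
    return EventRecord(chrom, s, t, b)


def _apply_inplace(values: np.ndarray, ev: EventRecord, layout: ChromLayout,
                   semantics: str) -> None:
    sl = layout.bin_slice(ev.chrom)
    window = values[sl][ev.start : ev.end + 1]
    if semantics == "CNT":
        window += ev.sign * (window != 0)
    else:
        window += ev.sign


def simulate_evolution(tree: Phylogeny, cfg: SimulationConfig) -> SimulationResult:
    """Evolve copy number profiles down a tree from a diploid root."""
    rng = np.random.default_rng(cfg.seed)
    layout = ChromLayout(
        [f"chr{i + 1}" for i in range(cfg.n_chromosomes)],
        [cfg.n_bins] * cfg.n_chromosomes,
    )
    bins = default_bins(layout)
    profiles: dict = {tree.root: np.full(layout.n_bins, cfg.baseline, dtype=np.int64)}
    log: list = []
    for v in tree.preorder():
        for child in tree.children(v):
            values = profiles[v].copy()
            k = int(rng.poisson(cfg.events_per_edge_mean))
            for _ in range(k):
                ev = _draw_event(layout, cfg, rng)
                if cfg.max_copy_cap is not None:
                    trial = values.copy()
                    _apply_inplace(trial, ev, layout, cfg.semantics)
                    if trial.max() > cfg.max_copy_cap:
                        continue  # cap would be exceeded: reject the event
                    values = trial
                else:
                    _apply_inplace(values, ev, layout, cfg.semantics)
                log.append(((v, child), ev))
            profiles[child] = values
    leaves = tree.leaves()
    matrix = CopyNumberMatrix(
        leaves,
        np.stack([profiles[leaf] for leaf in leaves]),
        bins,
        require_nonnegative=cfg.semantics == "CNT",
    )
    return SimulationResult(matrix, tree, profiles, log, cfg)


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Random topology plus evolution, driven by a single seed."""
    rng = np.random.default_rng(cfg.seed)
    topo_seed = int(rng.integers(2**31 - 1))
    tree = simulate_topology(cfg.n_cells, topo_seed)
    from dataclasses import replace

    evo_cfg = replace(cfg, seed=int(rng.integers(2**31 - 1)))
    return simulate_evolution(tree, evo_cfg)


def replay_events(result: SimulationResult) -> dict:
    """Re-apply the event log from the diploid root; returns vertex profiles."""
    cfg = result.config
    layout = result.matrix.layout
    semantics = cfg.semantics if cfg is not None else "CNT"
    baseline = cfg.baseline if cfg is not None else DIPLOID_BASELINE
    by_edge: dict = {}
    for edge, ev in result.event_log:
        by_edge.setdefault(edge, []).append(ev)
    profiles = {result.tree.root: np.full(layout.n_bins, baseline, dtype=np.int64)}
    for v in result.tree.preorder():
        for child in result.tree.children(v):
            values = profiles[v].copy()
            for ev in by_edge.get((v, child), []):
                _apply_inplace(values, ev, layout, semantics)
            profiles[child] = values
    return profiles


def event_log_frame(result: SimulationResult) -> pd.DataFrame:
    """Event log as a tidy table (one row per event)."""
    rows = [
        {
            "parent": str(edge[0]),
            "child": str(edge[1]),
            "chrom": ev.chrom,
            "start_bin": ev.start,
            "end_bin": ev.end,
            "sign": ev.sign,
        }
        for edge, ev in result.event_log
    ]
    return pd.DataFrame(
        rows, columns=["parent", "child", "chrom", "start_bin", "end_bin", "sign"]
    )


def enumerate_profiles(m: int, B: int) -> np.ndarray:
    """All (B+1)^m copy number profiles with entries 0..B, lexicographic."""
    if (B + 1) ** m > 10**6:
        raise ValueError("enumeration guard exceeded: (B+1)^m must be <= 1e6")
    grids = np.meshgrid(*([np.arange(B + 1)] * m), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)
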