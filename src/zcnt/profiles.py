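"""Copy number profiles, delta profiles, and copy number event algebra.

A copy number profile assigns a non-negative integer copy number to each
genomic bin of a cell.  The *delta profile* is the vector of differences
between the copy numbers of adjacent bins, padded with a diploid baseline at
both ends of each chromosome; its entries always sum to zero per chromosome
(the *balancing condition*).  The delta map is a bijection between integer
copy-number vectors and balanced integer vectors, and is the coordinate
system in which zero-agnostic copy number (ZCNT) events become local:
an interval event only touches two delta entries.

Three event semantics are implemented:

* CNT: an interval amplification/deletion that skips zero-copy loci, so a
  lost locus can never be regained.
* ZCNT: the zero-agnostic relaxation, acting on every covered locus and
  allowing negative intermediate values.
* delta: the image of a ZCNT event under the delta map; it adds ``b`` to one
  delta entry and subtracts ``b`` from another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Baseline ("normal") copy number used to pad chromosome ends in the delta map.
DIPLOID_BASELINE = 2


class BalancingError(ValueError):
    """A delta segment does not sum to zero."""


class BinError(ValueError):
    """Malformed genomic bin metadata."""


@dataclass(frozen=True, order=True)
class GenomicBin:
    """A half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise BinError(f"bin start must precede end: {self}")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def validate_bins(bins: pd.DataFrame) -> pd.DataFrame:
    """Validate bin metadata (columns chrom/start/end) and return it.

    Within each chromosome bins must be sorted by start and non-overlapping.
    Chromosome blocks must be contiguous (order of first appearance is the
    chromosome order used throughout).
    """
    required = {"chrom", "start", "end"}
    if not required.issubset(bins.columns):
        raise BinError(f"bin table must have columns {sorted(required)}")
    if (bins["start"] >= bins["end"]).any():
        raise BinError("every bin must satisfy start < end")
    chroms = bins["chrom"].to_numpy()
    seen: dict[str, int] = {}
    for idx, c in enumerate(chroms):
        if c in seen and chroms[idx - 1] != c:
            raise BinError(f"chromosome {c!r} bins are not contiguous")
        seen.setdefault(c, idx)
    for c, sub in bins.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if not (starts[1:] >= ends[:-1]).all() or not (np.diff(starts) > 0).all():
            raise BinError(f"bins on {c!r} must be sorted and non-overlapping")
    return bins.reset_index(drop=True)


class ChromLayout:
    """Per-chromosome bin bookkeeping shared by profiles and delta vectors.

    For a chromosome with ``m_c`` bins, the corresponding delta segment has
    ``m_c + 1`` entries (one per bin boundary, including both telomeres).
    """

    def __init__(self, chroms: Sequence[str], sizes: Sequence[int]):
        if len(chroms) != len(sizes) or len(chroms) == 0:
            raise BinError("layout needs one positive size per chromosome")
        if any(s <= 0 for s in sizes):
            raise BinError("each chromosome must contain at least one bin")
        if len(set(chroms)) != len(chroms):
            raise BinError("duplicate chromosome names in layout")
        self.chroms = tuple(str(c) for c in chroms)
        self.sizes = tuple(int(s) for s in sizes)
        bin_off = np.concatenate([[0], np.cumsum(self.sizes)])
        delta_off = np.concatenate([[0], np.cumsum([s + 1 for s in self.sizes])])
        self._bin_slices = {
            c: slice(int(bin_off[i]), int(bin_off[i + 1]))
            for i, c in enumerate(self.chroms)
        }
        self._delta_slices = {
            c: slice(int(delta_off[i]), int(delta_off[i + 1]))
            for i, c in enumerate(self.chroms)
        }
        self.n_bins = int(bin_off[-1])
        self.delta_length = int(delta_off[-1])

    @classmethod
    def from_bins(cls, bins: pd.DataFrame) -> "ChromLayout":
        bins = validate_bins(bins)
        chroms = list(dict.fromkeys(bins["chrom"]))
        sizes = [int((bins["chrom"] == c).sum()) for c in chroms]
        return cls(chroms, sizes)

    def bin_slice(self, chrom: str) -> slice:
        return self._bin_slices[chrom]

    def delta_slice(self, chrom: str) -> slice:
        return self._delta_slices[chrom]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ChromLayout)
            and self.chroms == other.chroms
            and self.sizes == other.sizes
        )

    def __hash__(self) -> int:
        return hash((self.chroms, self.sizes))

    def __repr__(self) -> str:
        return f"ChromLayout({dict(zip(self.chroms, self.sizes))})"


def default_bins(layout: ChromLayout, bin_width: int = 1_000_000) -> pd.DataFrame:
    """Evenly spaced synthetic bin coordinates for a layout."""
    rows = []
    for c in layout.chroms:
        m_c = layout.sizes[layout.chroms.index(c)]
        for i in range(m_c):
            rows.append((c, i * bin_width, (i + 1) * bin_width))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass(frozen=True)
class EventRecord:
    """One interval copy number event.

    ``start``/``end`` are 0-based inclusive bin indices *within* ``chrom``;
    ``sign`` is +1 for an amplification and -1 for a deletion.
    """

    chrom: str
    start: int
    end: int
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("event sign must be +1 or -1")
        if not 0 <= self.start <= self.end:
            raise ValueError("event must satisfy 0 <= start <= end")


def _as_int_array(values: Iterable[int]) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind == "f":
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("copy numbers must be integers")
        arr = np.round(arr)
    return arr.astype(np.int64)


class CopyNumberProfile:
    """Integer copy numbers over an ordered set of genomic bins.

    Observed (leaf) profiles are non-negative; ancestral profiles produced by
    the zero-agnostic model may contain negative entries, so negativity is
    only rejected when ``require_nonnegative`` is set (as file readers do).
    """

    def __init__(
        self,
        values: Iterable[int],
        bins: pd.DataFrame,
        *,
        require_nonnegative: bool = False,
    ):
        self.bins = validate_bins(bins)
        self.layout = ChromLayout.from_bins(self.bins)
        self.values = _as_int_array(values)
        if self.values.ndim != 1 or len(self.values) != self.layout.n_bins:
            raise ValueError("profile length must equal the number of bins")
        if require_nonnegative and (self.values < 0).any():
            raise ValueError("observed copy numbers must be non-negative")

    @classmethod
    def from_values(cls, values: Iterable[int], layout: ChromLayout | None = None):
        vals = _as_int_array(values)
        if layout is None:
            layout = ChromLayout(["chr1"], [len(vals)])
        return cls(vals, default_bins(layout))

    def delta(self, baseline: int = DIPLOID_BASELINE) -> "DeltaProfile":
        return delta_map(self, baseline)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CopyNumberProfile)
            and self.layout == other.layout
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"CopyNumberProfile({self.values.tolist()})"


class DeltaProfile:
    """Per-chromosome adjacent-difference vectors obeying the balancing condition."""

    def __init__(self, segments: Mapping[str, Iterable[int]], *, validate: bool = True):
        self.segments = {c: _as_int_array(v) for c, v in segments.items()}
        if validate:
            for c, seg in self.segments.items():
                if seg.sum() != 0:
                    raise BalancingError(
                        f"delta segment for {c!r} sums to {int(seg.sum())}, not 0"
                    )

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.segments)

    def concat(self, layout: ChromLayout | None = None) -> np.ndarray:
        order = layout.chroms if layout is not None else self.chroms
        return np.concatenate([self.segments[c] for c in order])

    def l1_norm(self) -> int:
        return int(sum(np.abs(seg).sum() for seg in self.segments.values()))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DeltaProfile)
            and self.chroms == other.chroms
            and all(np.array_equal(self.segments[c], other.segments[c]) for c in self.chroms)
        )

    def __repr__(self) -> str:
        return f"DeltaProfile({ {c: v.tolist() for c, v in self.segments.items()} })"


# ---------------------------------------------------------------------------
# Array-level delta transforms (used heavily by the solvers)
# ---------------------------------------------------------------------------

def delta_transform(
    values: np.ndarray, layout: ChromLayout, baseline: int = DIPLOID_BASELINE
) -> np.ndarray:
    """Delta map on raw arrays; last axis is bins, output last axis is boundaries.

    Per chromosome segment with bins ``p_0..p_{m-1}`` the output is
    ``(p_0 - baseline, p_1 - p_0, ..., p_{m-1} - p_{m-2}, baseline - p_{m-1})``.
    """
    values = np.asarray(values)
    out = np.empty(values.shape[:-1] + (layout.delta_length,), dtype=np.int64)
    for c in layout.chroms:
        p = values[..., layout.bin_slice(c)]
        q = out[..., layout.delta_slice(c)]
        q[..., 0] = p[..., 0] - baseline
        q[..., 1:-1] = np.diff(p, axis=-1)
        q[..., -1] = baseline - p[..., -1]
    return out


def inverse_delta_transform(
    delta: np.ndarray, layout: ChromLayout, baseline: int = DIPLOID_BASELINE
) -> np.ndarray:
    """Invert :func:`delta_transform` by cumulative summation.

    Raises :class:`BalancingError` if any segment does not sum to zero.
    """
    delta = np.asarray(delta)
    if delta.shape[-1] != layout.delta_length:
        raise ValueError("delta length does not match layout")
    out = np.empty(delta.shape[:-1] + (layout.n_bins,), dtype=np.int64)
    for c in layout.chroms:
        q = delta[..., layout.delta_slice(c)]
        if not (q.sum(axis=-1) == 0).all():
            raise BalancingError(f"delta segment for {c!r} violates the balancing condition")
        out[..., layout.bin_slice(c)] = baseline + np.cumsum(q[..., :-1], axis=-1)
    return out


def delta_map(profile: CopyNumberProfile, baseline: int = DIPLOID_BASELINE) -> DeltaProfile:
    """Map a copy number profile to its delta profile."""
    vec = delta_transform(profile.values, profile.layout, baseline)
    return DeltaProfile(
        {c: vec[profile.layout.delta_slice(c)] for c in profile.layout.chroms}
    )


def inverse_delta_map(
    delta: DeltaProfile,
    layout: ChromLayout | None = None,
    baseline: int = DIPLOID_BASELINE,
    bins: pd.DataFrame | None = None,
) -> CopyNumberProfile:
    """Reconstruct the unique copy number profile of a delta profile."""
    if layout is None:
        layout = ChromLayout(list(delta.chroms), [len(s) - 1 for s in delta.segments.values()])
    vec = delta.concat(layout)
    values = inverse_delta_transform(vec, layout, baseline)
    if bins is None:
        bins = default_bins(layout)
    return CopyNumberProfile(values, bins)


# ---------------------------------------------------------------------------
# Event application
# ---------------------------------------------------------------------------

def apply_cnt_event(profile: CopyNumberProfile, event: EventRecord) -> CopyNumberProfile:
    """Apply an interval event under CNT semantics: zero-copy loci are skipped."""
    values = profile.values.copy()
    sl = profile.layout.bin_slice(event.chrom)
    if event.end >= sl.stop - sl.start:
        raise ValueError("event interval exceeds chromosome length")
    seg = values[sl]
    window = slice(event.start, event.end + 1)
    mask = seg[window] != 0
    seg[window] += event.sign * mask
    return CopyNumberProfile(values, profile.bins)


def apply_zcnt_event(values: np.ndarray | CopyNumberProfile, event: EventRecord,
                     layout: ChromLayout | None = None):
    """Apply an interval event under ZCNT semantics: every covered locus changes.

    Accepts either a :class:`CopyNumberProfile` (returning one) or a raw
    integer vector over a single chromosome / an explicit layout.
    """
    if isinstance(values, CopyNumberProfile):
        new = values.values.copy()
        sl = values.layout.bin_slice(event.chrom)
        if event.end >= sl.stop - sl.start:
            raise ValueError("event interval exceeds chromosome length")
        new[sl][event.start : event.end + 1] += event.sign
        return CopyNumberProfile(new, values.bins)
    arr = _as_int_array(values).copy()
    if layout is None:
        layout = ChromLayout([event.chrom], [len(arr)])
    sl = layout.bin_slice(event.chrom)
    if event.end >= sl.stop - sl.start:
        raise ValueError("event interval exceeds chromosome length")
    arr[sl][event.start : event.end + 1] += event.sign
    return arr


def apply_delta_event(delta: DeltaProfile, event: EventRecord) -> DeltaProfile:
    """Apply the delta-space image of a ZCNT event: q[s] += b, q[t+1] -= b."""
    segments = {c: v.copy() for c, v in delta.segments.items()}
    seg = segments[event.chrom]
    if event.end + 1 >= len(seg):
        raise ValueError("event interval exceeds chromosome length")
    seg[event.start] += event.sign
    seg[event.end + 1] -= event.sign
    return DeltaProfile(segments)


# ---------------------------------------------------------------------------
# Copy number matrices
# ---------------------------------------------------------------------------

class CopyNumberMatrix:
    """An n-cells x m-bins integer copy number matrix with shared bin metadata."""

    def __init__(
        self,
        cells: Sequence[str],
        values: np.ndarray,
        bins: pd.DataFrame,
        *,
        require_nonnegative: bool = True,
    ):
        self.bins = validate_bins(bins)
        self.layout = ChromLayout.from_bins(self.bins)
        self.cells = [str(c) for c in cells]
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell identifiers")
        self.values = _as_int_array(values).reshape(len(self.cells), -1)
        if self.values.shape[1] != self.layout.n_bins:
            raise ValueError("matrix width must equal the number of bins")
        if len(self.cells) < 1:
            raise ValueError("matrix needs at least one cell")
        if require_nonnegative and (self.values < 0).any():
            raise ValueError("observed copy numbers must be non-negative")
        self._index = {c: i for i, c in enumerate(self.cells)}

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_bins(self) -> int:
        return self.layout.n_bins

    @property
    def max_copy(self) -> int:
        return int(self.values.max())

    def profile(self, cell: str | int) -> CopyNumberProfile:
        i = cell if isinstance(cell, int) else self._index[cell]
        return CopyNumberProfile(self.values[i], self.bins)

    def delta_matrix(self, baseline: int = DIPLOID_BASELINE) -> np.ndarray:
        """(n_cells, delta_length) array of concatenated delta segments."""
        return delta_transform(self.values, self.layout, baseline)

    def with_cell(self, name: str, values: Iterable[int]) -> "CopyNumberMatrix":
        vals = np.vstack([self.values, _as_int_array(values)[None, :]])
        return CopyNumberMatrix(self.cells + [name], vals, self.bins)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CopyNumberMatrix)
            and self.cells == other.cells
            and self.layout == other.layout
            and np.array_equal(self.values, other.values)
            and self.bins[["chrom", "start", "end"]].equals(
                other.bins[["chrom", "start", "end"]]
            )
        )

    def __repr__(self) -> str:
        return f"CopyNumberMatrix(n_cells={self.n_cells}, n_bins={self.n_bins})"
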