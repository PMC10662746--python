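"""The ZCNT multiple-median problem.

Given profiles p_1..p_n, find a profile r minimizing the total ZCNT
distance d(r, p_1) + ... + d(r, p_n).  In delta space the objective is a
separable sum of per-coordinate absolute deviations, coupled only by the
balancing condition, which a dynamic program over (prefix length,
prefix discrepancy) handles exactly in O(n m^2 B^2) time per chromosome.

For n = 2 the optimum equals the pairwise distance and is attained by either
input profile; for a single input the median is the input itself.
"""

from __future__ import annotations

import numpy as np

from .profiles import (
    CopyNumberProfile,
    DIPLOID_BASELINE,
    inverse_delta_transform,
)


def zcnt_median(
    profiles: list[CopyNumberProfile], baseline: int = DIPLOID_BASELINE
) -> tuple[CopyNumberProfile, float]:
    """Minimize total ZCNT distance to the inputs.

    Returns the median profile and the total distance in event units.
    Ties in the per-coordinate choice are broken toward the delta value
    nearest zero (the diploid difference), so the median stays as close to
    a flat profile as optimality allows.
    """
    if not profiles:
        raise ValueError("median of an empty profile list")
    layout = profiles[0].layout
    if any(p.layout != layout for p in profiles):
        raise ValueError("profiles must share the same bin structure")
    deltas = np.stack([p.delta(baseline).concat(layout) for p in profiles])  # (n, L)
    B = max(int(max(p.values.max(), 2)) for p in profiles)
    B = max(B, int(np.abs(deltas).max()))
    median_delta = np.empty(layout.delta_length, dtype=np.int64)
    total_l1 = 0.0
    for c in layout.chroms:
        sl = layout.delta_slice(c)
        seg_cost, seg = _median_segment(deltas[:, sl], B)
        total_l1 += seg_cost
        median_delta[sl] = seg
    values = inverse_delta_transform(median_delta, layout, baseline)
    median = CopyNumberProfile(values, profiles[0].bins)
    return median, total_l1 / 2.0


def _tie_order(B: int) -> list[int]:
    order = [0]
    for b in range(1, B + 1):
        order.extend([b, -b])
    return order


def _median_segment(deltas: np.ndarray, B: int) -> tuple[float, np.ndarray]:
    """DP over one chromosome's delta segment.

    ``A[j][k]`` is the minimal summed L1 deviation of a length-j prefix of
    the median's delta segment with prefix sum (discrepancy) k; the answer is
    ``A[L][0]``, forcing the balancing condition.  The empty prefix has
    discrepancy 0 at cost 0 and is otherwise infeasible.
    """
    n, L = deltas.shape
    R = B * L  # discrepancy bound after j <= L steps
    INF = np.inf
    A = np.full(2 * R + 1, INF)
    A[R] = 0.0  # offset encoding: index k + R
    choices = _tie_order(B)
    back = np.zeros((L, 2 * R + 1), dtype=np.int64)
    for j in range(L):
        col_cost = {b: float(np.abs(b - deltas[:, j]).sum()) for b in choices}
        new = np.full(2 * R + 1, INF)
        pick = np.zeros(2 * R + 1, dtype=np.int64)
        for b in choices:
            shifted = np.full(2 * R + 1, INF)
            if b >= 0:
                shifted[b:] = A[: 2 * R + 1 - b] if b else A
            else:
                shifted[:b] = A[-b:]
            cand = shifted + col_cost[b]
            better = cand < new  # strict: earlier (nearer-zero) b wins ties
            new[better] = cand[better]
            pick[better] = b
        A = new
        back[j] = pick
    cost = A[R]
    if not np.isfinite(cost):
        raise RuntimeError("median DP found no balanced solution")
    seg = np.zeros(L, dtype=np.int64)
    k = 0
    for j in range(L - 1, -1, -1):
        b = int(back[j, k + R])
        seg[j] = b
        k -= b
    assert k == 0
    return float(cost), seg
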