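"""Minimum-cost path search for layer boundaries.

A boundary is a row trace across the B-scan whose column-to-column jump
is bounded (smoothness).  The trace minimising the summed per-pixel cost
subject to that bound is found by dynamic programming.  To keep the
result invariant under horizontal mirroring of the image, the selection
combines a forward and a backward sweep: total[r, c] = fwd[r, c] +
bwd[r, c] - cost[r, c] is the cost of the best full path through (r, c),
a quantity independent of sweep direction, and the trace takes the
per-column argmin (smallest row on ties).

Inadmissible cells carry the BIG sentinel rather than inf so the
combined total stays finite and comparable.  The compiled kernel also
restricts the sweep to the row window actually admissible for a trace,
which is what makes whole-cohort segmentation cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1.0e30


@njit(cache=True)
def _banded_trace_kernel(signal, lo, hi, max_jump):
    """Best edge row per column for a signal to be maximised.

    cost[r, c] = -max(signal[r, c], 0) inside [lo[c], hi[c]], BIG
    outside.  Returns (rows, best_total_cost).
    """
    H, W = signal.shape
    cost = np.empty((H, W), dtype=np.float64)
    for c in range(W):
        for r in range(H):
            if lo[c] <= r <= hi[c]:
                s = signal[r, c]
                cost[r, c] = -s if s > 0.0 else 0.0
            else:
                cost[r, c] = BIG

    fwd = np.empty((H, W), dtype=np.float64)
    bwd = np.empty((H, W), dtype=np.float64)
    for r in range(H):
        fwd[r, 0] = cost[r, 0]
        bwd[r, W - 1] = cost[r, W - 1]
    for c in range(1, W):
        for r in range(H):
            a = r - max_jump
            if a < 0:
                a = 0
            b = r + max_jump
            if b > H - 1:
                b = H - 1
            best_f = fwd[a, c - 1]
            best_b = bwd[a, W - c]
            for rr in range(a + 1, b + 1):
                vf = fwd[rr, c - 1]
                if vf < best_f:
                    best_f = vf
                vb = bwd[rr, W - c]
                if vb < best_b:
                    best_b = vb
            fwd[r, c] = cost[r, c] + best_f
            bwd[r, W - 1 - c] = cost[r, W - 1 - c] + best_b

    rows = np.empty(W, dtype=np.int64)
    for c in range(W):
        best = BIG * 4.0
        arg = 0
        for r in range(H):
            t = fwd[r, c] + bwd[r, c] - cost[r, c]
            if t < best:
                best = t
                arg = r
        rows[c] = arg
    best0 = fwd[rows[0], 0] + bwd[rows[0], 0] - cost[rows[0], 0]
    return rows, best0


def banded_min_cost_trace(
    signal: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    max_jump: int = 3,
) -> tuple[np.ndarray, float]:
    """Best-path row per column maximising ``signal`` within per-column
    admissible bands [lo, hi] (inclusive, integer rows).

    The sweep is confined to the global row window [min(lo), max(hi)];
    results are identical to a full-height sweep because rows outside
    that window are inadmissible for every column.
    """
    signal = np.ascontiguousarray(signal, dtype=np.float64)
    H, W = signal.shape
    lo = np.clip(np.asarray(lo, dtype=np.int64), 0, H - 1)
    hi = np.clip(np.asarray(hi, dtype=np.int64), 0, H - 1)
    rmin = int(lo.min())
    rmax = int(hi.max())
    if rmin > rmax:
        return np.zeros(W, dtype=np.int64), BIG * 4.0
    window = signal[rmin : rmax + 1]
    rows, best = _banded_trace_kernel(
        np.ascontiguousarray(window), lo - rmin, hi - rmin, int(max_jump)
    )
    return rows + rmin, float(best)


def min_cost_trace(cost: np.ndarray, max_jump: int = 3) -> tuple[np.ndarray, float]:
    """Direction-symmetric min-cost trace of an explicit cost matrix.

    Convenience wrapper over the same kernel (signal = -cost, open band);
    used directly in tests against the pure-numpy reference below.
    """
    cost = np.ascontiguousarray(cost, dtype=np.float64)
    H, W = cost.shape
    # The kernel clamps negative signal to zero cost, so shift the whole
    # matrix to make every cost strictly representable as -signal.
    shift = float(cost.max()) + 1.0
    signal = shift - cost
    lo = np.zeros(W, dtype=np.int64)
    hi = np.full(W, H - 1, dtype=np.int64)
    rows, best = _banded_trace_kernel(signal, lo, hi, int(max_jump))
    return rows, float(best + shift * W)


def dp_sweep_ref(cost: np.ndarray, max_jump: int) -> np.ndarray:
    """Pure-numpy forward DP table (cross-checks the compiled kernel)."""
    from scipy.ndimage import minimum_filter1d

    cost = np.asarray(cost, dtype=np.float64)
    D = np.empty_like(cost)
    D[:, 0] = cost[:, 0]
    for c in range(1, cost.shape[1]):
        D[:, c] = cost[:, c] + minimum_filter1d(
            D[:, c - 1], size=2 * max_jump + 1, mode="nearest"
        )
    return D


def min_cost_trace_ref(cost: np.ndarray, max_jump: int = 3) -> tuple[np.ndarray, float]:
    """Pure-numpy reference for min_cost_trace (fwd+bwd selection)."""
    cost = np.asarray(cost, dtype=np.float64)
    fwd = dp_sweep_ref(cost, max_jump)
    bwd = dp_sweep_ref(cost[:, ::-1], max_jump)[:, ::-1]
    total = fwd + bwd - cost
    rows = np.argmin(total, axis=0)
    return rows.astype(np.int64), float(total[rows[0], 0])
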