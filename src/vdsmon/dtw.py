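"""Dynamic time warping between velocity sequences.

Plain table DTW: the cumulative cost D(i, j) of aligning prefixes of two
sequences is filled by

    D(i, j) = min over allowed predecessors + d(a_i, b_j)

and the warping path is recovered by backtracking from the final cell.
Two local step sets are supported:

``standard_a``
    predecessors {(i, j−1), (i−1, j), (i−1, j−1)} — the classic
    symmetric step set.
``extended_b``
    Itakura-style predecessors {(i−1, j−1), (i−2, j−1), (i−1, j−2)};
    every step advances both indices, which bounds the local slope to
    [1/2, 2].  Under the standard boundary this step set cannot align
    sequences whose lengths differ by more than a factor of two; the
    distance is then ``inf`` with an empty path.

Two boundary rules are supported:

``standard``
    a single virtual zero-cost origin just outside the table at
    (−1, −1) (0-based); first row and column accumulate cost.
``paper_literal``
    every cell outside the table has value 0, which lets a path start
    anywhere on the table border and skip prefixes of either sequence
    for free.  Kept as a documented variant; note that D(a, a) = 0 then
    no longer holds in general.

Path index pairs are 0-based, running from the start cell to
(M−1, N−1).  The local cost d is a scalar distance between speed values:
absolute difference by default, squared difference optionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

__all__ = ["DTWConfig", "DTWResult", "dtw_distance", "dtw_local_cost", "dtw_distance_matrix"]

_CONSTRAINTS = ("standard_a", "extended_b")
_BOUNDARIES = ("standard", "paper_literal")
_COSTS = ("absolute", "squared")

# predecessor offsets, in backtracking tie-break priority order
_STEPS = {
    "standard_a": ((-1, -1), (-1, 0), (0, -1)),
    "extended_b": ((-1, -1), (-2, -1), (-1, -2)),
}


@dataclass(frozen=True)
class DTWConfig:
    constraint: str = "standard_a"
    boundary: str = "standard"
    local_cost: str = "absolute"

    def __post_init__(self) -> None:
        if self.constraint not in _CONSTRAINTS:
            raise ValueError(f"constraint must be one of {_CONSTRAINTS}, got {self.constraint!r}")
        if self.boundary not in _BOUNDARIES:
            raise ValueError(f"boundary must be one of {_BOUNDARIES}, got {self.boundary!r}")
        if self.local_cost not in _COSTS:
            raise ValueError(f"local_cost must be one of {_COSTS}, got {self.local_cost!r}")


@dataclass
class DTWResult:
    distance: float
    path: list[tuple[int, int]]


def dtw_local_cost(x: float, y: float, cfg: DTWConfig | None = None) -> float:
    """Scalar matching cost between two speed values."""
    cfg = cfg or DTWConfig()
    d = float(x) - float(y)
    return d * d if cfg.local_cost == "squared" else abs(d)


def _fill_impl(a, b, extended, literal, squared):  # pragma: no cover - jitted
    M = a.shape[0]
    N = b.shape[0]
    D = np.empty((M, N), dtype=np.float64)
    for i in range(M):
        for j in range(N):
            diff = a[i] - b[j]
            if squared:
                d = diff * diff
            else:
                d = diff if diff >= 0.0 else -diff
            best = np.inf
            for s in range(3):
                if extended:
                    if s == 0:
                        pi, pj = i - 1, j - 1
                    elif s == 1:
                        pi, pj = i - 2, j - 1
                    else:
                        pi, pj = i - 1, j - 2
                else:
                    if s == 0:
                        pi, pj = i - 1, j - 1
                    elif s == 1:
                        pi, pj = i - 1, j
                    else:
                        pi, pj = i, j - 1
                if pi >= 0 and pj >= 0:
                    v = D[pi, pj]
                elif literal:
                    v = 0.0
                elif pi == -1 and pj == -1:
                    v = 0.0
                else:
                    v = np.inf
                if v < best:
                    best = v
            D[i, j] = best + d
    return D


_fill = njit(cache=False)(_fill_impl) if njit is not None else _fill_impl


def _as_values(seq) -> np.ndarray:
    values = getattr(seq, "values", seq)
    arr = np.asarray(values, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("DTW requires non-empty sequences")
    return arr


def _border_value(pi: int, pj: int, literal: bool) -> float:
    if literal:
        return 0.0
    if pi == -1 and pj == -1:
        return 0.0
    return np.inf


def dtw_distance(a, b, cfg: DTWConfig | None = None) -> DTWResult:
    """DTW distance and one optimal warping path.

    ``a`` and ``b`` may be :class:`~vdsmon.features.VelocitySequence`
    objects or plain 1-D arrays.  Backtracking tie-breaks prefer the
    diagonal predecessor, then the vertical, then the horizontal one, so
    the returned path is deterministic.
    """
    cfg = cfg or DTWConfig()
    av, bv = _as_values(a), _as_values(b)
    extended = cfg.constraint == "extended_b"
    literal = cfg.boundary == "paper_literal"
    squared = cfg.local_cost == "squared"
    D = _fill(av, bv, extended, literal, squared)
    dist = float(D[-1, -1])
    if not np.isfinite(dist):
        return DTWResult(dist, [])

    steps = _STEPS[cfg.constraint]
    path = [(len(av) - 1, len(bv) - 1)]
    i, j = path[0]
    while True:
        d_here = dtw_local_cost(av[i], bv[j], cfg)
        chosen = None
        for di, dj in steps:
            pi, pj = i + di, j + dj
            if pi >= 0 and pj >= 0:
                pred_val = D[pi, pj]
            else:
                pred_val = _border_value(pi, pj, literal)
            if np.isfinite(pred_val) and abs(pred_val + d_here - D[i, j]) <= 1e-9 * max(1.0, abs(D[i, j])):
                chosen = (pi, pj)
                break
        if chosen is None:  # should not happen for a finite table
            raise RuntimeError("backtracking failed to find a consistent predecessor")
        if chosen[0] < 0 or chosen[1] < 0:
            break  # reached a virtual border cell: the path starts here
        path.append(chosen)
        i, j = chosen
    path.reverse()
    return DTWResult(dist, path)


def dtw_distance_matrix(
    seqs_a,
    seqs_b=None,
    cfg: DTWConfig | None = None,
    length_normalize: bool = False,
) -> np.ndarray:
    """Pairwise DTW distances (no paths), optionally divided by M + N.

    With ``seqs_b=None`` the matrix is symmetric and only the upper
    triangle is computed.  Length normalization puts distances between
    sequences of different lengths on a common per-step scale.
    """
    cfg = cfg or DTWConfig()
    A = [_as_values(s) for s in seqs_a]
    extended = cfg.constraint == "extended_b"
    literal = cfg.boundary == "paper_literal"
    squared = cfg.local_cost == "squared"

    def one(x, y):
        d = float(_fill(x, y, extended, literal, squared)[-1, -1])
        if length_normalize:
            d /= len(x) + len(y)
        return d

    if seqs_b is None:
        n = len(A)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                out[i, j] = out[j, i] = one(A[i], A[j])
        return out
    B = [_as_values(s) for s in seqs_b]
    out = np.empty((len(A), len(B)))
    for i, x in enumerate(A):
        for j, y in enumerate(B):
            out[i, j] = one(x, y)
    return out
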