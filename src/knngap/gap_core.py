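"""Distance-difference statistics and the skewness curve over candidate sizes.

For each cell the sorted neighbour-distance curve D[m, k] is differenced once
(delta) and twice (ddelta); a planted cluster of size n produces a sharp
positive ddelta peak at k = n for exactly its member cells.  Per candidate
size k, the distribution of neighbour-smoothed ddelta values — Tukey-fenced
and augmented with the averaged value of the hypothetical rare group — is
summarised by its skewness; sizes whose skewness exceeds the threshold become
candidates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import NeighborTable

log = logging.getLogger(__name__)

FENCE_MODES = ("conventional", "as_printed")


@dataclass
class GapProfile:
    """First/second differences of the neighbour-distance curves.

    delta columns cover k = 1..K (with D[m, 0] := 0); ddelta and
    ddelta_smooth columns cover k = 2..K-1.
    """

    delta: np.ndarray
    ddelta: np.ndarray
    ddelta_smooth: np.ndarray

    @property
    def K(self) -> int:
        return self.delta.shape[1]


@dataclass
class SkewnessCurve:
    """skewness_<k> per candidate size k = 2..K-1 with threshold flags."""

    ks: np.ndarray
    skew: np.ndarray
    threshold: float
    candidate_k: np.ndarray
    per_k_top_cell: np.ndarray

    def __post_init__(self) -> None:
        self.ks = np.asarray(self.ks, dtype=np.int64)
        self.skew = np.asarray(self.skew, dtype=np.float64)
        self.candidate_k = np.asarray(self.candidate_k, dtype=np.int64)
        self.per_k_top_cell = np.asarray(self.per_k_top_cell, dtype=np.int64)
        expected = self.ks[self.skew > self.threshold]
        if not np.array_equal(np.sort(self.candidate_k), np.sort(expected)):
            raise ValueError("candidate_k must equal {k : skew[k] > threshold}")

    def skew_at(self, k: int) -> float:
        return float(self.skew[int(k) - int(self.ks[0])])

    def top_cell_at(self, k: int) -> int:
        return int(self.per_k_top_cell[int(k) - int(self.ks[0])])


def first_difference(nbrs: NeighborTable) -> np.ndarray:
    """delta[m, k] = D[m, k] - D[m, k-1] with D[m, 0] := 0 (columns k=1..K)."""
    return np.diff(nbrs.D, axis=1, prepend=0.0)


def second_difference(delta: np.ndarray) -> np.ndarray:
    """ddelta[m, k] = 2 delta[m, k] - delta[m, k-1] - delta[m, k+1], k=2..K-1."""
    delta = np.asarray(delta, dtype=np.float64)
    if delta.shape[1] < 4:
        raise ValueError("K too small for second difference (need K >= 4)")
    return 2.0 * delta[:, 1:-1] - delta[:, :-2] - delta[:, 2:]


def smooth_by_neighbor(ddelta: np.ndarray, nbrs: NeighborTable) -> np.ndarray:
    """Average each cell's ddelta row with its nearest neighbour's row."""
    ddelta = np.asarray(ddelta, dtype=np.float64)
    if ddelta.shape[0] != nbrs.N:
        raise ValueError("ddelta rows must match the neighbour table")
    return 0.5 * (ddelta + ddelta[nbrs.neighbor_index[:, 0]])


def gap_profile(nbrs: NeighborTable) -> GapProfile:
    """Convenience: delta, ddelta and neighbour-smoothed ddelta in one go."""
    delta = first_difference(nbrs)
    ddelta = second_difference(delta)
    return GapProfile(
        delta=delta, ddelta=ddelta, ddelta_smooth=smooth_by_neighbor(ddelta, nbrs)
    )


def skewness(values) -> float:
    """Type-3 sample skewness: g1 * ((n-1)/n)^(3/2)."""
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    if n < 3:
        raise ValueError("skewness requires at least 3 values")
    centred = x - x.mean()
    m2 = np.mean(centred**2)
    scale = max(1.0, float(np.abs(x).max()))
    if m2 <= (1e-12 * scale) ** 2:  # constant up to float rounding
        log.warning("skewness: zero variance, returning 0")
        return 0.0
    g1 = np.mean(centred**3) / m2**1.5
    return float(g1 * ((n - 1) / n) ** 1.5)


def skewness_at_k(
    ddelta_smooth: np.ndarray,
    nbrs: NeighborTable,
    k: int,
    fence_mode: str = "conventional",
) -> float:
    """Skewness of the fenced, rare-augmented smoothed-ddelta values at size k.

    Steps: (a) take the N smoothed values at this k and identify the top cell
    (ties to the smaller index); (b) drop the k largest values; (c) keep the
    remainder inside the Tukey fences as the abundant set; (d) average the
    smoothed values of the top cell and its k-1 nearest neighbours; (e) append
    two copies of that average; (f) return the skewness of the combined
    vector.
    """
    if fence_mode not in FENCE_MODES:
        raise ValueError(f"fence_mode must be one of {FENCE_MODES}")
    K = nbrs.K
    if not 2 <= k <= K - 1:
        raise ValueError(f"k must satisfy 2 <= k <= K-1, got {k}")
    col = np.asarray(ddelta_smooth, dtype=np.float64)[:, k - 2]
    n = col.size

    top_cell = int(np.argmax(col))  # first occurrence -> smaller index on ties
    rest = np.partition(col, n - k)[: n - k]  # all but the k largest values

    q1, q3 = np.percentile(rest, [25.0, 75.0])  # linear interpolation
    iqr = q3 - q1
    lo = q1 + 1.5 * iqr if fence_mode == "as_printed" else q1 - 1.5 * iqr
    abundant = rest[(rest >= lo) & (rest <= q3 + 1.5 * iqr)]
    if abundant.size < 3:
        log.warning("skewness_at_k(k=%d): abundant set smaller than 3, returning 0", k)
        return 0.0

    members = np.concatenate(([top_cell], nbrs.neighbor_index[top_cell, : k - 1]))
    r = float(col[members].mean())
    return skewness(np.concatenate((abundant, [r, r])))


def candidates_from(ks: np.ndarray, skew: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold rule: candidate sizes are exactly {k : skew[k] > threshold}."""
    ks = np.asarray(ks, dtype=np.int64)
    return ks[np.asarray(skew, dtype=np.float64) > threshold]


def build_skewness_curve(
    ddelta_smooth: np.ndarray,
    nbrs: NeighborTable,
    threshold: float = 2.0,
    fence_mode: str = "conventional",
) -> SkewnessCurve:
    """skewness_at_k for every k in 2..K-1, with candidate flags and top cells."""
    ddelta_smooth = np.asarray(ddelta_smooth, dtype=np.float64)
    ks = np.arange(2, nbrs.K)
    skew = np.empty(ks.size)
    top = np.empty(ks.size, dtype=np.int64)
    for i, k in enumerate(ks):
        skew[i] = skewness_at_k(ddelta_smooth, nbrs, int(k), fence_mode=fence_mode)
        top[i] = int(np.argmax(ddelta_smooth[:, k - 2]))
    return SkewnessCurve(
        ks=ks,
        skew=skew,
        threshold=float(threshold),
        candidate_k=candidates_from(ks, skew, threshold),
        per_k_top_cell=top,
    )
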