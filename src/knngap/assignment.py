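"""Convert the skewness curve into confirmed rare clusters and cell scores.

Each candidate size k nominates the top-ddelta cell and its k-1 nearest
neighbours; cells keep only their strongest nomination, and a size is
confirmed only when exactly k cells end up carrying it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gap_core import SkewnessCurve
from .preprocess import NeighborTable

log = logging.getLogger(__name__)


@dataclass
class RareCluster:
    size_k: int
    member_cells: np.ndarray  # cell indices, sorted
    skewness_value: float
    top_cell: int

    def __post_init__(self) -> None:
        self.member_cells = np.sort(np.asarray(self.member_cells, dtype=np.int64))
        if self.member_cells.size != self.size_k:
            raise ValueError("|member_cells| must equal size_k")
        if self.top_cell not in self.member_cells:
            raise ValueError("top_cell must be a member of the cluster")


@dataclass
class RareCellResult:
    clusters: list
    per_cell_label: np.ndarray  # cluster id ("R1", ...) or "" for none
    per_cell_score: np.ndarray
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.per_cell_label = np.asarray(self.per_cell_label, dtype=object)
        self.per_cell_score = np.asarray(self.per_cell_score, dtype=np.float64)
        seen: set[int] = set()
        for c in self.clusters:
            members = set(int(m) for m in c.member_cells)
            if members & seen:
                raise ValueError("cluster memberships must be disjoint")
            seen |= members
        if np.any(self.per_cell_score < 0):
            raise ValueError("scores must be >= 0")

    @property
    def rare_cells(self) -> np.ndarray:
        """Indices of all confirmed rare cells, across clusters."""
        if not self.clusters:
            return np.empty(0, dtype=np.int64)
        return np.sort(np.concatenate([c.member_cells for c in self.clusters]))


def per_cell_score(ddelta_smooth: np.ndarray, curve: SkewnessCurve) -> np.ndarray:
    """Continuous rarity score: each cell's largest smoothed ddelta over the
    candidate sizes (over all sizes when there is no candidate), floored at 0.

    A stated substitute — the source method reports continuous scores without
    giving a formula.
    """
    ddelta_smooth = np.asarray(ddelta_smooth, dtype=np.float64)
    if curve.candidate_k.size:
        cols = curve.candidate_k - int(curve.ks[0])
        best = ddelta_smooth[:, cols].max(axis=1)
    else:
        best = ddelta_smooth.max(axis=1)
    return np.maximum(best, 0.0)


def assign_rare_cells(
    curve: SkewnessCurve,
    nbrs: NeighborTable,
    ddelta_smooth: np.ndarray,
    parameters: dict | None = None,
) -> RareCellResult:
    """Resolve candidate sizes into confirmed rare clusters.

    For each candidate k the top cell at k plus its k-1 nearest neighbours are
    provisionally tagged with skewness_<k>.  A cell keeps the tag with the
    largest skewness (ties to the smaller k).  k is confirmed iff exactly k
    cells keep it.
    """
    ddelta_smooth = np.asarray(ddelta_smooth, dtype=np.float64)
    N = nbrs.N
    best_skew = np.full(N, -np.inf)
    best_k = np.zeros(N, dtype=np.int64)
    for k in np.sort(curve.candidate_k):
        k = int(k)
        t = curve.top_cell_at(k)
        members = np.concatenate(([t], nbrs.neighbor_index[t, : k - 1]))
        s = curve.skew_at(k)
        take = s > best_skew[members]  # ties keep the earlier (smaller) k
        idx = members[take]
        best_skew[idx] = s
        best_k[idx] = k

    clusters = []
    labels = np.full(N, "", dtype=object)
    for k in np.sort(np.unique(best_k[best_k > 0])):
        labelled = np.flatnonzero(best_k == k)
        if labelled.size != k:
            log.info("size k=%d not confirmed: %d cells labelled", k, labelled.size)
            continue
        cid = f"R{len(clusters) + 1}"
        labels[labelled] = cid
        clusters.append(
            RareCluster(
                size_k=int(k),
                member_cells=labelled,
                skewness_value=curve.skew_at(int(k)),
                top_cell=curve.top_cell_at(int(k)),
            )
        )
    return RareCellResult(
        clusters=clusters,
        per_cell_label=labels,
        per_cell_score=per_cell_score(ddelta_smooth, curve),
        parameters=dict(parameters or {}),
    )


def run_iterative(*args, **kwargs):
    """Iterative rerun with confirmed rare cells removed (see knngap.pipeline)."""
    from .pipeline import run_iterative as _impl

    return _impl(*args, **kwargs)
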