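"""Preprocessing: filtering, normalisation, feature selection, embedding, kNN.

Turns a raw gene-by-cell count matrix into a low-dimensional embedding and an
exact K-nearest-neighbour table, the substrate for the distance-gap
statistics downstream.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)

#: distance names accepted by the pipeline -> scipy cdist metric names
METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}


def _labels(values, what: str) -> np.ndarray:
    arr = np.asarray([str(v) for v in values], dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    if len(set(arr)) != arr.size:
        raise ValueError(f"duplicate {what} are not allowed")
    return arr


@dataclass
class CountMatrix:
    """Raw gene x cell non-negative integer counts with identifiers."""

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        counts = self.counts
        if sp.issparse(counts):
            counts = counts.toarray()
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene x cell matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)):
                raise ValueError("counts must be finite")
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.gene_ids = _labels(self.gene_ids, "gene_ids")
        self.cell_ids = _labels(self.cell_ids, "cell_ids")
        if counts.shape != (self.gene_ids.size, self.cell_ids.size):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{self.gene_ids.size} genes x {self.cell_ids.size} cells"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedMatrix:
    """log2(median-normalised counts + 1) values with the size-factor record."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    normalization_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D gene x cell matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("normalised values must be finite")
        if values.size and values.min() < 0:
            raise ValueError("normalised values must be non-negative")
        self.values = values
        self.gene_ids = _labels(self.gene_ids, "gene_ids")
        self.cell_ids = _labels(self.cell_ids, "cell_ids")
        if values.shape != (self.gene_ids.size, self.cell_ids.size):
            raise ValueError("values shape does not match labels")

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureSet:
    """Genes ranked by decreasing standardized variance, cut at the elbow."""

    selected_gene_ids: np.ndarray
    standardized_variance: np.ndarray
    elbow_index: int

    def __post_init__(self) -> None:
        self.selected_gene_ids = _labels(self.selected_gene_ids, "selected_gene_ids")
        sv = np.asarray(self.standardized_variance, dtype=np.float64)
        if sv.size != self.selected_gene_ids.size:
            raise ValueError("standardized_variance length mismatch")
        if np.any(sv < 0) or np.any(np.diff(sv) > 1e-12):
            raise ValueError("standardized_variance must be non-negative and non-increasing")
        self.standardized_variance = sv
        if not 1 <= self.elbow_index:
            raise ValueError("elbow_index must be >= 1")


@dataclass
class Embedding:
    """Cell x P principal-component coordinates."""

    coordinates: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=np.float64)
        if coords.ndim != 2 or not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be a finite 2-D cell x P matrix")
        ev = np.asarray(self.explained_variance, dtype=np.float64)
        if ev.size != coords.shape[1] or np.any(ev < -1e-12):
            raise ValueError("explained_variance must be per-component and >= 0")
        if np.any(np.diff(ev) > 1e-9 * max(1.0, abs(ev[0]) if ev.size else 1.0)):
            raise ValueError("explained_variance must be non-increasing")
        self.coordinates = coords
        self.explained_variance = ev

    @property
    def n_cells(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class NeighborTable:
    """Per-cell sorted neighbour distances D[m, k] and indices, k = 1..K."""

    K: int
    neighbor_index: np.ndarray
    D: np.ndarray
    metric: str
    N: int

    def __post_init__(self) -> None:
        self.neighbor_index = np.asarray(self.neighbor_index, dtype=np.int64)
        self.D = np.asarray(self.D, dtype=np.float64)
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {sorted(METRICS)}")
        if self.neighbor_index.shape != (self.N, self.K) or self.D.shape != (self.N, self.K):
            raise ValueError("neighbour tables must be N x K")
        if not 2 <= self.K <= self.N - 1:
            raise ValueError(f"K must satisfy 2 <= K <= N-1, got K={self.K}, N={self.N}")
        if np.any(self.D < 0) or not np.all(np.isfinite(self.D)):
            raise ValueError("distances must be finite and non-negative")
        if np.any(np.diff(self.D, axis=1) < -1e-12):
            raise ValueError("D[m, .] must be non-decreasing in k")
        if np.any(self.neighbor_index == np.arange(self.N)[:, None]):
            raise ValueError("a cell may not be its own neighbour")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_counts(
    raw: CountMatrix, min_cells_per_gene: int = 3, min_genes_per_cell: int = 200
) -> CountMatrix:
    """Drop rarely-expressed genes, then sparsely-expressing cells.

    Single pass: the gene filter is applied first, then the cell filter; the
    gene filter is not re-applied afterwards.
    """
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("filter thresholds must be >= 0")
    expressed = raw.counts > 0
    gene_mask = expressed.sum(axis=1) >= min_cells_per_gene
    if not gene_mask.any():
        raise ValueError(
            f"no genes survive filtering at min_cells_per_gene={min_cells_per_gene}"
        )
    cell_mask = expressed[gene_mask].sum(axis=0) >= min_genes_per_cell
    if not cell_mask.any():
        raise ValueError(
            f"no cells survive filtering at min_genes_per_cell={min_genes_per_cell}"
        )
    log.info(
        "filter_counts: %d/%d genes, %d/%d cells retained",
        gene_mask.sum(), raw.n_genes, cell_mask.sum(), raw.n_cells,
    )
    return CountMatrix(
        counts=raw.counts[np.ix_(gene_mask, cell_mask)],
        gene_ids=raw.gene_ids[gene_mask],
        cell_ids=raw.cell_ids[cell_mask],
    )


def median_normalize(filtered: CountMatrix) -> NormalizedMatrix:
    """Global median normalisation followed by log2(x + 1).

    The size factor of cell j is total_j / median(totals); values are
    log2(count / size_factor + 1).
    """
    totals = filtered.counts.sum(axis=0, dtype=np.float64)
    if np.any(totals <= 0):
        bad = filtered.cell_ids[np.flatnonzero(totals <= 0)[0]]
        raise ValueError(
            f"cell {bad!r} has zero total count; it should have been removed by filter_counts"
        )
    size_factors = totals / np.median(totals)
    values = filtered.counts / size_factors[None, :]
    np.log1p(values, out=values)
    values *= 1.0 / math.log(2.0)
    return NormalizedMatrix(
        values=values,
        gene_ids=filtered.gene_ids,
        cell_ids=filtered.cell_ids,
        normalization_record={"method": "median", "size_factors": size_factors},
    )


def lognorm_identity(filtered: CountMatrix, assume_logged: bool = True) -> NormalizedMatrix:
    """Wrap pre-normalised input without touching the values (--no-normalize)."""
    return NormalizedMatrix(
        values=np.asarray(filtered.counts, dtype=np.float64),
        gene_ids=filtered.gene_ids,
        cell_ids=filtered.cell_ids,
        normalization_record={
            "method": "none",
            "size_factors": np.ones(filtered.n_cells),
        },
    )


def elbow_point(sorted_values: np.ndarray) -> int:
    """Index of the knee of a descending curve: the 0-based position with the
    maximum perpendicular distance to the chord joining its endpoints.

    The returned index doubles as the count of points retained before the
    knee, so it is always >= 1.
    """
    y = np.asarray(sorted_values, dtype=np.float64)
    n = y.size
    if n < 3:
        return max(1, n - 1)
    x = np.arange(n, dtype=np.float64)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = math.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    return max(1, int(np.argmax(dist)))


def _vst_trend(log_mean: np.ndarray, log_var: np.ndarray) -> np.ndarray:
    """Fitted log10-variance trend; lowess with a quadratic-polynomial fallback."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    delta = 0.005 * float(np.ptp(log_mean)) if log_mean.size > 1500 else 0.0
    fitted = lowess(log_var, log_mean, frac=0.3, delta=delta, return_sorted=False)
    if not np.all(np.isfinite(fitted)):
        coef = np.polyfit(log_mean, log_var, deg=2)
        fitted = np.polyval(coef, log_mean)
        log.warning("vst trend: lowess fit degenerate, fell back to quadratic polynomial")
    return fitted


def vst_select_features(
    norm: NormalizedMatrix,
    raw: CountMatrix,
    min_features: int = 500,
    max_features: int = 5000,
) -> FeatureSet:
    """Variance-stabilising feature selection on raw counts.

    Fits a lowess trend (span 0.3) of log10 variance on log10 mean,
    standardises each gene's counts by the trend-predicted standard deviation
    with an upper clip at sqrt(N), ranks genes by the variance of the clipped
    values, and cuts the ranking at the elbow of the sorted curve (bounded to
    [min_features, max_features]).
    """
    if not np.array_equal(norm.gene_ids, raw.gene_ids):
        raise ValueError("norm and raw must carry the same genes in the same order")
    counts = np.asarray(raw.counts, dtype=np.float64)
    n_genes, n_cells = counts.shape
    if n_cells < 2:
        raise ValueError("feature selection requires at least 2 cells")
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    pos = var > 0
    n_pos = int(pos.sum())
    if n_pos < 2:
        raise ValueError("fewer than 2 genes with positive variance")

    fitted = _vst_trend(np.log10(mean[pos]), np.log10(var[pos]))
    sd_expected = np.sqrt(np.power(10.0, fitted))
    clip = math.sqrt(n_cells)

    # standardized variance about zero of the clipped z-scores, chunked to
    # keep memory flat on large matrices
    std_var = np.zeros(n_genes)
    pos_idx = np.flatnonzero(pos)
    for start in range(0, n_pos, 2048):
        sel = pos_idx[start : start + 2048]
        z = (counts[sel] - mean[sel, None]) / sd_expected[start : start + 2048, None]
        np.minimum(z, clip, out=z)
        std_var[sel] = np.sum(z * z, axis=1)
    std_var /= n_cells - 1
    std_var = np.maximum(std_var, 0.0)

    order = np.argsort(-std_var, kind="stable")[:n_pos]
    sorted_var = std_var[order]
    if n_pos < min_features:
        log.warning(
            "vst_select_features: only %d genes with positive variance "
            "(< lower bound %d); keeping all of them", n_pos, min_features,
        )
        n_keep = n_pos
    else:
        raw_elbow = elbow_point(sorted_var)
        n_keep = min(max(raw_elbow, min_features), max_features, n_pos)
    return FeatureSet(
        selected_gene_ids=raw.gene_ids[order[:n_keep]],
        standardized_variance=sorted_var[:n_keep],
        elbow_index=n_keep,
    )


def pca_embed(
    norm: NormalizedMatrix,
    features: FeatureSet,
    n_components: int = 50,
    seed: int = 1,
) -> Embedding:
    """Centred, unit-variance-scaled PCA scores of the selected-gene submatrix.

    Component signs are fixed by making the largest-magnitude loading of each
    component positive.
    """
    from sklearn.decomposition import PCA

    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    if features.selected_gene_ids.size == 0:
        raise ValueError("feature set is empty")
    index = {g: i for i, g in enumerate(norm.gene_ids)}
    try:
        rows = np.array([index[g] for g in features.selected_gene_ids])
    except KeyError as exc:
        raise ValueError(f"feature gene {exc} absent from normalised matrix") from exc

    X = norm.values[rows].T.astype(np.float64)  # cells x genes
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all selected genes are constant across cells")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    n_cells, n_feats = X.shape
    cap = min(n_cells - 1, n_feats)
    if n_components > cap:
        log.warning("pca_embed: clamping n_components from %d to %d", n_components, cap)
        n_components = cap
    solver = "full" if min(n_cells, n_feats) < 500 else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_components), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    return Embedding(coordinates=scores * flip[None, :], explained_variance=pca.explained_variance_)


def default_k(n_cells: int) -> int:
    """Default neighbour count: min(max(50, ceil(0.05 N)) + 10, N - 1)."""
    return min(max(50, math.ceil(0.05 * n_cells)) + 10, n_cells - 1)


def knn_search(emb: Embedding, K: int | None = None, metric: str = "euclidean") -> NeighborTable:
    """Exact K-nearest-neighbour search on the embedding.

    Brute force in chunks; distance ties are broken towards the smaller cell
    index for determinism.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}")
    X = emb.coordinates
    N = X.shape[0]
    if K is None:
        K = default_k(N)
    if not 2 <= K <= N - 1:
        raise ValueError(f"K must satisfy 2 <= K <= N-1 (N={N}), got {K}")

    nbr = np.empty((N, K), dtype=np.int64)
    dist = np.empty((N, K), dtype=np.float64)
    chunk = max(1, int(2.5e7 // max(N, 1)))
    use_partition = N > 5000
    pad = min(N, K + 16)
    for start in range(0, N, chunk):
        stop = min(start + chunk, N)
        d = cdist(X[start:stop], X, metric=METRICS[metric])
        d[np.arange(stop - start), np.arange(start, stop)] = np.inf
        if use_partition:
            part = np.argpartition(d, pad - 1, axis=1)[:, :pad]
            dp = np.take_along_axis(d, part, axis=1)
            for i in range(stop - start):
                o = np.lexsort((part[i], dp[i]))[:K]
                nbr[start + i] = part[i][o]
                dist[start + i] = dp[i][o]
        else:
            order = np.argsort(d, axis=1, kind="stable")[:, :K]
            nbr[start:stop] = order
            dist[start:stop] = np.take_along_axis(d, order, axis=1)
    return NeighborTable(K=K, neighbor_index=nbr, D=dist, metric=metric, N=N)
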