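"""End-to-end orchestration: filter -> normalise -> vst -> PCA -> kNN ->
gap statistics -> skewness curve -> assignment, plus the iterative rerun."""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import assignment as _assignment
from . import gap_core, preprocess
from .preprocess import CountMatrix

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved run settings; defaults reproduce the reference settings."""

    input_path: str | None = None
    dialect: str = "auto"
    cells_in_rows: bool = False
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    normalization: str = "median"  # median | none
    min_features: int = 500
    max_features: int = 5000
    n_pcs: int = 50
    k_max: int | None = None
    metric: str = "euclidean"
    skew_threshold: float = 2.0
    fence_mode: str = "conventional"
    seed: int = 1
    out_dir: str | None = None
    rounds: int = 1

    def __post_init__(self) -> None:
        if self.normalization not in ("median", "none"):
            raise ValueError("normalization must be 'median' or 'none'")
        if self.metric not in preprocess.METRICS:
            raise ValueError(f"metric must be one of {sorted(preprocess.METRICS)}")
        if self.fence_mode not in gap_core.FENCE_MODES:
            raise ValueError(f"fence_mode must be one of {gap_core.FENCE_MODES}")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-18s %.2fs", name, t1 - t0)
    return t1


def detect(counts: CountMatrix, config: RunConfig | None = None):
    """Run the full detection pipeline on an in-memory count matrix.

    Returns a RareCellResult whose cell indices refer to the FILTERED matrix;
    ``result.parameters['cell_ids']`` carries the surviving identifiers.
    """
    config = config or RunConfig()
    t0 = time.perf_counter()
    try:
        filtered = preprocess.filter_counts(
            counts, config.min_cells_per_gene, config.min_genes_per_cell
        )
    except ValueError as exc:
        raise ValueError(f"stage filter ({counts.n_genes} genes x {counts.n_cells} cells): {exc}") from exc
    t0 = _stage("filter", t0)

    if filtered.n_cells < 5:
        raise ValueError(
            f"stage filter: only {filtered.n_cells} cells survive; too few to analyse"
        )

    if config.normalization == "median":
        norm = preprocess.median_normalize(filtered)
    else:
        norm = preprocess.lognorm_identity(filtered)
    t0 = _stage("normalize", t0)

    features = preprocess.vst_select_features(
        norm, filtered, min_features=config.min_features, max_features=config.max_features
    )
    t0 = _stage("vst", t0)

    emb = preprocess.pca_embed(norm, features, n_components=config.n_pcs, seed=config.seed)
    t0 = _stage("pca", t0)

    K = config.k_max if config.k_max is not None else preprocess.default_k(filtered.n_cells)
    K = min(K, filtered.n_cells - 1)
    nbrs = preprocess.knn_search(emb, K=K, metric=config.metric)
    t0 = _stage("knn", t0)

    profile = gap_core.gap_profile(nbrs)
    curve = gap_core.build_skewness_curve(
        profile.ddelta_smooth, nbrs,
        threshold=config.skew_threshold, fence_mode=config.fence_mode,
    )
    t0 = _stage("skewness", t0)

    result = _assignment.assign_rare_cells(
        curve, nbrs, profile.ddelta_smooth,
        parameters={
            "threshold": config.skew_threshold,
            "K": K,
            "metric": config.metric,
            "seed": config.seed,
            "fence_mode": config.fence_mode,
            "n_pcs": config.n_pcs,
            "cell_ids": filtered.cell_ids,
        },
    )
    _stage("assignment", t0)
    log.info(
        "detect: %d confirmed cluster(s) of sizes %s",
        len(result.clusters), [c.size_k for c in result.clusters],
    )
    return result


def run_pipeline(config: RunConfig):
    """Read the configured input, detect, and (optionally) persist outputs."""
    from . import io as _io

    if config.input_path is None:
        raise ValueError("config.input_path is required")
    counts = _io.read_matrix(
        config.input_path, dialect=config.dialect, cells_in_rows=config.cells_in_rows
    )
    result = detect(counts, config)
    if config.out_dir is not None:
        _io.write_result(result, result.parameters["cell_ids"], config.out_dir, config=config)
    return result


def run_iterative(counts: CountMatrix, config: RunConfig | None = None,
                  max_rounds: int | None = None) -> list:
    """Repeat detection, removing confirmed rare cells between rounds.

    Stops when a round confirms nothing or ``max_rounds`` is reached; every
    round's result is returned (the terminating empty round included).
    """
    config = config or RunConfig()
    rounds = max_rounds if max_rounds is not None else config.rounds
    if rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    results = []
    current = counts
    for rnd in range(1, rounds + 1):
        try:
            result = detect(current, config)
        except ValueError as exc:
            raise ValueError(f"round {rnd}: {exc}") from exc
        result.parameters["round"] = rnd
        results.append(result)
        if not result.clusters:
            break
        survivors = result.parameters["cell_ids"]
        rare_ids = set(survivors[result.rare_cells])
        keep = np.array([c not in rare_ids for c in counts.cell_ids])
        current = CountMatrix(
            counts=counts.counts[:, keep],
            gene_ids=counts.gene_ids,
            cell_ids=counts.cell_ids[keep],
        )
        counts = current
    return results
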