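"""Gamma-Poisson scRNA-seq count simulator with group DE factors and dropout.

A minimal groups-mode reimplementation of the Splat generative model: gamma
base gene means, per-group log-normal DE factors (probability de_prob per
gene, randomly inverted for down-regulation), log-normal library sizes,
Poisson sampling, and optional logistic expression-dependent dropout.  No
batch effects, BCV trend or paths.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .preprocess import CountMatrix

log = logging.getLogger(__name__)

#: DE-probability grid used by the differential-expression-level experiments
DE_PROB_GRID = (0.1, 0.2, 0.4, 0.6, 0.8)
#: dropout-midpoint grid used by the dropout-rate experiments
DROPOUT_MID_GRID = (0.1068, 0.2033, 0.3090, 0.4050, 0.5023, 0.6078, 0.7041, 0.8026, 0.9067)


@dataclass
class SimParams:
    """Simulator parameters (defaults follow the reference simulator)."""

    n_genes: int = 5000
    group_sizes: tuple = (120, 540, 540)
    de_prob: float = 0.1
    de_downprob: float = 0.5
    de_fac_loc: float = 0.1
    de_fac_scale: float = 0.4
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    dropout_mid: float | None = None
    dropout_shape: float = -1.0
    seed: int = 1

    def __post_init__(self) -> None:
        self.group_sizes = tuple(int(s) for s in self.group_sizes)
        if self.n_genes < 1 or not self.group_sizes or any(s < 1 for s in self.group_sizes):
            raise ValueError("n_genes and every group size must be >= 1")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must be a probability")
        if min(self.de_fac_scale, self.mean_shape, self.mean_rate, self.lib_scale) <= 0:
            raise ValueError("scale/shape/rate parameters must be positive")


@dataclass
class SimulatedDataset:
    """Counts plus ground truth: group labels and per-group DE-gene flags."""

    counts: CountMatrix
    true_labels: np.ndarray
    de_gene_flags: np.ndarray  # genes x groups bool
    params: SimParams
    reserve: CountMatrix | None = None  # held-out genes (gene-replacement design)
    replacements: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.true_labels = np.asarray([str(v) for v in self.true_labels], dtype=object)
        if self.true_labels.size != self.counts.n_cells:
            raise ValueError("one label per cell required")

    def rare_mask(self, group: str = "group1") -> np.ndarray:
        return self.true_labels == group


def simulate_counts(params: SimParams) -> SimulatedDataset:
    """Draw a gamma-Poisson count matrix with planted group structure."""
    rng = np.random.default_rng(params.seed)
    n_groups = len(params.group_sizes)
    n_cells = sum(params.group_sizes)

    base_mean = rng.gamma(shape=params.mean_shape, scale=1.0 / params.mean_rate,
                          size=params.n_genes)
    de_flags = rng.random((params.n_genes, n_groups)) < params.de_prob
    factors = np.ones((params.n_genes, n_groups))
    n_de = int(de_flags.sum())
    if n_de:
        fac = rng.lognormal(mean=params.de_fac_loc, sigma=params.de_fac_scale, size=n_de)
        down = rng.random(n_de) < params.de_downprob
        fac[down] = 1.0 / fac[down]
        factors[de_flags] = fac
    group_means = base_mean[:, None] * factors  # genes x groups

    lib_sizes = rng.lognormal(mean=params.lib_loc, sigma=params.lib_scale, size=n_cells)
    group_of_cell = np.repeat(np.arange(n_groups), params.group_sizes)
    proportions = group_means / group_means.sum(axis=0, keepdims=True)
    rate = proportions[:, group_of_cell] * lib_sizes[None, :]
    counts = rng.poisson(rate)

    if params.dropout_mid is not None:
        with np.errstate(divide="ignore"):
            p_drop = expit(params.dropout_shape * (np.log(rate) - params.dropout_mid))
        counts[rng.random(rate.shape) < p_drop] = 0

    gene_ids = np.array([f"gene{i + 1}" for i in range(params.n_genes)], dtype=object)
    cell_ids = np.array([f"cell{i + 1}" for i in range(n_cells)], dtype=object)
    labels = np.array([f"group{g + 1}" for g in group_of_cell], dtype=object)
    return SimulatedDataset(
        counts=CountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=cell_ids),
        true_labels=labels,
        de_gene_flags=de_flags,
        params=params,
    )


def _subsample(data: SimulatedDataset, keep: np.ndarray) -> SimulatedDataset:
    return SimulatedDataset(
        counts=CountMatrix(
            counts=data.counts.counts[:, keep],
            gene_ids=data.counts.gene_ids,
            cell_ids=data.counts.cell_ids[keep],
        ),
        true_labels=data.true_labels[keep],
        de_gene_flags=data.de_gene_flags,
        params=data.params,
    )


def plant_rare_group(
    params: SimParams, rare_size: int, major_sizes=(500, 500)
) -> SimulatedDataset:
    """Simulate, then subsample a rare group and large majors with known labels.

    Group 1 supplies the rare cells; the remaining groups supply the majors.
    """
    if rare_size < 2:
        raise ValueError("rare_size must be >= 2")
    major_sizes = [int(s) for s in major_sizes]
    if len(major_sizes) != len(params.group_sizes) - 1:
        raise ValueError("need one major size per non-rare simulated group")
    requested = [rare_size] + major_sizes
    for want, have in zip(requested, params.group_sizes):
        if want > have:
            raise ValueError(
                f"requested {want} cells but simulated group only has {have}"
            )
    data = simulate_counts(params)
    rng = np.random.default_rng(params.seed + 0x5EED)
    keep = []
    for g, want in enumerate(requested):
        pool = np.flatnonzero(data.true_labels == f"group{g + 1}")
        keep.append(rng.choice(pool, size=want, replace=False))
    keep = np.sort(np.concatenate(keep))
    return _subsample(data, keep)


def replace_genes(
    data: SimulatedDataset,
    de_pool,
    non_de_pool,
    r: int,
    seed: int = 1,
) -> SimulatedDataset:
    """Swap r random working non-DE genes for r random held-out DE genes.

    The DE pool lives in ``data.reserve`` (same cells, held-out genes); the
    swap happens in place positionally, so the gene count never changes and
    r = 0 is the identity.
    """
    de_pool = np.asarray([str(g) for g in de_pool], dtype=object)
    non_de_pool = np.asarray([str(g) for g in non_de_pool], dtype=object)
    if r < 0 or r > min(de_pool.size, non_de_pool.size):
        raise ValueError(
            f"r must satisfy 0 <= r <= min(|de_pool|={de_pool.size}, "
            f"|non_de_pool|={non_de_pool.size})"
        )
    if r == 0:
        return data
    if data.reserve is None:
        raise ValueError("data has no reserve matrix to draw DE genes from")
    if not np.array_equal(data.reserve.cell_ids, data.counts.cell_ids):
        raise ValueError("reserve must cover the same cells")

    rng = np.random.default_rng(seed)
    out_genes = rng.choice(non_de_pool, size=r, replace=False)
    in_genes = rng.choice(de_pool, size=r, replace=False)

    gene_pos = {g: i for i, g in enumerate(data.counts.gene_ids)}
    reserve_pos = {g: i for i, g in enumerate(data.reserve.gene_ids)}
    try:
        out_idx = np.array([gene_pos[g] for g in out_genes])
        in_idx = np.array([reserve_pos[g] for g in in_genes])
    except KeyError as exc:
        raise ValueError(f"pool gene {exc} not found") from exc

    counts = data.counts.counts.copy()
    gene_ids = data.counts.gene_ids.copy()
    counts[out_idx] = data.reserve.counts[in_idx]
    gene_ids[out_idx] = in_genes
    return SimulatedDataset(
        counts=CountMatrix(counts=counts, gene_ids=gene_ids, cell_ids=data.counts.cell_ids),
        true_labels=data.true_labels,
        de_gene_flags=data.de_gene_flags,
        params=data.params,
        reserve=data.reserve,
        replacements=data.replacements + [(list(out_genes), list(in_genes))],
    )


def make_replacement_fixture(
    rare_size: int = 5,
    major_size: int = 500,
    n_genes: int = 2000,
    de_prob: float = 0.06,
    seed: int = 1,
    lfc_cutoff: float = 1.0,
    de_fac_loc: float = 0.6,
    de_fac_scale: float = 0.6,
) -> tuple[SimulatedDataset, np.ndarray, np.ndarray]:
    """Two-group fixture for the DE-gene replacement experiment.

    Simulates a rare + major pair, defines a stringent DE pool (flagged genes
    whose group-mean |log2 ratio| exceeds ``lfc_cutoff``), strips those genes
    into the reserve, and returns (dataset, de_pool, non_de_pool).
    """
    params = SimParams(
        n_genes=n_genes,
        group_sizes=(max(rare_size, 10), major_size),
        de_prob=de_prob,
        de_fac_loc=de_fac_loc,
        de_fac_scale=de_fac_scale,
        seed=seed,
    )
    data = plant_rare_group(params, rare_size=rare_size, major_sizes=[major_size])

    flagged = data.de_gene_flags.any(axis=1)
    base = simulate_counts(params)  # same seed -> same gene-level ground truth
    ratio = np.log2(_group_mean_ratio(base))
    de_mask = flagged & (np.abs(ratio) >= lfc_cutoff)
    non_de_mask = ~flagged
    de_pool = data.counts.gene_ids[de_mask]
    non_de_pool = data.counts.gene_ids[non_de_mask]

    # working matrix holds only truly non-DE genes; flagged-but-weak genes are
    # dropped from both sets so the baseline carries no group signal
    working = non_de_mask
    fixture = SimulatedDataset(
        counts=CountMatrix(
            counts=data.counts.counts[working],
            gene_ids=data.counts.gene_ids[working],
            cell_ids=data.counts.cell_ids,
        ),
        true_labels=data.true_labels,
        de_gene_flags=data.de_gene_flags,
        params=params,
        reserve=CountMatrix(
            counts=data.counts.counts[de_mask],
            gene_ids=de_pool,
            cell_ids=data.counts.cell_ids,
        ),
    )
    return fixture, de_pool, non_de_pool


def _group_mean_ratio(data: SimulatedDataset) -> np.ndarray:
    """Per-gene ratio of group1 vs group2 mean counts (pseudo-count 1)."""
    g1 = data.true_labels == "group1"
    g2 = data.true_labels == "group2"
    m1 = data.counts.counts[:, g1].mean(axis=1) + 1.0
    m2 = data.counts.counts[:, g2].mean(axis=1) + 1.0
    return m1 / m2
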