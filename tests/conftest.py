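import numpy as np
import pytest

import knngap as kg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_count_matrix(counts) -> kg.CountMatrix:
    counts = np.asarray(counts)
    return kg.CountMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        cell_ids=[f"c{j}" for j in range(counts.shape[1])],
    )


def make_embedding(coords) -> kg.Embedding:
    coords = np.asarray(coords, dtype=float)
    return kg.Embedding(
        coordinates=coords, explained_variance=np.ones(coords.shape[1])
    )


def planted_embedding(
    n_blob: int = 500,
    n_rare: int = 5,
    dim: int = 5,
    gap: float = 50.0,
    spread: float = 0.01,
    seed: int = 0,
) -> tuple:
    """Gaussian blob plus a tight planted cluster at distance ``gap``.

    Returns (Embedding, rare_indices) — rare cells occupy the last positions.
    """
    r = np.random.default_rng(seed)
    blob = r.normal(size=(n_blob, dim))
    centre = np.zeros(dim)
    centre[0] = gap
    rare = centre + spread * r.normal(size=(n_rare, dim))
    coords = np.vstack([blob, rare])
    return make_embedding(coords), np.arange(n_blob, n_blob + n_rare)


def f1_of_result(result, data) -> float:
    """F1 of the confirmed rare set against a SimulatedDataset's group1."""
    ids = result.parameters["cell_ids"]
    predicted = set(ids[result.rare_cells])
    truth = set(data.counts.cell_ids[data.rare_mask()])
    return kg.f1_score(kg.confusion(predicted, truth, N=ids.size))


def truth_mask_for(result, data) -> np.ndarray:
    """Boolean group-1 mask aligned with the result's surviving cells."""
    pos = {c: i for i, c in enumerate(data.counts.cell_ids)}
    ids = result.parameters["cell_ids"]
    return np.array([data.true_labels[pos[c]] == "group1" for c in ids])
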