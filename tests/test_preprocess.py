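import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import knngap as kg
from knngap.preprocess import elbow_point

from conftest import make_count_matrix, make_embedding


# ---------------------------------------------------------------------------
# filter_counts
# ---------------------------------------------------------------------------

def test_filter_drops_rare_gene_keeps_cells():
    counts = np.array([
        [1, 2, 0, 4],
        [5, 0, 6, 7],
        [0, 0, 3, 0],  # g2: nonzero in one cell only
    ])
    out = kg.filter_counts(make_count_matrix(counts), 2, 0)
    assert list(out.gene_ids) == ["g0", "g1"]
    assert list(out.cell_ids) == ["c0", "c1", "c2", "c3"]


def test_filter_zero_thresholds_is_identity(rng):
    cm = make_count_matrix(rng.poisson(1.0, size=(30, 10)))
    out = kg.filter_counts(cm, 0, 0)
    assert np.array_equal(out.counts, cm.counts)
    assert np.array_equal(out.gene_ids, cm.gene_ids)
    assert np.array_equal(out.cell_ids, cm.cell_ids)


def test_filter_matches_brute_force_predicates(rng):
    counts = rng.poisson(0.3, size=(200, 100))
    cm = make_count_matrix(counts)
    out = kg.filter_counts(cm, 3, 20)
    # independent oracle: gene predicate on the raw matrix, cell predicate on
    # the gene-filtered matrix, single pass
    genes = [i for i in range(200) if (counts[i] > 0).sum() >= 3]
    cells = [j for j in range(100) if (counts[np.ix_(genes, [j])] > 0).sum() >= 20]
    assert list(out.gene_ids) == [f"g{i}" for i in genes]
    assert list(out.cell_ids) == [f"c{j}" for j in cells]
    assert np.array_equal(out.counts, counts[np.ix_(genes, cells)])


def test_filter_empty_result_names_threshold():
    cm = make_count_matrix(np.ones((3, 4), dtype=int))
    with pytest.raises(ValueError, match="min_cells_per_gene=99"):
        kg.filter_counts(cm, 99, 0)
    with pytest.raises(ValueError, match="min_genes_per_cell=99"):
        kg.filter_counts(cm, 0, 99)


# ---------------------------------------------------------------------------
# median_normalize
# ---------------------------------------------------------------------------

def test_normalize_identity_size_factors():
    counts = np.array([[1, 2], [3, 2]])  # both cells total 4
    norm = kg.median_normalize(make_count_matrix(counts))
    np.testing.assert_allclose(norm.normalization_record["size_factors"], [1.0, 1.0])
    np.testing.assert_allclose(norm.values, np.log2(counts + 1.0))


def test_normalize_size_factor_definition():
    counts = np.array([[100, 200, 400]])
    norm = kg.median_normalize(make_count_matrix(counts))
    np.testing.assert_allclose(
        norm.normalization_record["size_factors"], [0.5, 1.0, 2.0]
    )


def test_normalize_conserves_totals(rng):
    counts = rng.poisson(3.0, size=(50, 17)) + 1
    cm = make_count_matrix(counts)
    norm = kg.median_normalize(cm)
    sf = norm.normalization_record["size_factors"]
    scaled_totals = counts.sum(axis=0) / sf
    np.testing.assert_allclose(scaled_totals, np.median(counts.sum(axis=0)))


def test_normalize_conserves_within_cell_rank(rng):
    counts = rng.poisson(2.0, size=(40, 8)) + 1
    norm = kg.median_normalize(make_count_matrix(counts))
    for j in range(8):
        assert np.array_equal(
            np.argsort(counts[:, j], kind="stable"),
            np.argsort(norm.values[:, j], kind="stable"),
        )


def test_normalize_zero_total_cell_named():
    counts = np.array([[1, 0], [2, 0]])
    with pytest.raises(ValueError, match="c1"):
        kg.median_normalize(make_count_matrix(counts))


# ---------------------------------------------------------------------------
# vst_select_features
# ---------------------------------------------------------------------------

def _norm_and_raw(counts):
    cm = make_count_matrix(counts)
    return kg.median_normalize(cm), cm


def test_vst_constant_gene_never_selected(rng):
    counts = rng.poisson(5.0, size=(50, 30)) + 1
    counts[7] = 4  # constant gene
    norm, raw = _norm_and_raw(counts)
    fs = kg.vst_select_features(norm, raw)
    assert "g7" not in fs.selected_gene_ids


def test_vst_planted_shift_ranks_top(rng):
    # 50 of 1000 genes carry an 8-fold mean shift in half the cells
    n_genes, n_cells = 1000, 200
    base = rng.lognormal(mean=1.0, sigma=1.2, size=n_genes)
    # planted genes sit inside the bulk mean range so the mean-variance trend
    # is anchored by their null neighbours
    base[:50] = rng.uniform(0.5, 2.0, size=50)
    means = np.tile(base[:, None], (1, n_cells))
    means[:50, 100:] *= 8.0
    counts = rng.poisson(means)
    norm, raw = _norm_and_raw(counts)
    fs = kg.vst_select_features(norm, raw)
    ranks = {g: i for i, g in enumerate(fs.selected_gene_ids)}
    assert all(ranks[f"g{i}"] < 100 for i in range(50))


def _elbow_oracle(values):
    """Brute force: index maximising perpendicular distance to the chord."""
    y = np.asarray(values, dtype=float)
    n = len(y)
    x0, y0, x1, y1 = 0.0, y[0], float(n - 1), y[-1]
    norm = math.hypot(x1 - x0, y1 - y0)
    best, best_d = 1, -1.0
    for i in range(n):
        d = abs((y1 - y0) * (i - x0) - (x1 - x0) * (y[i] - y0)) / norm
        if d > best_d:
            best, best_d = i, d
    return max(1, best)


def test_elbow_point_fixture_and_oracle():
    curve = np.array([10.0, 9.5, 9.0] + list(np.arange(1.0, 0.05, -0.1)))
    assert _elbow_oracle(curve) == 3  # frozen from the oracle
    assert elbow_point(curve) == 3


def test_elbow_point_matches_oracle_random(rng):
    for _ in range(20):
        curve = np.sort(rng.exponential(size=50))[::-1]
        assert elbow_point(curve) == _elbow_oracle(curve)


def test_vst_variance_ordering_invariant(rng):
    counts = rng.poisson(rng.lognormal(1.0, 1.0, size=(300, 1))[:, 0][:, None]
                         * np.ones((300, 40)))
    norm, raw = _norm_and_raw(counts)
    fs = kg.vst_select_features(norm, raw)
    assert np.all(np.diff(fs.standardized_variance) <= 1e-12)
    assert fs.elbow_index == fs.selected_gene_ids.size


def test_vst_all_constant_fails():
    counts = np.full((10, 5), 3)
    norm, raw = _norm_and_raw(counts)
    with pytest.raises(ValueError, match="positive variance"):
        kg.vst_select_features(norm, raw)


# ---------------------------------------------------------------------------
# pca_embed
# ---------------------------------------------------------------------------

def _embed_fixture(values, n_components=5, seed=1):
    n_genes, n_cells = values.shape
    norm = kg.NormalizedMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{j}" for j in range(n_cells)],
    )
    sv = np.sort(values.var(axis=1))[::-1]
    fs = kg.FeatureSet(
        selected_gene_ids=norm.gene_ids[np.argsort(-values.var(axis=1), kind="stable")],
        standardized_variance=sv,
        elbow_index=n_genes,
    )
    return kg.pca_embed(norm, fs, n_components=n_components, seed=seed), norm


def test_pca_planar_data_is_rank_two(rng):
    basis = rng.normal(size=(2, 8))
    weights = rng.normal(size=(30, 2))
    plane = weights @ basis  # cells x genes, rank 2
    values = (plane - plane.min() + 1.0).T  # genes x cells, affine rank <= 3
    emb, _ = _embed_fixture(values, n_components=6)
    # at most 3 informative directions (2 basis + offset removed by centering)
    assert np.all(emb.explained_variance[3:] <= 1e-8 * emb.explained_variance[0])


def test_pca_matches_dense_eigendecomposition(rng):
    values = rng.lognormal(0.0, 1.0, size=(10, 20))
    emb, norm = _embed_fixture(values, n_components=5)
    # oracle: full eigendecomposition of the scaled submatrix's covariance
    X = values.T
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    evals, evecs = np.linalg.eigh(np.cov(X.T))
    order = np.argsort(evals)[::-1][:5]
    scores = X @ evecs[:, order]
    np.testing.assert_allclose(emb.explained_variance, evals[order], rtol=1e-8)
    for j in range(5):
        diff = min(
            np.abs(emb.coordinates[:, j] - scores[:, j]).max(),
            np.abs(emb.coordinates[:, j] + scores[:, j]).max(),
        )
        assert diff < 1e-8


def test_pca_duplicate_cells_identical_rows(rng):
    values = rng.lognormal(0.0, 1.0, size=(12, 15))
    values[:, 7] = values[:, 3]
    emb, _ = _embed_fixture(values, n_components=4)
    np.testing.assert_allclose(emb.coordinates[7], emb.coordinates[3], atol=1e-10)


def test_pca_full_rank_preserves_distances(rng):
    values = rng.lognormal(0.0, 0.5, size=(8, 25))
    emb, _ = _embed_fixture(values, n_components=8)  # clamped to full rank
    X = values.T
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    expected = cdist(X, X)
    got = cdist(emb.coordinates, emb.coordinates)
    np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-8)


def test_pca_clamps_components_with_warning(rng, caplog):
    values = rng.lognormal(0.0, 1.0, size=(5, 30))
    with caplog.at_level("WARNING"):
        emb, _ = _embed_fixture(values, n_components=20)
    assert emb.coordinates.shape[1] == 5
    assert any("clamping" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# knn_search
# ---------------------------------------------------------------------------

def test_knn_three_points_on_line():
    emb = make_embedding(np.array([[0.0], [1.0], [3.0]]))
    nbrs = kg.knn_search(emb, K=2)
    assert list(nbrs.neighbor_index[0]) == [1, 2]
    np.testing.assert_allclose(nbrs.D[0], [1.0, 3.0])


def _knn_oracle(X, K, metric):
    d = cdist(X, X, metric={"euclidean": "euclidean", "manhattan": "cityblock"}[metric])
    idx = np.empty((len(X), K), dtype=int)
    dist = np.empty((len(X), K))
    for m in range(len(X)):
        order = sorted((j for j in range(len(X)) if j != m), key=lambda j: (d[m, j], j))
        idx[m] = order[:K]
        dist[m] = d[m, idx[m]]
    return idx, dist


@pytest.mark.parametrize("metric", ["euclidean", "manhattan"])
def test_knn_matches_brute_force(rng, metric):
    X = rng.normal(size=(50, 5))
    nbrs = kg.knn_search(make_embedding(X), K=10, metric=metric)
    idx, dist = _knn_oracle(X, 10, metric)
    assert np.array_equal(nbrs.neighbor_index, idx)
    np.testing.assert_allclose(nbrs.D, dist, rtol=1e-12)


def test_knn_duplicates_give_zero_distance(rng):
    X = rng.normal(size=(10, 3))
    X[4] = X[1]
    nbrs = kg.knn_search(make_embedding(X), K=3)
    assert nbrs.D[4, 0] == 0.0 and nbrs.D[1, 0] == 0.0
    assert nbrs.neighbor_index[4, 0] == 1  # tie resolved towards smaller index


def test_knn_permutation_invariance(rng):
    X = rng.normal(size=(40, 4))
    perm = rng.permutation(40)
    a = kg.knn_search(make_embedding(X), K=8)
    b = kg.knn_search(make_embedding(X[perm]), K=8)
    inv = np.argsort(perm)
    # relabelling cells permutes the tables consistently
    for m in range(40):
        np.testing.assert_allclose(a.D[m], b.D[inv[m]], rtol=1e-12)
        assert np.array_equal(a.neighbor_index[m], perm[b.neighbor_index[inv[m]]])


def test_knn_rejects_bad_k(rng):
    emb = make_embedding(rng.normal(size=(10, 2)))
    with pytest.raises(ValueError, match="2 <= K <= N-1"):
        kg.knn_search(emb, K=1)
    with pytest.raises(ValueError, match="2 <= K <= N-1"):
        kg.knn_search(emb, K=10)


def test_knn_sorted_distance_contract(rng):
    nbrs = kg.knn_search(make_embedding(rng.normal(size=(60, 6))), K=20)
    assert np.all(np.diff(nbrs.D, axis=1) >= 0)


def test_default_k_formula():
    assert kg.default_k(100) == 60
    assert kg.default_k(1003) == 61
    assert kg.default_k(20000) == 1010
    assert kg.default_k(30) == 29  # capped at N - 1
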