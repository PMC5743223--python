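"""Affinity calibration, t-SNE, PCA, co-ancestry distance and MDS."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from clonepotency.embedding import (AffinityMatrix, classical_mds,
                                    conditional_affinities, embed_tsne,
                                    joint_affinities, lineage_ancestry_distance,
                                    pca_scores, spearman_distance)
from clonepotency.errors import InsufficientDataError, ValidationError


def _entropy_bits(p):
    p = p[p > 0]
    return -np.sum(p * np.log2(p))


def test_equilateral_triangle_rows_are_uniform():
    X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    P, sigma = conditional_affinities(X, perplexity=1.999)
    for i in range(3):
        row = np.delete(P[i], i)
        np.testing.assert_allclose(row, 0.5, atol=1e-9)


def test_rows_calibrated_to_target_perplexity(rng):
    X = rng.normal(size=(120, 6))
    for u in (5.0, 20.0, 50.0):
        P, _ = conditional_affinities(X, perplexity=u)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.abs(np.diag(P)).max() == 0.0
        perp = np.array([2 ** _entropy_bits(P[i]) for i in range(120)])
        assert np.abs(np.log2(perp) - np.log2(u)).max() < 1e-4


def test_binary_search_sigma_matches_grid_search_oracle(rng):
    """Independent oracle: dense grid over sigma, pick the best per row."""
    X = rng.normal(size=(10, 4))
    u = 4.0
    P, sigma = conditional_affinities(X, perplexity=u)
    D2 = squareform(pdist(X, "sqeuclidean"))
    grid = np.geomspace(1e-3, 1e3, 240_001)
    for i in range(10):
        d = np.delete(D2[i], i)
        w = np.exp(-d[None, :] / (2.0 * grid[:, None] ** 2))
        p = w / w.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=1)
        best = grid[np.argmin(np.abs(h - np.log2(u)))]
        assert abs(sigma[i] - best) / best < 1e-3


def test_affinities_need_three_points_and_valid_perplexity(rng):
    with pytest.raises(InsufficientDataError):
        conditional_affinities(rng.normal(size=(2, 3)))
    with pytest.raises(ValidationError):
        conditional_affinities(rng.normal(size=(10, 3)), perplexity=10.0)


def test_degenerate_coincident_points_reported():
    X = np.zeros((5, 3))
    with pytest.raises(ValidationError, match="row"):
        conditional_affinities(X, perplexity=2.0)


def test_joint_symmetric_and_sums_to_one(rng):
    for _ in range(20):
        n = int(rng.integers(3, 30))
        C = rng.dirichlet(np.ones(n - 1), size=n)
        full = np.zeros((n, n))
        for i in range(n):
            full[i, np.arange(n) != i] = C[i]
        A = joint_affinities(full)
        assert abs(A.P.sum() - 1.0) < 1e-10
        np.testing.assert_allclose(A.P, A.P.T, atol=1e-15)


def test_joint_of_symmetric_conditional_is_conditional_over_n():
    C = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
    A = joint_affinities(C)
    np.testing.assert_allclose(A.P, C / 3.0, atol=1e-15)


def test_joint_hand_computed_asymmetric_instance():
    C = np.array([[0.0, 0.7, 0.3],
                  [0.2, 0.0, 0.8],
                  [0.6, 0.4, 0.0]])
    expected = np.array([[0.0, 0.9, 0.9],
                         [0.9, 0.0, 1.2],
                         [0.9, 1.2, 0.0]]) / 6.0
    A = joint_affinities(C)
    np.testing.assert_allclose(A.P, expected, atol=1e-15)


def test_affinity_matrix_invariants_enforced():
    with pytest.raises(ValidationError):
        AffinityMatrix(P=np.array([[0.0, 0.6], [0.4, 0.0]]), sigma=np.ones(2), perplexity=2)


def test_tsne_two_points_have_zero_kl():
    A = AffinityMatrix(P=np.array([[0.0, 0.5], [0.5, 0.0]]), sigma=np.ones(2), perplexity=1)
    emb = embed_tsne(A, seed=0, n_iter=50)
    assert emb.kl_final == pytest.approx(0.0, abs=1e-9)


def test_tsne_reproducible_and_kl_decreases(rng):
    X = rng.normal(size=(60, 6))
    P, _ = conditional_affinities(X, 10.0)
    A = joint_affinities(P)
    e1 = embed_tsne(A, seed=42, n_iter=300)
    e2 = embed_tsne(A, seed=42, n_iter=300)
    np.testing.assert_array_equal(e1.coords, e2.coords)
    assert e1.kl_final <= e1.kl_initial
    assert e1.kl_final >= 0.0


def test_duplicated_rows_end_adjacent_across_seeds(rng):
    X = rng.normal(size=(30, 6))
    X[1] = X[0]  # exact duplicate
    P, _ = conditional_affinities(X + rng.normal(0, 1e-9, X.shape), 8.0)
    A = joint_affinities(P)
    for seed in range(20):
        emb = embed_tsne(A, seed=seed)
        d01 = np.linalg.norm(emb.coords[0] - emb.coords[1])
        others = np.linalg.norm(emb.coords[2:] - emb.coords[0], axis=1)
        assert d01 < others.min()


def test_tsne_permutation_equivariance(rng):
    X = rng.normal(size=(40, 6))
    P, _ = conditional_affinities(X, 8.0)
    A = joint_affinities(P)
    perm = rng.permutation(40)
    Pp, _ = conditional_affinities(X[perm], 8.0)
    np.testing.assert_allclose(joint_affinities(Pp).P, A.P[np.ix_(perm, perm)], atol=1e-12)


def test_pca_on_a_line_has_unit_first_component(rng):
    t = rng.normal(size=50)
    X = np.column_stack([t, 2 * t, -t])
    res = pca_scores(X)
    assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_scores_orthogonal_and_reconstruct(rng):
    X = rng.normal(size=(40, 6))
    res = pca_scores(X)
    G = res.scores.T @ res.scores
    assert np.abs(G - np.diag(np.diag(G))).max() < 1e-9
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    np.testing.assert_allclose(res.scores @ res.loadings.T, Z, atol=1e-9)
    assert res.variance_fraction.sum() == pytest.approx(1.0)


def test_pca_constant_column_dropped(rng):
    X = np.column_stack([rng.normal(size=30), np.full(30, 3.0), rng.normal(size=30)])
    with pytest.warns(UserWarning, match="constant"):
        res = pca_scores(X)
    assert res.dropped_columns == [1]
    assert res.loadings.shape[0] == 2


def test_spearman_distance_identical_and_reversed_columns():
    x = np.arange(10, dtype=float)
    M = np.column_stack([x, x, x[::-1]])
    D = spearman_distance(M)
    assert D[0, 1] == pytest.approx(0.0)
    assert D[0, 2] == pytest.approx(2.0)


def test_spearman_hand_ranked_instance():
    # ranks of y vs x differ by d = (1,-1,1,-1,0): rho = 1 - 6*4/(5*24) = 0.8
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 1, 4, 3, 5])
    D = spearman_distance(np.column_stack([x, y]))
    assert D[0, 1] == pytest.approx(1 - 0.8)


def test_lineage_ancestry_distance_shape_and_bounds(small_table):
    D = lineage_ancestry_distance(small_table)
    assert D.shape == (6, 6)
    np.testing.assert_allclose(D, D.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)
    assert (D >= -1e-12).all() and (D <= 2 + 1e-12).all()


def test_mds_recovers_planar_distances(rng):
    pts = rng.normal(size=(4, 2))
    D = squareform(pdist(pts))
    coords, eig = classical_mds(D, k=2)
    np.testing.assert_allclose(squareform(pdist(coords)), D, atol=1e-8)
    assert eig.min() > -1e-9  # Euclidean input: Gram part is PSD


def test_mds_zero_distances_give_zero_coordinates():
    with pytest.warns(UserWarning, match="positive eigenvalue"):
        coords, _ = classical_mds(np.zeros((4, 4)), k=2)
    np.testing.assert_array_equal(coords, 0.0)


def test_mds_of_transposed_analysis_round_trips(small_table):
    """The clone-by-clone variant reuses the same two operations on the
    transposed matrix; shapes and symmetry carry over."""
    Y = small_table.yields()
    Y = Y[Y.sum(axis=1) > 0][:40]
    D = spearman_distance(Y.T)  # distances between clones
    assert D.shape == (40, 40)
    coords, _ = classical_mds(D, k=2)
    assert coords.shape == (40, 2)
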