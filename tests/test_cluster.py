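"""PCA, K-means selection, Spearman distance, PAM and consensus clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, rankdata

from blcasig.cluster import (
    consensus_cluster,
    heatmap_order,
    kmeans_select_k,
    pam,
    pca,
    spearman_distance,
    standardize,
)
from blcasig.exceptions import DomainError


def _blobs(n_per=20, centers=((0, 0), (8, 8)), seed=0, n_features=2):
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for i, c in enumerate(centers):
        c = np.resize(np.asarray(c, float), n_features)
        pts.append(rng.normal(c, 0.5, size=(n_per, n_features)))
        labels += [i] * n_per
    return np.vstack(pts), np.array(labels)


# -- standardize -----------------------------------------------------------

def test_standardize_sample_sd_convention():
    out = standardize(np.array([[1.0], [2.0], [3.0]]))
    assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])


def test_standardize_constant_column_zeroed_with_warning():
    with pytest.warns(UserWarning):
        out = standardize(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
    assert np.allclose(out[:, 1], 0.0)


def test_standardize_idempotent():
    rng = np.random.default_rng(0)
    X = rng.normal(3, 2, size=(30, 4))
    once = standardize(X)
    twice = standardize(once)
    assert np.allclose(once, twice)


# -- PCA -------------------------------------------------------------------

def test_pca_collinear_data_first_component_explains_all():
    t = np.linspace(-1, 1, 20)
    X = np.column_stack([t, 2 * t])
    res = pca(standardize(X))
    assert res.explained_fraction[0] == pytest.approx(1.0)


def test_pca_reconstruction_with_all_components():
    rng = np.random.default_rng(1)
    X = standardize(rng.normal(size=(25, 4)))
    res = pca(X)
    recon = res.scores @ res.loadings.T + X.mean(axis=0)
    assert np.allclose(recon, X, atol=1e-10)


def test_pca_explained_matches_independent_covariance_eigenvalues():
    rng = np.random.default_rng(2)
    X = standardize(rng.normal(size=(40, 5)) @ np.diag([3, 2, 1, 1, 0.5]))
    res = pca(X)
    eig = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
    assert np.allclose(res.explained_fraction, eig / eig.sum(), atol=1e-10)
    assert np.all(np.diff(res.eigenvalues) <= 1e-12)


def test_pca_isotropic_data_near_equal_fractions():
    rng = np.random.default_rng(3)
    res = pca(standardize(rng.normal(size=(4000, 4))))
    assert np.allclose(res.explained_fraction, 0.25, atol=0.03)


def test_pca_truncation_warns():
    rng = np.random.default_rng(4)
    with pytest.warns(UserWarning):
        pca(standardize(rng.normal(size=(5, 3))), n_components=10)


# -- K-means selection -----------------------------------------------------

def test_kmeans_finds_four_separated_blobs():
    X, _ = _blobs(n_per=25, centers=((0, 0), (8, 0), (0, 8), (8, 8)), seed=5)
    res = kmeans_select_k(X, range(2, 7), seed=5)
    assert res.k_best == 4
    assert res.silhouettes[4] > 0.7
    assert not res.no_structure


def test_kmeans_single_blob_flags_no_structure():
    rng = np.random.default_rng(6)
    res = kmeans_select_k(rng.normal(size=(60, 10)), range(2, 6), seed=6)
    assert res.no_structure


def test_kmeans_duplicate_points_no_crash():
    X = np.tile([[1.0, 2.0]], (10, 1))
    res = kmeans_select_k(X, [2, 3], seed=0)
    assert res.k_best in (2, 3)


# -- Spearman distance -----------------------------------------------------

def test_spearman_distance_identical_and_reversed_profiles():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    D = spearman_distance(np.vstack([a, a, a[::-1]]))
    assert D[0, 1] == pytest.approx(0.0)
    assert D[0, 2] == pytest.approx(2.0)
    assert np.allclose(np.diag(D), 0.0)


def test_spearman_distance_constant_profile_warns():
    with pytest.warns(UserWarning):
        D = spearman_distance(np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))
    assert D[0, 1] == pytest.approx(1.0)


def test_spearman_distance_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(10, 10))
    D = spearman_distance(X)
    for i in range(10):
        for j in range(i + 1, 10):
            rho = pearsonr(rankdata(X[i]), rankdata(X[j])).statistic
            assert D[i, j] == pytest.approx(1 - rho, abs=1e-10)


# -- PAM -------------------------------------------------------------------

def test_pam_recovers_two_blobs():
    from scipy.spatial.distance import cdist
    X, truth = _blobs(seed=8)
    D = cdist(X, X)
    res = pam(D, 2)
    # partition matches ground truth up to label swap
    same = (res.labels == res.labels[0])
    assert np.array_equal(same, truth == truth[0]) or \
        np.array_equal(same, truth != truth[0])


def test_pam_k_equals_n_gives_zero_objective():
    from scipy.spatial.distance import cdist
    X, _ = _blobs(n_per=3, seed=9)
    D = cdist(X, X)
    res = pam(D, D.shape[0])
    assert res.objective == 0.0


def test_pam_swap_never_worse_than_build():
    from scipy.spatial.distance import cdist
    rng = np.random.default_rng(10)
    X = rng.normal(size=(25, 3))
    D = cdist(X, X)
    for k in (2, 3, 5):
        res = pam(D, k)
        assert res.objective <= res.build_objective + 1e-12


def test_pam_matches_global_optimum_on_small_instance():
    from itertools import combinations
    from scipy.spatial.distance import cdist
    rng = np.random.default_rng(11)
    X = rng.normal(size=(8, 2))
    D = cdist(X, X)
    res = pam(D, 2)
    best = min(D[:, list(m)].min(axis=1).sum()
               for m in combinations(range(8), 2))
    assert res.objective == pytest.approx(best)


def test_pam_k_out_of_range_rejected():
    D = np.zeros((3, 3))
    with pytest.raises(DomainError):
        pam(D, 4)


# -- consensus clustering --------------------------------------------------

def test_consensus_matrix_symmetric_unit_diagonal_bounded():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(20, 8))
    res = consensus_cluster(X, [2, 3], reps=10, seed=12)[2]
    M = res.matrix
    assert np.allclose(M, M.T)
    assert np.allclose(np.diag(M), 1.0)
    assert (M >= 0).all() and (M <= 1).all()


def test_consensus_full_subsample_deterministic_pam_binary_entries():
    X, _ = _blobs(n_per=8, seed=13, n_features=6)
    res = consensus_cluster(X, [2], reps=2, subsample_fraction=1.0, seed=13)[2]
    assert set(np.unique(res.matrix)) <= {0.0, 1.0}


def test_consensus_separated_blobs_crisp_matrix():
    # blobs separated in profile *shape*, so Spearman distance sees them
    rng = np.random.default_rng(14)
    up = np.sort(rng.normal(size=(12, 10)), axis=1)
    down = -np.sort(rng.normal(size=(12, 10)), axis=1)
    X = np.vstack([up + rng.normal(0, 0.01, (12, 10)),
                   down + rng.normal(0, 0.01, (12, 10))])
    res = consensus_cluster(X, [2], reps=30, seed=14)[2]
    M = res.matrix
    within = np.r_[M[:12, :12][np.triu_indices(12, 1)],
                   M[12:, 12:][np.triu_indices(12, 1)]]
    between = M[:12, 12:].ravel()
    assert within.min() > 0.99
    assert between.max() < 0.01
    labels = res.assignments
    assert len(set(labels[:12])) == 1 and len(set(labels[12:])) == 1
    assert labels[0] != labels[-1]


def test_consensus_invalid_params_rejected():
    X = np.zeros((10, 4))
    with pytest.raises(DomainError):
        consensus_cluster(X, [2], reps=1)
    with pytest.raises(DomainError):
        consensus_cluster(X, [2], reps=5, subsample_fraction=0.0)


# -- heatmap ordering ------------------------------------------------------

def test_heatmap_blocks_contiguous_and_orders_are_permutations(small_cohort):
    genes = small_cohort.gene_ids[:10]
    samples = small_cohort.sample_ids
    clusters = pd.Series(["a" if i % 2 == 0 else "b"
                          for i in range(len(samples))], index=samples)
    spec = heatmap_order(small_cohort, genes, clusters,
                         annotations=["histology_group"])
    assert sorted(spec.sample_order) == sorted(samples)
    assert sorted(spec.gene_order) == sorted(genes)
    labels = [clusters[s] for s in spec.sample_order]
    # cluster blocks are contiguous
    changes = sum(1 for i in range(1, len(labels)) if labels[i] != labels[i - 1])
    assert changes == 1
    assert list(spec.annotations.columns) == ["histology_group", "cluster"]


def test_heatmap_single_gene_trivially_ordered(small_cohort):
    gene = small_cohort.gene_ids[:1]
    clusters = pd.Series("a", index=small_cohort.sample_ids)
    spec = heatmap_order(small_cohort, gene, clusters)
    assert spec.gene_order == gene


def test_heatmap_unknown_annotation_rejected(small_cohort):
    clusters = pd.Series("a", index=small_cohort.sample_ids)
    with pytest.raises(DomainError):
        heatmap_order(small_cohort, small_cohort.gene_ids[:3], clusters,
                      annotations=["not_a_column"])
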