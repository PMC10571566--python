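"""Patient clustering: PCA + K-means track, and PAM/Spearman consensus track.

Two clustering tracks operate on samples with genes as features.  The
exploratory track standardizes variables, projects onto principal
components (eigenvectors of the covariance matrix) and runs K-means with
the silhouette criterion and the inertia elbow for choosing K.  The main
track clusters samples with Partitioning Around Medoids (PAM) over the
Spearman-correlation distance d = 1 - rho_s, wrapped in consensus
clustering: repeated subsampling, a co-clustering (consensus) matrix,
and a final partition from average-linkage hierarchical clustering of
1 - M.  PAM is implemented here directly (greedy BUILD initialization
followed by best-improvement SWAP until convergence), since dissimilarity
medoid clustering is not covered by the scientific stack the package
builds on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .exceptions import DomainError
from .ingest import Cohort

_SILHOUETTE_STRUCTURE_FLOOR = 0.25


@dataclass
class PcaResult:
    loadings: np.ndarray            # columns are eigenvectors
    eigenvalues: np.ndarray         # descending
    scores: np.ndarray              # per-sample projections
    explained_fraction: np.ndarray


@dataclass
class KSelectionResult:
    k_best: int
    assignments: np.ndarray
    silhouettes: dict[int, float]
    inertias: dict[int, float]
    elbow_k: int
    no_structure: bool


@dataclass
class PamResult:
    medoids: np.ndarray
    labels: np.ndarray
    objective: float
    build_objective: float


@dataclass
class ConsensusResult:
    k: int
    matrix: np.ndarray
    assignments: np.ndarray
    reps: int
    subsample_fraction: float
    cdf_x: np.ndarray = field(default=None)
    cdf_y: np.ndarray = field(default=None)


@dataclass
class HeatmapSpec:
    sample_order: list[str]
    gene_order: list[str]
    matrix: pd.DataFrame            # standardized, reordered (samples x genes)
    annotations: pd.DataFrame       # per-sample tracks, reordered


def standardize(matrix, ddof: int = 1) -> np.ndarray:
    """Center and scale each variable (column) to mean 0, SD 1.

    Uses the sample SD (``ddof=1``) by default, consistent with the
    statistics elsewhere in the package; zero-variance variables map to
    all-zeros with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance variables mapped to zeros",
                      stacklevel=2)
    sd = np.where(zero, 1.0, sd)
    out = (X - mean) / sd
    out[:, zero] = 0.0
    return out


def pca(matrix, n_components: int | None = None) -> PcaResult:
    """Principal components from the covariance-matrix eigendecomposition.

    Input should already be standardized.  Components are ordered by
    descending eigenvalue; each eigenvector is sign-fixed so that its
    largest-magnitude loading is positive.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2:
        raise DomainError("PCA needs at least 2 samples")
    max_rank = min(n - 1, p)
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        warnings.warn(f"n_components truncated from {n_components} to rank "
                      f"{max_rank}", stacklevel=2)
        n_components = max_rank
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] *= -1
    total = eigval.sum()
    frac = eigval / total if total > 0 else np.zeros_like(eigval)
    centered = X - X.mean(axis=0)
    return PcaResult(
        loadings=eigvec[:, :n_components],
        eigenvalues=eigval[:n_components],
        scores=centered @ eigvec[:, :n_components],
        explained_fraction=frac[:n_components],
    )


def kmeans_select_k(points, k_range, seed: int | None = None,
                    n_init: int = 10) -> KSelectionResult:
    """K-means over a range of K with silhouette and elbow diagnostics.

    ``k_best`` is the silhouette argmax; the inertia elbow (maximum
    distance to the chord joining the endpoints of the inertia curve) is
    reported alongside.  A ``no_structure`` flag is raised when no K
    reaches a mean silhouette of 0.25.
    """
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise DomainError("need at least 3 points to select K")
    k_range = [k for k in k_range]
    if any(k < 2 or k > n - 1 for k in k_range):
        raise DomainError("k_range must lie within [2, n-1]")
    rng = np.random.default_rng(seed)
    sil: dict[int, float] = {}
    inertia: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init,
                    random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(X)
        labels[k] = lab
        inertia[k] = float(km.inertia_)
        sil[k] = (silhouette_score(X, lab) if len(set(lab)) > 1 else -1.0)
    k_best = max(sil, key=lambda k: (sil[k], -k))
    # elbow: maximum distance to the chord of the (k, inertia) curve
    ks = np.asarray(sorted(inertia))
    vals = np.asarray([inertia[k] for k in ks])
    if len(ks) > 2:
        p0, p1 = np.array([ks[0], vals[0]]), np.array([ks[-1], vals[-1]])
        chord = p1 - p0
        chord = chord / np.linalg.norm(chord)
        pts = np.column_stack([ks, vals]) - p0
        dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0])
        elbow_k = int(ks[int(np.argmax(dist))])
    else:
        elbow_k = int(ks[0])
    return KSelectionResult(
        k_best=int(k_best), assignments=labels[k_best], silhouettes=sil,
        inertias=inertia, elbow_k=elbow_k,
        no_structure=max(sil.values()) < _SILHOUETTE_STRUCTURE_FLOOR,
    )


def spearman_distance(matrix) -> np.ndarray:
    """Sample x sample distance d_ij = 1 - Spearman rho of profiles.

    ``matrix`` is samples x genes; profiles are correlated across genes,
    so d ranges over [0, 2] with d_ii = 0.  Constant profiles have an
    undefined correlation; their distances are set to 1 with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    n, g = X.shape
    if g < 2:
        raise DomainError("need at least 2 genes as features")
    ranks = stats.rankdata(X, axis=1)
    constant = np.ptp(ranks, axis=1) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant profiles: distance set to 1",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    d = 1.0 - rho
    d[np.isnan(d)] = 1.0
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _pam_objective(D: np.ndarray, medoids: np.ndarray) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam(D, k: int, seed: int | None = None,
        max_swaps: int = 1000) -> PamResult:
    """Partitioning Around Medoids on a precomputed dissimilarity matrix.

    BUILD greedily picks medoids minimizing total dissimilarity; SWAP
    repeatedly applies the single medoid/non-medoid exchange with the
    largest objective decrease until none improves.  The objective is
    non-increasing throughout; the procedure is deterministic (``seed``
    is accepted for interface symmetry only).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1]:
        raise DomainError("dissimilarity matrix must be square")
    if not 1 <= k <= n:
        raise DomainError(f"k must lie in [1, {n}], got {k}")
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.sum(np.maximum(current[None, :] - D, 0.0), axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.asarray(sorted(medoids))
    build_obj = _pam_objective(D, medoids)
    # SWAP
    obj = build_obj
    for _ in range(max_swaps):
        best_delta, best_pair = -1e-12, None
        med_set = set(medoids.tolist())
        for mi, m in enumerate(medoids):
            others = np.delete(medoids, mi)
            for h in range(n):
                if h in med_set:
                    continue
                cand = np.append(others, h)
                new_obj = _pam_objective(D, cand)
                delta = new_obj - obj
                if delta < best_delta:
                    best_delta, best_pair = delta, (mi, h)
        if best_pair is None:
            break
        mi, h = best_pair
        medoids = np.asarray(sorted(np.append(np.delete(medoids, mi), h)))
        obj += best_delta
    obj = _pam_objective(D, medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    return PamResult(medoids=medoids, labels=labels, objective=obj,
                     build_objective=build_obj)


def consensus_cluster(matrix, k_range, reps: int = 250,
                      subsample_fraction: float = 0.8,
                      seed: int | None = None) -> dict[int, ConsensusResult]:
    """Consensus clustering of samples with PAM over Spearman distance.

    Per repetition a fraction of samples is drawn without replacement and
    PAM is run for every K in ``k_range`` on the subsample's Spearman
    distance matrix.  M_ij is the fraction of co-sampled repetitions in
    which i and j fell in the same cluster (diagonal 1; pairs never
    co-sampled get 0 with a warning).  The final K-group assignment comes
    from average-linkage hierarchical clustering of 1 - M.  The empirical
    CDF of the off-diagonal consensus entries is attached per K.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if reps < 2:
        raise DomainError("reps must be at least 2")
    if not 0 < subsample_fraction <= 1:
        raise DomainError("subsample_fraction must lie in (0, 1]")
    k_range = sorted(set(int(k) for k in k_range))
    rng = np.random.default_rng(seed)
    m_sub = max(2, int(np.floor(subsample_fraction * n)))
    together = {k: np.zeros((n, n)) for k in k_range}
    cosampled = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m_sub, replace=False))
        D = spearman_distance(X[idx])
        cosampled[np.ix_(idx, idx)] += 1
        for k in k_range:
            if k >= m_sub:
                continue
            lab = pam(D, k).labels
            same = lab[:, None] == lab[None, :]
            together[k][np.ix_(idx, idx)] += same
    never = cosampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn("some sample pairs were never co-sampled; consensus set to 0",
                      stacklevel=2)
    results: dict[int, ConsensusResult] = {}
    denom = np.where(cosampled > 0, cosampled, 1.0)
    for k in k_range:
        M = together[k] / denom
        M[never] = 0.0
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
        Z = linkage(squareform(1.0 - M, checks=False), method="average")
        assign = fcluster(Z, t=k, criterion="maxclust") - 1
        off = M[np.triu_indices(n, k=1)]
        xs = np.sort(off)
        ys = np.arange(1, xs.size + 1) / xs.size
        results[k] = ConsensusResult(
            k=k, matrix=M, assignments=assign, reps=reps,
            subsample_fraction=subsample_fraction, cdf_x=xs, cdf_y=ys,
        )
    return results


def _leaf_order(D: np.ndarray) -> np.ndarray:
    if D.shape[0] <= 2:
        return np.arange(D.shape[0])
    Z = linkage(squareform(D, checks=False), method="average")
    return leaves_list(Z)


def heatmap_order(cohort: Cohort, genes, clusters,
                  annotations=()) -> HeatmapSpec:
    """Order samples and genes for heatmap export.

    Samples are ordered by cluster label, then by average-linkage leaf
    order on the within-cluster Spearman distances; genes by hierarchical
    clustering of gene-gene Spearman distances.  ``annotations`` names
    clinical columns to attach as per-sample tracks (the cluster label is
    always attached); unknown names raise an error.  Values are
    standardized per gene.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in cohort.expression.index]
    if missing:
        raise DomainError(f"genes not in cohort: {missing[:5]}")
    samples = cohort.sample_ids
    clusters = pd.Series(clusters)
    clusters = clusters.reindex(samples)
    if clusters.isna().any():
        raise DomainError("cluster labels missing for some samples")
    unknown = [a for a in annotations if a not in cohort.clinical.columns]
    if unknown:
        raise DomainError(f"unknown annotation keys: {unknown}")

    sub = cohort.expression.loc[genes, samples]          # genes x samples
    values = standardize(sub.T.to_numpy())               # samples x genes, per gene

    sample_order: list[str] = []
    D_samples = spearman_distance(sub.T.to_numpy()) if len(genes) >= 2 else None
    for c in sorted(clusters.unique(), key=str):
        members = [s for s in samples if clusters[s] == c]
        pos = [samples.index(s) for s in members]
        if D_samples is not None and len(members) > 2:
            order = _leaf_order(D_samples[np.ix_(pos, pos)])
            members = [members[i] for i in order]
        sample_order.extend(members)

    if len(genes) >= 2 and len(samples) >= 2:
        D_genes = spearman_distance(sub.to_numpy())
        gene_order = [genes[i] for i in _leaf_order(D_genes)]
    else:
        gene_order = genes

    mat = pd.DataFrame(values, index=samples, columns=genes)
    mat = mat.loc[sample_order, gene_order]
    ann = cohort.clinical.loc[sample_order, list(annotations)].copy()
    ann["cluster"] = clusters.reindex(sample_order).to_numpy()
    return HeatmapSpec(sample_order=sample_order, gene_order=gene_order,
                       matrix=mat, annotations=ann)
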