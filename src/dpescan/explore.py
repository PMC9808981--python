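"""Unsupervised structure of the cohort: Ward clustering, PCA and MDS.

All three operate on a matrix of normalized log2-CPM values restricted to a
selected exon set (typically the consensus DPE calls or the cross-comparison
signature), with samples as the observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform


@dataclass
class LinkageTree:
    merges: np.ndarray        # scipy linkage matrix (n-1, 4)
    leaf_labels: list[str]

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (1..k) for a k-cluster cut."""
        return fcluster(self.merges, t=k, criterion="maxclust")


@dataclass
class PcaResult:
    scores: np.ndarray               # samples x components
    loadings: np.ndarray             # exons x components, orthonormal
    explained_variance_ratio: np.ndarray
    mean: np.ndarray                 # per-exon centering vector

    def project(self, new_data: np.ndarray) -> np.ndarray:
        """Project new samples (exons x samples) onto the fitted components."""
        return (new_data - self.mean[:, None]).T @ self.loadings


def ward_cluster(logcpm_subset: np.ndarray, sample_ids: list[str]) -> LinkageTree:
    """Ward variance-minimizing linkage of samples (columns) on Euclidean distance.

    Uses the Ward.D2 update (merge cost = increase in total within-cluster
    sum of squares).
    """
    X = np.asarray(logcpm_subset, dtype=float).T  # samples as rows
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = linkage(X, method="ward")
    return LinkageTree(merges=Z, leaf_labels=list(sample_ids))


def pca(logcpm_subset: np.ndarray, n_components: int = 2) -> PcaResult:
    """PCA of samples on per-exon-centered log-CPM, via SVD; no variance scaling.

    Sign convention: the largest-magnitude loading of each component is
    positive, making the output order-deterministic.
    """
    X = np.asarray(logcpm_subset, dtype=float)
    n_exons, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    max_rank = min(n_exons, n_samples)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds min(dim)={max_rank}")
    mean = X.mean(axis=1)
    Xc = (X - mean[:, None]).T  # samples x exons, each exon centered to mean 0
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fix signs: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s ** 2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return PcaResult(
        scores=(U * s)[:, :n_components],
        loadings=Vt[:n_components].T,
        explained_variance_ratio=evr[:n_components],
        mean=mean,
    )


def leading_logfc_distance(logcpm: np.ndarray, top_k: int = 500) -> np.ndarray:
    """Pairwise "leading log-fold-change" distances between samples.

    The distance between two samples is the root-mean-square of the top_k
    largest absolute per-exon log-CPM differences.
    """
    X = np.asarray(logcpm, dtype=float)
    n_exons, n_samples = X.shape
    if top_k > n_exons:
        import warnings

        warnings.warn(f"top_k={top_k} clipped to exon count {n_exons}")
        top_k = n_exons
    D = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            d2 = (X[:, i] - X[:, j]) ** 2
            top = np.partition(d2, n_exons - top_k)[n_exons - top_k:]
            D[i, j] = D[j, i] = np.sqrt(top.mean())
    return D


def classical_mds(distance: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS from a distance matrix."""
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_components]
    lam = np.maximum(vals[order], 0.0)
    coords = vecs[:, order] * np.sqrt(lam)
    # deterministic signs
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] *= -1
    return coords


def mds_leading_logfc(
    logcpm: np.ndarray, top_k: int = 500, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Leading-logFC distance matrix and its 2-D classical-MDS embedding."""
    if logcpm.shape[1] < 3:
        raise ValueError("need at least 3 samples for an MDS plot")
    D = leading_logfc_distance(logcpm, top_k=top_k)
    return D, classical_mds(D, n_components=n_components)
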