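"""Spectral clustering of the thresholded similarity graph.

Pipeline: threshold the similarity matrix against the reshuffle null and
rescale retained weights into (0, 1]; form the symmetric normalized
Laplacian ``L = I - D^{-1/2} W D^{-1/2}``; choose the number of clusters K
by the largest eigengap among the smallest eigenvalues; embed each node in
the first K eigenvectors, normalize rows to unit norm, and run k-means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .alignment import SimilarityMatrix

UNASSIGNED = -1


@dataclass
class AdjacencyMatrix:
    """Thresholded, rescaled similarity graph.

    ``W[i][j] = 0`` whenever the score is <= theta; retained entries lie in
    (0, 1] after normalization; the diagonal is zero.  Nodes left with zero
    degree are flagged in ``isolated``.
    """

    ids: list[str]
    W: np.ndarray
    theta: float
    normalization: str = "max"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def isolated(self) -> np.ndarray:
        return self.degrees == 0

    def drop_isolated(self) -> "AdjacencyMatrix":
        keep = ~self.isolated
        idx = np.flatnonzero(keep)
        ids = [self.ids[i] for i in idx]
        return AdjacencyMatrix(ids, self.W[np.ix_(idx, idx)], self.theta, self.normalization)


def build_adjacency(
    sim: SimilarityMatrix,
    theta: float,
    normalization: str = "max",
) -> AdjacencyMatrix:
    """Keep scores strictly above theta and rescale them into (0, 1].

    ``normalization='max'`` divides by the maximum retained off-diagonal
    score; ``'minself'`` divides by the smallest self-alignment score;
    ``'none'`` keeps raw scores.
    """
    S = sim.S.copy()
    np.fill_diagonal(S, -np.inf)
    mask = S > theta
    if not mask.any():
        raise ValueError("empty graph: no score exceeds the threshold")
    W = np.where(mask, S, 0.0)
    if normalization == "max":
        W = W / W.max()
    elif normalization == "minself":
        W = W / np.min(np.diag(sim.S))
    elif normalization == "none":
        pass
    else:
        raise ValueError(f"unknown adjacency normalization {normalization!r}")
    np.fill_diagonal(W, 0.0)
    return AdjacencyMatrix(list(sim.ids), W, float(theta), normalization)


@dataclass
class LaplacianSpectrum:
    """Eigendecomposition of the symmetric normalized Laplacian."""

    ids: list[str]
    eigenvalues: np.ndarray   # ascending
    eigenvectors: np.ndarray  # orthonormal columns
    degrees: np.ndarray


def laplacian_spectrum(adj: AdjacencyMatrix) -> LaplacianSpectrum:
    """Full spectrum of ``I - D^{-1/2} W D^{-1/2}``, ascending.

    Isolated nodes must be removed first (their degree is zero and the
    normalization is undefined).
    """
    d = adj.degrees
    if (d == 0).any():
        bad = [adj.ids[i] for i in np.flatnonzero(d == 0)][:5]
        raise ValueError(
            f"zero-degree nodes present (e.g. {bad!r}); call drop_isolated() first"
        )
    inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(len(d)) - (inv_sqrt[:, None] * adj.W) * inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    vals, vecs = scipy.linalg.eigh(L)
    return LaplacianSpectrum(list(adj.ids), vals, vecs, d)


def eigengap_K(
    spectrum: LaplacianSpectrum, k_max: int = 15
) -> tuple[int, np.ndarray]:
    """Number of clusters by the largest gap lambda_{k+1} - lambda_k.

    Ties break toward smaller K.  Returns (K, gap profile for k=1..k_max).
    """
    vals = spectrum.eigenvalues
    if k_max < 1 or k_max > len(vals) - 1:
        raise ValueError("k_max must be in [1, N-1]")
    gaps = np.diff(vals[: k_max + 1])  # gaps[k-1] = lambda_{k+1} - lambda_k
    K = int(np.argmax(gaps)) + 1  # argmax returns the first (smallest K) on ties
    return K, gaps


@dataclass
class ClusterAssignment:
    """k-means result on the row-normalized spectral embedding."""

    ids: list[str]
    K: int
    labels: np.ndarray           # cluster id in 0..K-1, or UNASSIGNED
    embedding: np.ndarray        # N x K row-normalized (zero rows kept as zero)
    centroids: np.ndarray = field(default=None)
    inertia: float = field(default=np.nan)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.ids, (int(l) for l in self.labels)))


def spectral_kmeans(
    spectrum: LaplacianSpectrum,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    restarts: int = 50,
) -> ClusterAssignment:
    """Embed nodes in the first K eigenvectors and cluster with k-means.

    Rows of the embedding are normalized to unit norm; a node whose row is
    numerically zero cannot be normalized and is reported unassigned.
    k-means uses Euclidean distance, ``restarts`` random initializations
    under ``seed`` (best inertia kept) and centroid tolerance ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    U = spectrum.eigenvectors[:, :K]
    norms = np.linalg.norm(U, axis=1)
    ok = norms > 1e-12
    T = np.zeros_like(U)
    T[ok] = U[ok] / norms[ok, None]

    labels = np.full(len(spectrum.ids), UNASSIGNED, dtype=int)
    km = KMeans(
        n_clusters=K,
        n_init=restarts,
        tol=tol,
        random_state=seed,
        init="random",
    )
    labels[ok] = km.fit_predict(T[ok])
    return ClusterAssignment(
        ids=list(spectrum.ids),
        K=K,
        labels=labels,
        embedding=T,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def cluster_promoters(
    sim: SimilarityMatrix,
    theta: float,
    k_max: int = 15,
    seed: int = 0,
    tol: float = 1e-6,
    restarts: int = 50,
    normalization: str = "max",
    K: int | None = None,
) -> ClusterAssignment:
    """End-to-end: threshold, Laplacian, eigengap, k-means.

    Isolated nodes are excluded from the Laplacian and reported with the
    UNASSIGNED label; pass ``K`` to override the eigengap choice.
    """
    adj = build_adjacency(sim, theta, normalization)
    connected = adj.drop_isolated()
    spectrum = laplacian_spectrum(connected)
    if K is None:
        K, _ = eigengap_K(spectrum, min(k_max, len(connected.ids) - 1))
    assign = spectral_kmeans(spectrum, K, seed=seed, tol=tol, restarts=restarts)
    labels = np.full(len(sim.ids), UNASSIGNED, dtype=int)
    pos = {pid: i for i, pid in enumerate(sim.ids)}
    for pid, lab in zip(assign.ids, assign.labels):
        labels[pos[pid]] = lab
    return ClusterAssignment(
        ids=list(sim.ids),
        K=K,
        labels=labels,
        embedding=assign.embedding,
        centroids=assign.centroids,
        inertia=assign.inertia,
    )
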