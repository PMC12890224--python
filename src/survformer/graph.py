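"""Sample-similarity graphs: per-omics KNN kernel graphs, fusion, and the
spectrally normalised convolution matrix used to bias inter-sample attention.

Each omics layer yields a K-nearest-neighbour graph whose edge weights come
from an exponential kernel on squared Euclidean distance,

    w(i, j) = exp(-rho^2(x_i, x_j) / (mu * delta^2)),   j among the K nearest
                                                        neighbours of i,

with delta^2 the median of all pairwise squared distances (a scale-free
normaliser) and mu a per-omics bandwidth (default 0.3 for gene-like layers,
0.2 for microRNA-like layers).  The directed KNN weights are symmetrised by
elementwise max, the per-omics graphs are fused by elementwise averaging
(union of edge sets), and the fused adjacency A is turned into the
convolution matrix

    A_hat = D~^{-1/2} (A + I) D~^{-1/2}

whose positive entries define each sample's attention neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FusedGraph",
    "knn_kernel_graph",
    "fuse_graphs",
    "spectral_normalize",
    "build_fused_graph",
    "attach_test_samples",
    "default_mu",
]

#: per-omics kernel bandwidths by position: first layer gene-like, second
#: microRNA-like, further layers fall back to the gene-like value.
_DEFAULT_MUS = (0.3, 0.2)


def default_mu(layer_index: int) -> float:
    return _DEFAULT_MUS[layer_index] if layer_index < len(_DEFAULT_MUS) else _DEFAULT_MUS[0]


@dataclass
class FusedGraph:
    """Fused multi-omics sample graph and its convolution matrix."""

    per_omics_adjacency: list
    fused_adjacency: np.ndarray
    conv_matrix: np.ndarray
    K: int
    mu: list
    delta_sq: list
    neighbor_sets: list = field(default_factory=list)

    def __post_init__(self):
        if not self.neighbor_sets:
            # neighbourhoods from the fused convolution matrix; self always in
            self.neighbor_sets = [
                set(np.flatnonzero(row > 0)) for row in self.conv_matrix
            ]

    @property
    def n(self) -> int:
        return self.fused_adjacency.shape[0]


def _pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    return cdist(X, X, metric="sqeuclidean")


def median_pairwise_sq_dist(X: np.ndarray) -> float:
    """Median squared Euclidean distance over unordered distinct pairs."""
    D = _pairwise_sq_dists(X)
    iu = np.triu_indices(len(X), k=1)
    return float(np.median(D[iu]))


def knn_kernel_graph(X: np.ndarray, K: int, mu: float,
                     delta_sq: float | None = None) -> np.ndarray:
    """Symmetrised K-nearest-neighbour exponential-kernel adjacency matrix."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < K + 1:
        raise ValueError(f"need at least K+1={K + 1} samples, got {n}")
    D = _pairwise_sq_dists(X)
    if delta_sq is None:
        iu = np.triu_indices(n, k=1)
        delta_sq = float(np.median(D[iu]))
    if delta_sq == 0:
        raise ValueError("degenerate distance distribution: all samples identical")

    W = np.zeros((n, n))
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf  # self excluded from the neighbour set
        nbrs = np.argsort(d, kind="stable")[:K]
        W[i, nbrs] = np.exp(-D[i, nbrs] / (mu * delta_sq))
    return np.maximum(W, W.T)


def fuse_graphs(adjacencies: list) -> np.ndarray:
    """Elementwise mean of the per-omics adjacencies (union of edge sets)."""
    mats = [np.asarray(a, dtype=float) for a in adjacencies]
    shape = mats[0].shape
    for a in mats:
        if a.shape != shape:
            raise ValueError("adjacency shape mismatch")
    return np.mean(mats, axis=0)


def spectral_normalize(A: np.ndarray) -> np.ndarray:
    """A_hat = D~^{-1/2} (A + I) D~^{-1/2}; always well defined (d~_i >= 1)."""
    A = np.asarray(A, dtype=float)
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * np.outer(inv_sqrt, inv_sqrt)


def build_fused_graph(X_list: list, K: int, mus: list | None = None) -> FusedGraph:
    """Per-omics KNN kernel graphs -> fused adjacency -> convolution matrix."""
    if mus is None:
        mus = [default_mu(l) for l in range(len(X_list))]
    delta_sqs = [median_pairwise_sq_dist(np.asarray(X)) for X in X_list]
    adjs = [
        knn_kernel_graph(X, K, mu, ds)
        for X, mu, ds in zip(X_list, mus, delta_sqs)
    ]
    A = fuse_graphs(adjs)
    return FusedGraph(adjs, A, spectral_normalize(A), K, list(mus), delta_sqs)


def attach_test_samples(graph: FusedGraph, X_train_list: list,
                        X_test_list: list) -> FusedGraph:
    """Attach held-out samples to a training graph inductively.

    Each test sample is linked to its K nearest *training* samples per omics,
    using the training kernel scale (delta^2, mu); test-test edges are
    excluded so no information flows between held-out samples.  The
    convolution matrix is recomputed on the combined graph.
    """
    n_tr = graph.n
    n_te = np.asarray(X_test_list[0]).shape[0]
    combined_adjs = []
    for l, (Xtr, Xte) in enumerate(zip(X_train_list, X_test_list)):
        Xtr, Xte = np.asarray(Xtr, float), np.asarray(Xte, float)
        D = cdist(Xte, Xtr, metric="sqeuclidean")
        K = min(graph.K, n_tr)
        W = np.zeros((n_te, n_tr))
        scale = graph.mu[l] * graph.delta_sq[l]
        for i in range(n_te):
            nbrs = np.argsort(D[i], kind="stable")[:K]
            W[i, nbrs] = np.exp(-D[i, nbrs] / scale)
        A_tr = graph.per_omics_adjacency[l]
        A_comb = np.zeros((n_tr + n_te, n_tr + n_te))
        A_comb[:n_tr, :n_tr] = A_tr
        A_comb[n_tr:, :n_tr] = W
        A_comb[:n_tr, n_tr:] = W.T
        combined_adjs.append(A_comb)
    A = fuse_graphs(combined_adjs)
    return FusedGraph(combined_adjs, A, spectral_normalize(A), graph.K,
                      list(graph.mu), list(graph.delta_sq))
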