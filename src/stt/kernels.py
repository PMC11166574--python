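"""Cell-cell transition kernels and their convex mixture.

Three row-stochastic components share one sparsity pattern (the union of
an expression-kNN graph and, when coordinates exist, a spatial-kNN
graph):

* ``velocity_kernel`` — inner-product kernel
  ``w_kl = exp(V_u(k)·(U_l−U_k) + V_s(k)·(S_l−S_k))``, softmax-normalized
  per row (row-max subtracted before exponentiation; exact, softmax is
  shift-invariant);
* ``similarity_kernel`` — Gaussian affinities on expression principal
  components with adaptive per-cell bandwidths, symmetrized then
  Markov-normalized (one diffusion-map step);
* ``spatial_kernel`` — the same Gaussian construction on physical
  coordinates with a global median-distance bandwidth.

``combine_kernels`` mixes them as ``P = w1 Pv + w2 Pc + (1−w1−w2) Ps``;
without spatial data the spatial weight folds into the similarity term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

ROW_SUM_TOL = 1e-10


class GraphError(ValueError):
    pass


class KernelConfigurationError(ValueError):
    pass


@dataclass
class NeighborGraph:
    """Per-cell neighbor index lists (self excluded) on a stated basis."""

    indices: np.ndarray            # (n_cells, k) int
    basis: str                     # "expression_pca" | "spatial" | "union"

    def __post_init__(self):
        idx = np.asarray(self.indices)
        if idx.ndim != 2 or idx.shape[1] < 1:
            raise GraphError("every cell needs at least one neighbor")
        if any((idx[i] == i).any() for i in range(idx.shape[0])):
            raise GraphError("self-loops are not allowed in neighbor lists")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]

    def pattern(self) -> sp.csr_matrix:
        """Boolean adjacency (directed) of the neighbor lists."""
        n, k = self.indices.shape
        rows = np.repeat(np.arange(n), k)
        return sp.csr_matrix(
            (np.ones(n * k), (rows, self.indices.ravel())), shape=(n, n)
        )


@dataclass
class CellRandomWalk:
    """Mixture random walk plus its components and weights."""

    P: sp.csr_matrix
    Pv: sp.csr_matrix
    Pc: sp.csr_matrix
    Ps: Optional[sp.csr_matrix]
    w1: float
    w2: float


def _knn_indices(X: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=min(k + 1, X.shape[0])).fit(X)
    _, idx = nn.kneighbors(X)
    out = np.empty((X.shape[0], idx.shape[1] - 1), dtype=int)
    for i in range(X.shape[0]):
        row = idx[i][idx[i] != i][: idx.shape[1] - 1]
        if len(row) < idx.shape[1] - 1:  # duplicate points: self not in list
            row = np.concatenate([row, idx[i][-1:]])[: idx.shape[1] - 1]
        out[i] = row
    return out


def expression_pca(U: np.ndarray, S: np.ndarray, n_pcs: int = 30,
                   random_state: int = 0) -> np.ndarray:
    """Principal components of the concatenated joint state [U, S]."""
    X = np.hstack([np.asarray(U, float), np.asarray(S, float)])
    n_pcs = min(n_pcs, X.shape[1], X.shape[0] - 1)
    return PCA(n_components=n_pcs, random_state=random_state).fit_transform(X)


def build_neighbor_graph(
    U: np.ndarray, S: np.ndarray, n_neighbors: int = 30, n_pcs: int = 30,
    spatial: Optional[np.ndarray] = None, n_neighbors_spatial: int = 8,
) -> NeighborGraph:
    """Shared sparsity pattern: expression kNN, union spatial kNN if given."""
    Z = expression_pca(U, S, n_pcs=n_pcs)
    idx = _knn_indices(Z, n_neighbors)
    if spatial is None:
        return NeighborGraph(indices=idx, basis="expression_pca")
    idx_sp = _knn_indices(np.asarray(spatial, float), n_neighbors_spatial)
    n = idx.shape[0]
    merged = []
    width = 0
    for i in range(n):
        row = np.unique(np.concatenate([idx[i], idx_sp[i]]))
        merged.append(row)
        width = max(width, len(row))
    # ragged union rows padded by repeating the first entry (harmless: the
    # duplicated edge just receives its weight once in CSR assembly via max)
    out = np.empty((n, width), dtype=int)
    for i, row in enumerate(merged):
        out[i, : len(row)] = row
        out[i, len(row):] = row[0]
    return NeighborGraph(indices=out, basis="union")


def _rows_cols(graph: NeighborGraph):
    n, k = graph.indices.shape
    return np.repeat(np.arange(n), k), graph.indices.ravel()


def _row_normalize_from_weights(graph: NeighborGraph, W: np.ndarray) -> sp.csr_matrix:
    """Assemble CSR from per-edge weights, collapsing duplicate edges, and
    normalize each row to sum to one."""
    n = graph.n_cells
    rows, cols = _rows_cols(graph)
    # padded duplicate edges carry identical weights; CSR assembly sums
    # duplicates, so divide by the multiplicity to recover the raw weight
    A = sp.csr_matrix((W.ravel(), (rows, cols)), shape=(n, n))
    counts = sp.csr_matrix(
        (np.ones_like(rows, dtype=float), (rows, cols)), shape=(n, n)
    )
    A.data = A.data / counts.data
    rs = np.asarray(A.sum(axis=1)).ravel()
    if np.any(rs <= 0):
        raise GraphError("a row of the kernel has zero total weight")
    return (sp.diags(1.0 / rs) @ A).tocsr()


def velocity_kernel(
    V_u: np.ndarray, V_s: np.ndarray, U: np.ndarray, S: np.ndarray,
    graph: NeighborGraph,
) -> sp.csr_matrix:
    """Inner-product velocity kernel, row-softmax over graph neighbors."""
    U = np.asarray(U, float); S = np.asarray(S, float)
    V_u = np.asarray(V_u, float); V_s = np.asarray(V_s, float)
    n, k = graph.indices.shape
    dU = U[graph.indices] - U[:, None, :]          # (n, k, g)
    dS = S[graph.indices] - S[:, None, :]
    logits = np.einsum("ng,nkg->nk", V_u, dU) + np.einsum("ng,nkg->nk", V_s, dS)
    logits -= logits.max(axis=1, keepdims=True)
    W = np.exp(logits)
    return _row_normalize_from_weights(graph, W)


def _gaussian_weights(X: np.ndarray, graph: NeighborGraph,
                      adaptive: bool) -> np.ndarray:
    d = np.linalg.norm(X[graph.indices] - X[:, None, :], axis=2)  # (n, k)
    if adaptive:
        sig = np.median(d, axis=1)
        sig = np.maximum(sig, 1e-12)
        denom = sig[:, None] * sig[graph.indices]
    else:
        s = np.median(d)
        denom = max(s, 1e-12) ** 2
    return np.exp(-(d ** 2) / denom)


def _symmetrized_gaussian(X: np.ndarray, graph: NeighborGraph,
                          adaptive: bool) -> sp.csr_matrix:
    W = _gaussian_weights(X, graph, adaptive)
    n = graph.n_cells
    rows, cols = _rows_cols(graph)
    ones = sp.csr_matrix((np.ones_like(rows, float), (rows, cols)), shape=(n, n))
    A = sp.csr_matrix((W.ravel(), (rows, cols)), shape=(n, n))
    A.data = A.data / ones.data                    # undo duplicate-edge summing
    A = A.maximum(A.T)                             # symmetrize on union pattern
    rs = np.asarray(A.sum(axis=1)).ravel()
    rs = np.maximum(rs, 1e-300)
    return (sp.diags(1.0 / rs) @ A).tocsr()


def similarity_kernel(U: np.ndarray, S: np.ndarray, graph: NeighborGraph,
                      n_pcs: int = 30) -> sp.csr_matrix:
    """Expression-similarity kernel: adaptive Gaussian on joint-state PCs."""
    Z = expression_pca(U, S, n_pcs=n_pcs)
    return _symmetrized_gaussian(Z, graph, adaptive=True)


def spatial_kernel(spatial: np.ndarray, graph: NeighborGraph,
                   bandwidth: Optional[float] = None) -> sp.csr_matrix:
    """Gaussian kernel on physical coordinates (median-distance bandwidth)."""
    if spatial is None:
        raise KernelConfigurationError(
            "no spatial coordinates present; run with spatial weight 0 instead"
        )
    X = np.asarray(spatial, float)
    if bandwidth is None:
        return _symmetrized_gaussian(X, graph, adaptive=False)
    d = np.linalg.norm(X[graph.indices] - X[:, None, :], axis=2)
    W = np.exp(-(d ** 2) / max(bandwidth, 1e-12) ** 2)
    return _row_normalize_from_weights(graph, W)


def combine_kernels(
    Pv: sp.csr_matrix, Pc: sp.csr_matrix, Ps: Optional[sp.csr_matrix],
    w1: float, w2: float,
) -> CellRandomWalk:
    """Convex mixture ``P = w1 Pv + w2 Pc + (1-w1-w2) Ps``.

    Without a spatial component the residual weight is folded into the
    similarity kernel: ``P = w1 Pv + (1-w1) Pc``.
    """
    if w1 < 0 or w2 < 0 or w1 + w2 > 1 + 1e-12:
        raise KernelConfigurationError(
            f"weights must satisfy w1,w2 >= 0 and w1+w2 <= 1; got {w1}, {w2}"
        )
    if Ps is None:
        P = (w1 * Pv + (1.0 - w1) * Pc).tocsr()
    else:
        P = (w1 * Pv + w2 * Pc + (1.0 - w1 - w2) * Ps).tocsr()
    assert_row_stochastic(P)
    return CellRandomWalk(P=P, Pv=Pv, Pc=Pc, Ps=Ps, w1=w1, w2=w2)


def assert_row_stochastic(P: sp.spmatrix, tol: float = ROW_SUM_TOL) -> None:
    rs = np.asarray(P.sum(axis=1)).ravel()
    if np.abs(rs - 1.0).max() > tol:
        raise AssertionError(
            f"matrix is not row-stochastic (max |rowsum-1| = {np.abs(rs - 1).max():.2e})"
        )
    if P.data.size and P.data.min() < 0:
        raise AssertionError("negative transition probability")
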