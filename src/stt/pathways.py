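"""Pathway-level tensor similarity: velocity graphs, correlation, clusters.

For each gene set overlapping the selected multistability genes by at
least ``min_overlap``, a cosine-kernel velocity graph is computed on the
shared cell kNN pattern from the gene-set-restricted averaged tensor.
Pathway graphs are flattened on one shared edge ordering, compared by
Pearson correlation, embedded (UMAP on the principal components of the
correlation matrix) and clustered with k-means, choosing k by mean
silhouette.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .kernels import NeighborGraph

log = logging.getLogger(__name__)


class PathwayAnalysisError(RuntimeError):
    pass


def read_gmt(path) -> Dict[str, list]:
    """Read a GMT gene-set file into ``{pathway: [genes]}``."""
    from gseapy.parser import read_gmt as _read_gmt

    return {k: list(v) for k, v in _read_gmt(str(path)).items()}


def pathway_velocity_graph(
    V_u: np.ndarray, V_s: np.ndarray, U: np.ndarray, S: np.ndarray,
    gene_idx: Sequence[int], graph: NeighborGraph,
) -> np.ndarray:
    """Cosine similarities between restricted velocity and displacement.

    Returns an (n_cells, k_neighbors) array aligned with
    ``graph.indices``: entry (k, j) is the cosine between cell k's joint
    velocity and the joint displacement toward its j-th neighbor, both
    restricted to ``gene_idx``.
    """
    gene_idx = np.asarray(gene_idx, dtype=int)
    V = np.hstack([np.asarray(V_u, float)[:, gene_idx],
                   np.asarray(V_s, float)[:, gene_idx]])
    X = np.hstack([np.asarray(U, float)[:, gene_idx],
                   np.asarray(S, float)[:, gene_idx]])
    idx = graph.indices
    dX = X[idx] - X[:, None, :]
    denom = np.linalg.norm(dX, axis=2) * np.linalg.norm(V, axis=1)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("nkg,ng->nk", dX, V) / denom
    return np.nan_to_num(cos, nan=0.0)


@dataclass
class PathwayTensorAnalysis:
    pathway_names: list
    gene_overlap: dict
    min_overlap: int
    corr: np.ndarray
    embedding2d: np.ndarray
    cluster_labels: np.ndarray
    chosen_k: int
    silhouette_by_k: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pathway": self.pathway_names,
            "n_genes_overlap": [len(self.gene_overlap[p]) for p in self.pathway_names],
            "cluster": self.cluster_labels,
            "x": self.embedding2d[:, 0],
            "y": self.embedding2d[:, 1],
        }).set_index("pathway")


def pathway_similarity_and_cluster(
    V_u: np.ndarray, V_s: np.ndarray, U: np.ndarray, S: np.ndarray,
    graph: NeighborGraph, gene_sets: Dict[str, Sequence[str]],
    selected_genes: Sequence[int], gene_names: Sequence[str],
    min_overlap: int = 3, seed: int = 0, max_k: int = 10,
) -> PathwayTensorAnalysis:
    """Correlate, embed and cluster pathway velocity graphs.

    Pathways overlapping the selected multistability genes by fewer
    than ``min_overlap`` genes are skipped (logged, never an error);
    fewer than three surviving pathways aborts with an overlap report.
    Missing graph entries are zero-filled so all flattened vectors share
    one edge ordering and length.
    """
    name_to_idx = {str(g): i for i, g in enumerate(gene_names)}
    selected = set(int(i) for i in _as_indices(selected_genes))
    overlaps, graphs, skipped = {}, {}, {}
    for pw, genes in gene_sets.items():
        idx = sorted(
            name_to_idx[g] for g in map(str, genes)
            if g in name_to_idx and name_to_idx[g] in selected
        )
        if len(idx) < min_overlap:
            skipped[pw] = len(idx)
            log.info("pathway %s skipped: overlap %d < %d", pw, len(idx), min_overlap)
            continue
        overlaps[pw] = idx
        graphs[pw] = pathway_velocity_graph(V_u, V_s, U, S, idx, graph).ravel()
    names = sorted(overlaps)
    if len(names) < 3:
        raise PathwayAnalysisError(
            f"only {len(names)} pathways pass the overlap filter "
            f"(min_overlap={min_overlap}); overlaps of skipped: {skipped}"
        )
    M = np.vstack([graphs[p] for p in names])
    corr = np.corrcoef(M)
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)

    n_pc = min(10, len(names) - 1)
    Z = PCA(n_components=n_pc, random_state=seed).fit_transform(corr)
    emb = _umap_embed(Z, seed, n_neighbors=min(15, len(names) - 1))

    best_k, best_s, labels, by_k = 2, -np.inf, None, {}
    for k in range(2, min(max_k, len(names) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
        if len(np.unique(km.labels_)) < 2:
            continue
        s = silhouette_score(emb, km.labels_)
        by_k[k] = float(s)
        if s > best_s:
            best_k, best_s, labels = k, s, km.labels_
    if labels is None:
        labels = np.zeros(len(names), dtype=int)
        best_k = 1
    return PathwayTensorAnalysis(
        pathway_names=names, gene_overlap=overlaps, min_overlap=min_overlap,
        corr=corr, embedding2d=emb, cluster_labels=labels, chosen_k=best_k,
        silhouette_by_k=by_k, skipped=skipped,
    )


def _umap_embed(Z: np.ndarray, seed: int, n_neighbors: int = 15) -> np.ndarray:
    import umap

    n_neighbors = max(2, min(n_neighbors, Z.shape[0] - 1))
    # spectral initialization is ill-posed for a handful of points
    init = "random" if Z.shape[0] < 10 else "spectral"
    reducer = umap.UMAP(n_components=2, random_state=seed,
                        n_neighbors=n_neighbors, init=init)
    return np.asarray(reducer.fit_transform(Z), dtype=float)


def _as_indices(x):
    """Flatten index-like input to a 1-D integer array."""
    return np.asarray(x, dtype=int).ravel()
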