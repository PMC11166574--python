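"""Joint unspliced/spliced expression data container and I/O.

The universal input is a pair of cell-by-gene count matrices (unspliced U,
spliced S) with optional physical coordinates and an initial cell-state
labelling used to seed the attractor decomposition.  On disk the container
is an AnnData ``.h5ad`` file with layers ``"unspliced"``/``"spliced"``,
which is the community convention for splicing-aware single-cell data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
import anndata as ad


def _to_dense(x) -> np.ndarray:
    """Return a dense float ndarray view of a dense or sparse matrix."""
    if sp.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


class DatasetFormatError(ValueError):
    """Raised when an on-disk container lacks a required layer or key."""


@dataclass
class ExpressionDataset:
    """Cell x gene unspliced/spliced matrices plus optional annotations.

    Parameters
    ----------
    U, S
        Nonnegative matrices of shape ``(n_cells, n_genes)``; dense or
        sparse accepted, stored as given.
    gene_names, cell_ids
        Identifiers; generated as ``g0..``/``c0..`` when omitted.
    spatial
        Optional ``(n_cells, 2)`` or ``(n_cells, 3)`` physical coordinates.
    initial_labels
        Optional categorical vector of length ``n_cells`` seeding the
        attractor memberships (needs >= 2 distinct categories downstream).
    true_velocity_u, true_velocity_s
        Ground-truth drift layers, present only for simulated data.
    """

    U: np.ndarray
    S: np.ndarray
    gene_names: Sequence[str] = None
    cell_ids: Sequence[str] = None
    spatial: Optional[np.ndarray] = None
    initial_labels: Optional[np.ndarray] = None
    true_velocity_u: Optional[np.ndarray] = None
    true_velocity_s: Optional[np.ndarray] = None
    obs: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self):
        U, S = self.U, self.S
        if U.shape != S.shape:
            raise ValueError(
                f"U and S must have identical shape; got {U.shape} vs {S.shape}"
            )
        for name, M in (("U", U), ("S", S)):
            Md = _to_dense(M)
            if not np.all(np.isfinite(Md)):
                raise ValueError(f"{name} contains non-finite entries")
            if Md.min() < 0:
                raise ValueError(f"{name} contains negative entries")
        n_c, n_g = U.shape
        if self.gene_names is None:
            self.gene_names = [f"g{i}" for i in range(n_g)]
        if self.cell_ids is None:
            self.cell_ids = [f"c{i}" for i in range(n_c)]
        if len(self.gene_names) != n_g or len(self.cell_ids) != n_c:
            raise ValueError("identifier lengths do not match matrix shape")
        if self.spatial is not None:
            self.spatial = np.asarray(self.spatial, dtype=float)
            if self.spatial.shape[0] != n_c or self.spatial.ndim != 2:
                raise ValueError(
                    f"spatial must have {n_c} rows; got shape {self.spatial.shape}"
                )
        if self.initial_labels is not None:
            self.initial_labels = np.asarray(self.initial_labels)
            if len(self.initial_labels) != n_c:
                raise ValueError("initial_labels length does not match n_cells")
        if self.obs is None:
            self.obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell"))

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.U.shape[0]

    @property
    def n_genes(self) -> int:
        return self.U.shape[1]

    def dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense float copies of (U, S)."""
        return _to_dense(self.U), _to_dense(self.S)

    def nonconstant_gene_mask(self) -> np.ndarray:
        """Genes with positive variance in U or S.

        Genes constant in both layers make the multistability score
        undefined and are excluded from kinetic estimation.
        """
        U, S = self.dense()
        return (U.var(axis=0) + S.var(axis=0)) > 0

    # -- AnnData bridge --------------------------------------------------
    def to_anndata(self) -> AnnData:
        adata = AnnData(
            X=self.S if sp.issparse(self.S) else np.asarray(self.S, dtype=float),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=pd.Index(list(self.gene_names), name="gene")),
        )
        adata.obs_names = [str(c) for c in self.cell_ids]
        adata.layers["unspliced"] = self.U
        adata.layers["spliced"] = self.S
        if self.true_velocity_u is not None:
            adata.layers["velocity_u_true"] = self.true_velocity_u
            adata.layers["velocity_s_true"] = self.true_velocity_s
        if self.spatial is not None:
            adata.obsm["X_spatial"] = self.spatial
        if self.initial_labels is not None:
            adata.obs["initial_label"] = pd.Categorical(
                [str(v) for v in self.initial_labels]
            )
        return adata

    @classmethod
    def from_anndata(
        cls,
        adata: AnnData,
        layer_names: tuple[str, str] = ("unspliced", "spliced"),
        label_key: Optional[str] = "initial_label",
        spatial_key: Optional[str] = "X_spatial",
    ) -> "ExpressionDataset":
        u_key, s_key = layer_names
        for key in (u_key, s_key):
            if key not in adata.layers:
                raise DatasetFormatError(f"required layer {key!r} missing from file")
        U, S = adata.layers[u_key], adata.layers[s_key]
        if U.shape != S.shape:
            raise ValueError(
                f"layer shapes differ: {u_key}={U.shape}, {s_key}={S.shape}"
            )
        labels = None
        if label_key is not None and label_key in adata.obs:
            labels = np.asarray(adata.obs[label_key].astype(str))
        spatial = None
        if spatial_key is not None and spatial_key in adata.obsm:
            spatial = np.asarray(adata.obsm[spatial_key])
        tv_u = adata.layers.get("velocity_u_true")
        tv_s = adata.layers.get("velocity_s_true")
        return cls(
            U=U,
            S=S,
            gene_names=list(adata.var_names),
            cell_ids=list(adata.obs_names),
            spatial=spatial,
            initial_labels=labels,
            true_velocity_u=None if tv_u is None else np.asarray(tv_u),
            true_velocity_s=None if tv_s is None else np.asarray(tv_s),
            obs=adata.obs.copy(),
        )


def read_dataset(
    path,
    layer_names: tuple[str, str] = ("unspliced", "spliced"),
    label_key: Optional[str] = "initial_label",
    spatial_key: Optional[str] = "X_spatial",
) -> ExpressionDataset:
    """Read an ``.h5ad`` container into an :class:`ExpressionDataset`.

    Missing optional keys (labels, spatial) yield absent fields, never
    errors; a missing required layer raises :class:`DatasetFormatError`.
    """
    adata = ad.read_h5ad(path)
    return ExpressionDataset.from_anndata(
        adata, layer_names=layer_names, label_key=label_key, spatial_key=spatial_key
    )


def write_dataset(ds: ExpressionDataset, path) -> None:
    """Write the dataset as ``.h5ad``; :func:`read_dataset` inverts it."""
    ds.to_anndata().write_h5ad(path)


def smooth_moments(ds: ExpressionDataset, n_neighbors: int) -> ExpressionDataset:
    """kNN first-moment smoothing of U and S (optional, off by default).

    Neighbours (self included) are found in the top principal components
    of the concatenated ``[U, S]`` matrix; each cell's counts are replaced
    by the mean over its neighbourhood.  ``n_neighbors=1`` is the identity.
    """
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    if ds.n_cells < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} cells, have {ds.n_cells}"
        )
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    U, S = ds.dense()
    X = np.hstack([U, S])
    n_pcs = min(30, X.shape[1], ds.n_cells - 1)
    Z = PCA(n_components=n_pcs, random_state=0).fit_transform(X)
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(Z)
    _, idx = nn.kneighbors(Z)
    U_s = U[idx].mean(axis=1)
    S_s = S[idx].mean(axis=1)
    return replace(ds, U=U_s, S=S_s)
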