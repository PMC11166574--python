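"""The spatial transition tensor model and its fitted results.

:class:`STTModel` holds an :class:`~stt.datasets.ExpressionDataset` plus
hyperparameters; :meth:`STTModel.fit` runs the alternating scheme

1. estimate attractor-wise kinetics (alpha_c, beta) on the training fold
   with the current memberships rho^n;
2. score genes for multistability on the held-out fold and refilter the
   gene set used for the velocity kernel;
3. rebuild the transition tensor, average it with rho^n, construct the
   mixed cellular random walk, and re-decompose it (GPCCA) into rho^{n+1};
4. stop when the mean absolute membership change (after Hungarian column
   matching) falls below tolerance, or at ``max_iter``.

The returned :class:`STTResults` carries estimates, memberships,
entropies, the coarse-grained chain, per-round diagnostics and a
``summary()`` table, and exposes the downstream analyses (dynamical
manifold, transition paths, streamlines, pathway similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import kinetics, kernels
from .coarse import (CoarseChain, Membership, averaged_velocity, entropy,
                     gpcca_decompose, match_columns)
from .datasets import ExpressionDataset


class InitializationError(ValueError):
    pass


class GeneFilterError(RuntimeError):
    """Raised when too few genes pass the multistability threshold."""


def initialize_membership(labels: Sequence) -> tuple[Membership, np.ndarray]:
    """One-hot memberships from categorical initial labels.

    Returns the membership and the ordered category array; requires at
    least two nonempty categories.
    """
    labels = np.asarray(labels)
    cats, codes = np.unique(labels, return_inverse=True)
    if len(cats) < 2:
        raise InitializationError("need >= 2 initial clusters to seed attractors")
    rho = np.zeros((len(labels), len(cats)))
    rho[np.arange(len(labels)), codes] = 1.0
    return Membership(rho=rho), cats


def train_test_split_stratified(
    assignment: np.ndarray, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index split with ``|train| = round(train_fraction * n)``, stratified
    by the hard assignment so small attractors appear in both folds."""
    n = len(assignment)
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)
    order = []
    for c in np.unique(assignment):
        idx = np.flatnonzero(assignment == c)
        rng.shuffle(idx)
        order.append(idx)
    # interleave strata so truncation at n_train keeps proportions
    interleaved = np.concatenate(order)
    prio = np.concatenate([np.linspace(0, 1, len(ix), endpoint=False) for ix in order])
    interleaved = interleaved[np.argsort(prio, kind="stable")]
    train = np.sort(interleaved[:n_train])
    test = np.sort(interleaved[n_train:])
    return train, test


@dataclass
class IterationState:
    """Diagnostics for one round of the alternating scheme."""

    round: int
    params: kinetics.KineticParams
    membership: Membership
    train_scores: np.ndarray
    test_scores: np.ndarray
    selected_genes: np.ndarray
    delta_membership: float
    converged: bool = False

    @property
    def selected_gene_count(self) -> int:
        return len(self.selected_genes)


def monitor_report(state: IterationState, gene_names=None) -> dict:
    """Structured per-round monitor record (train/test score summary)."""
    tr, te = state.train_scores, state.test_scores
    fin_tr, fin_te = tr[np.isfinite(tr)], te[np.isfinite(te)]
    rec = {
        "round": state.round,
        "n_selected": state.selected_gene_count,
        "delta_membership": state.delta_membership,
        "train_score_median": float(np.median(fin_tr)) if len(fin_tr) else None,
        "test_score_median": float(np.median(fin_te)) if len(fin_te) else None,
        "train_score_max": float(fin_tr.max()) if len(fin_tr) else None,
        "test_score_max": float(fin_te.max()) if len(fin_te) else None,
        "converged": state.converged,
    }
    if state.selected_gene_count == 0:
        rec["recommendation"] = "no gene passes the threshold; lower it or stop"
    if gene_names is not None:
        rec["selected_gene_names"] = [str(gene_names[i]) for i in state.selected_genes]
    return rec


class STTModel:
    """Multistable splicing-kinetics model of a single-cell dataset.

    Parameters
    ----------
    data
        Joint unspliced/spliced dataset (optionally spatial).
    k
        Number of attractors; defaults to the number of initial-label
        categories.
    w1, w2
        Mixture weights of the velocity and expression-similarity
        kernels (remainder goes to the spatial kernel when coordinates
        are present; otherwise it folds into the similarity term).
    lam
        Ridge strength of the kinetic estimator.
    score_threshold
        Multistability-score cutoff for the gene filter.
    n_neighbors, n_pcs, n_neighbors_spatial
        Neighbor-graph geometry.
    train_fraction
        Fraction of cells used to fit kinetics; the rest scores genes.
    """

    def __init__(
        self,
        data: ExpressionDataset,
        k: Optional[int] = None,
        w1: float = 0.5,
        w2: float = 0.3,
        lam: float = 0.01,
        score_threshold: float = 0.5,
        n_neighbors: int = 30,
        n_pcs: int = 30,
        n_neighbors_spatial: int = 8,
        train_fraction: float = 0.8,
        min_genes: int = 3,
        refilter_every_round: bool = True,
    ):
        self.data = data
        if data.initial_labels is None:
            raise InitializationError(
                "dataset has no initial labels; provide clustering output "
                "(e.g. Leiden/Louvain) in initial_labels"
            )
        self.membership0, self.categories = initialize_membership(data.initial_labels)
        self.k = int(k) if k is not None else self.membership0.n_attractors
        if self.k != self.membership0.n_attractors and k is not None:
            # user override: re-seed by merging/splitting is out of scope,
            # keep one-hot of labels only when K matches
            raise InitializationError(
                f"k={k} does not match the {self.membership0.n_attractors} "
                "initial label categories"
            )
        if not (0 <= w1 and 0 <= w2 and w1 + w2 <= 1):
            raise ValueError("weights must satisfy w1,w2 >= 0, w1+w2 <= 1")
        self.w1, self.w2, self.lam = w1, w2, lam
        self.score_threshold = score_threshold
        self.n_neighbors = n_neighbors
        self.n_pcs = n_pcs
        self.n_neighbors_spatial = n_neighbors_spatial
        self.train_fraction = train_fraction
        self.min_genes = min(min_genes, data.n_genes)
        self.refilter_every_round = refilter_every_round

        U, S = data.dense()
        self._U, self._S = U, S
        self._gene_mask = data.nonconstant_gene_mask()
        self.graph = kernels.build_neighbor_graph(
            U, S, n_neighbors=min(n_neighbors, data.n_cells - 1), n_pcs=n_pcs,
            spatial=data.spatial, n_neighbors_spatial=n_neighbors_spatial,
        )
        self._Pc = kernels.similarity_kernel(U, S, self.graph, n_pcs=n_pcs)
        self._Ps = (
            kernels.spatial_kernel(data.spatial, self.graph)
            if data.spatial is not None else None
        )

    # -- one full round --------------------------------------------------
    def _round(self, rho: np.ndarray, train_idx, test_idx, selected):
        U, S = self._U, self._S
        params = kinetics.estimate_params(
            U[train_idx], S[train_idx], rho[train_idx], lam=self.lam
        )
        train_scores = kinetics.multistability_score(
            U[train_idx], S[train_idx], params, rho[train_idx],
            threshold=self.score_threshold,
        ).score
        test_scores = kinetics.multistability_score(
            U[test_idx], S[test_idx], params, rho[test_idx],
            threshold=self.score_threshold,
        ).score
        if self.refilter_every_round or selected is None:
            sel = np.flatnonzero(
                (test_scores > self.score_threshold) & self._gene_mask
            )
        else:
            sel = selected
        if len(sel) < self.min_genes:
            raise GeneFilterError(
                f"only {len(sel)} genes pass multistability threshold "
                f"{self.score_threshold}; lower the threshold (monitor the "
                "train/test score distributions)"
            )
        tensor = kinetics.build_tensor(U, S, params)
        Vu, Vs = averaged_velocity(tensor, Membership(rho=rho))
        Pv = kernels.velocity_kernel(
            Vu[:, sel], Vs[:, sel], U[:, sel], S[:, sel], self.graph
        )
        walk = kernels.combine_kernels(Pv, self._Pc, self._Ps, self.w1, self.w2)
        m_new, chain = gpcca_decompose(walk.P, self.k)
        rho_new = match_columns(m_new.rho, rho)
        return params, rho_new, chain, train_scores, test_scores, sel, tensor, walk

    def fit(
        self,
        max_iter: int = 20,
        tol: float = 1e-3,
        seed: int = 42,
        callback: Optional[Callable[[dict], Optional[bool]]] = None,
    ) -> "STTResults":
        """Run the alternating scheme to convergence.

        ``callback`` receives each round's monitor record; returning
        ``True`` from it stops the iteration early (the scriptable
        analogue of interactive control).
        """
        rho = self.membership0.rho.copy()
        train_idx, test_idx = train_test_split_stratified(
            rho.argmax(axis=1), self.train_fraction, seed
        )
        history: list[IterationState] = []
        params = chain = tensor = walk = None
        tr = te = sel = None
        converged = False
        n_rounds = max(max_iter, 0)
        for n in range(n_rounds):
            params, rho_new, chain, tr, te, sel, tensor, walk = self._round(
                rho, train_idx, test_idx, sel
            )
            delta = float(np.abs(rho_new - rho).mean())
            state = IterationState(
                round=n, params=params, membership=Membership(rho=rho_new),
                train_scores=tr, test_scores=te, selected_genes=sel,
                delta_membership=delta,
            )
            rho = rho_new
            converged = delta < tol
            state.converged = converged
            history.append(state)
            if callback is not None:
                if callback(monitor_report(state, self.data.gene_names)):
                    break
            if converged:
                break
        if params is None:
            # max_iter = 0: pure estimation from the initialization
            params = kinetics.estimate_params(
                self._U[train_idx], self._S[train_idx], rho[train_idx],
                lam=self.lam,
            )
            tr = kinetics.multistability_score(
                self._U[train_idx], self._S[train_idx], params, rho[train_idx],
                threshold=self.score_threshold).score
            te = kinetics.multistability_score(
                self._U[test_idx], self._S[test_idx], params, rho[test_idx],
                threshold=self.score_threshold).score
            sel = np.flatnonzero((te > self.score_threshold) & self._gene_mask)
            tensor = kinetics.build_tensor(self._U, self._S, params)
            chain = None
            walk = None
        return STTResults(
            model=self, params=params, membership=Membership(rho=rho),
            chain=chain, tensor=tensor, walk=walk, train_scores=tr,
            test_scores=te, selected_genes=sel, history=history,
            converged=converged, train_idx=train_idx, test_idx=test_idx,
            seed=seed,
        )


@dataclass
class STTResults:
    """Fitted transition-tensor model: estimates, memberships, dynamics."""

    model: STTModel
    params: kinetics.KineticParams
    membership: Membership
    chain: Optional[CoarseChain]
    tensor: np.ndarray
    walk: Optional[kernels.CellRandomWalk]
    train_scores: np.ndarray
    test_scores: np.ndarray
    selected_genes: np.ndarray
    history: list = field(default_factory=list)
    converged: bool = False
    train_idx: np.ndarray = None
    test_idx: np.ndarray = None
    seed: int = 42

    # -- derived quantities ---------------------------------------------
    @property
    def rho(self) -> np.ndarray:
        return self.membership.rho

    @property
    def entropy(self) -> np.ndarray:
        return entropy(self.membership)

    @property
    def attractor(self) -> np.ndarray:
        return self.membership.hard_assignment

    def averaged_velocity(self):
        """Membership-averaged (V_u, V_s) over the attractor axis."""
        return averaged_velocity(self.tensor, self.membership)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        g = self.model.data.gene_names
        lines = [
            "Spatial transition tensor fit",
            "=" * 64,
            f"cells: {self.model.data.n_cells}   genes: {self.model.data.n_genes}"
            f"   attractors: {self.membership.n_attractors}",
            f"rounds run: {len(self.history)}   converged: {self.converged}",
            f"selected multistable genes: {len(self.selected_genes)} "
            f"(threshold {self.model.score_threshold})",
            f"kernel weights: w1={self.model.w1} w2={self.model.w2}"
            f"   lambda={self.model.lam}",
            "",
            self.param_table().to_string(),
        ]
        if self.chain is not None:
            lines += [
                "",
                "coarse-grained transition matrix P_cg:",
                pd.DataFrame(
                    self.chain.P_cg,
                    index=[f"attr{i}" for i in range(self.chain.P_cg.shape[0])],
                    columns=[f"attr{i}" for i in range(self.chain.P_cg.shape[0])],
                ).round(4).to_string(),
                "stationary distribution: "
                + np.array2string(self.chain.pi, precision=4),
            ]
        return "\n".join(lines)

    def param_table(self) -> pd.DataFrame:
        """Per-gene kinetic estimates and multistability scores."""
        g = list(self.model.data.gene_names)
        tab = pd.DataFrame({"gene": g, "beta": self.params.beta})
        for c in range(self.params.n_attractors):
            tab[f"alpha_{c}"] = self.params.alpha[c]
        tab["score_train"] = self.train_scores
        tab["score_test"] = self.test_scores
        tab["selected"] = np.isin(np.arange(len(g)), self.selected_genes)
        return tab.set_index("gene")

    def to_anndata(self):
        """Annotated container with memberships, entropy and tensor layers."""
        adata = self.model.data.to_anndata()
        adata.obs["attractor"] = pd.Categorical(
            [f"attr{i}" for i in self.attractor]
        )
        adata.obs["entropy"] = self.entropy
        for c in range(self.membership.n_attractors):
            adata.obs[f"rho_{c + 1}"] = self.rho[:, c]
            adata.layers[f"velocity_u_{c}"] = self.tensor[:, 0, c, :]
            adata.layers[f"velocity_s_{c}"] = self.tensor[:, 1, c, :]
        Vu, Vs = self.averaged_velocity()
        adata.layers["velocity_u"] = Vu
        adata.layers["velocity_s"] = Vs
        if self.chain is not None:
            adata.uns["P_cg"] = self.chain.P_cg
            adata.uns["pi_cg"] = self.chain.pi
        adata.var["multistability_score"] = self.test_scores
        return adata

    # -- downstream analyses ----------------------------------------------
    def build_manifold(self, embedding=None, seed: Optional[int] = None):
        from .dynamics import build_manifold

        if embedding is None:
            embedding = kernels.expression_pca(
                self.model._U, self.model._S, n_pcs=2
            )
        return build_manifold(
            self.membership, embedding, self.chain,
            seed=self.seed if seed is None else seed,
        )

    def transition_paths(self, source, target):
        from .dynamics import transition_paths

        if self.chain is None:
            raise ValueError("no coarse chain available (max_iter=0 fit)")
        return transition_paths(self.chain, source, target)

    def project_streamlines(self, embedding=None, mode: str = "nonlinear",
                            attractor: Optional[int] = None,
                            membership_cutoff: float = 0.2):
        from .dynamics import project_streamlines

        if embedding is None:
            embedding = kernels.expression_pca(
                self.model._U, self.model._S, n_pcs=2
            )
        if attractor is None:
            Vu, Vs = self.averaged_velocity()
            mask = None
        else:
            Vu = self.tensor[:, 0, attractor, :]
            Vs = self.tensor[:, 1, attractor, :]
            mask = self.rho[:, attractor] > membership_cutoff
        arrows = project_streamlines(
            Vu, Vs, self.model._U, self.model._S, embedding, self.model.graph,
            mode=mode,
        )
        if mask is not None:
            arrows = arrows.copy()
            arrows[~mask] = 0.0
        return arrows

    def pathway_analysis(self, gene_sets: dict, min_overlap: int = 3,
                         seed: Optional[int] = None):
        from .pathways import pathway_similarity_and_cluster

        Vu, Vs = self.averaged_velocity()
        return pathway_similarity_and_cluster(
            Vu, Vs, self.model._U, self.model._S, self.model.graph,
            gene_sets=gene_sets,
            selected_genes=self.selected_genes,
            gene_names=list(self.model.data.gene_names),
            min_overlap=min_overlap,
            seed=self.seed if seed is None else seed,
        )
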