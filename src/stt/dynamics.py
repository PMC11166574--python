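"""Dynamical manifold, transition-path theory and streamline projection.

The dynamical manifold places each cell at the membership-weighted
average of attractor centers in a 2-D embedding, fits a K-component
Gaussian mixture to those positions (EM, initialized at the centers
with the coarse chain's stationary weights) and exposes the landscape
``phi(y) = -ln P(y)`` on a rectangular grid.

Transition-path theory runs on the coarse K-state chain: forward and
backward committors by linear solve, Metzner-style net reactive flux
``f+_ij = max(f_ij - f_ji, 0)`` with ``f_ij = pi_i q-_i P_ij q+_j``,
and a greedy widest-path decomposition into ranked attractor sequences
with their fractions of the total flux.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .coarse import CoarseChain, Membership
from .kernels import NeighborGraph

COMMITTOR_TOL = 1e-10


# ---------------------------------------------------------------------------
# dynamical manifold
# ---------------------------------------------------------------------------

@dataclass
class DynamicalManifold:
    """Membership-weighted 2-D positions with a mixture landscape."""

    y: np.ndarray            # (n_cells, 2)
    mu: np.ndarray           # (K, 2) attractor centers
    gmm: GaussianMixture
    grid_x: np.ndarray
    grid_y: np.ndarray
    phi: np.ndarray          # (grid, grid) landscape -ln P(y)

    def landscape_at(self, points: np.ndarray) -> np.ndarray:
        logp = self.gmm.score_samples(points)
        return -np.maximum(logp, np.log(1e-12))


def build_manifold(
    m: Membership,
    embedding: np.ndarray,
    chain: Optional[CoarseChain],
    grid_size: int = 200,
    seed: int = 0,
) -> DynamicalManifold:
    """Fit the mixture landscape over membership-weighted cell positions.

    ``mu_c`` is the membership-weighted mean of the embedding per
    attractor; ``y_k = sum_c rho_kc mu_c``.  The EM fit is initialized
    with component weights from the coarse chain's stationary
    distribution (uniform if absent) and means at ``mu_c``.
    """
    embedding = np.asarray(embedding, float)
    if embedding.ndim != 2 or embedding.shape[1] != 2:
        raise ValueError("embedding must be (n_cells, 2)")
    rho = m.rho
    K = rho.shape[1]
    w = rho.sum(axis=0)
    mu = (rho.T @ embedding) / np.maximum(w, 1e-300)[:, None]
    y = rho @ mu

    weights0 = chain.pi if chain is not None else np.full(K, 1.0 / K)
    weights0 = np.maximum(weights0, 1e-12)
    weights0 = weights0 / weights0.sum()
    span = max(np.ptp(y[:, 0]), np.ptp(y[:, 1]), 1e-6)
    gmm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        weights_init=weights0,
        means_init=mu,
        reg_covar=1e-6 * span ** 2,
        random_state=seed,
    )
    gmm.fit(y)

    pad = 0.1
    x0, x1 = y[:, 0].min(), y[:, 0].max()
    y0, y1 = y[:, 1].min(), y[:, 1].max()
    dx, dy = max(x1 - x0, 1e-6), max(y1 - y0, 1e-6)
    gx = np.linspace(x0 - pad * dx, x1 + pad * dx, grid_size)
    gy = np.linspace(y0 - pad * dy, y1 + pad * dy, grid_size)
    XX, YY = np.meshgrid(gx, gy)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    dens = np.exp(gmm.score_samples(pts))
    phi = -np.log(np.maximum(dens, 1e-12)).reshape(grid_size, grid_size)
    return DynamicalManifold(y=y, mu=mu, gmm=gmm, grid_x=gx, grid_y=gy, phi=phi)


# ---------------------------------------------------------------------------
# transition path theory
# ---------------------------------------------------------------------------

@dataclass
class TransitionPathResult:
    source: tuple
    target: tuple
    q_plus: np.ndarray
    q_minus: np.ndarray
    flux_matrix: np.ndarray      # net reactive flux f+
    gross_flux: np.ndarray       # f_ij before netting
    rate: float                  # total reactive flux out of the source
    paths: list = field(default_factory=list)        # [(tuple(path), fraction)]
    unreachable: bool = False


def _committor_forward(P: np.ndarray, source, target) -> np.ndarray:
    n = P.shape[0]
    q = np.zeros(n)
    q[list(target)] = 1.0
    interior = [i for i in range(n) if i not in source and i not in target]
    if interior:
        A = np.eye(len(interior)) - P[np.ix_(interior, interior)]
        b = P[np.ix_(interior, list(target))].sum(axis=1)
        q[interior] = np.linalg.solve(A, b)
    return q


def transition_paths(
    chain: CoarseChain, source: Sequence[int], target: Sequence[int],
    max_paths: int = 100,
) -> TransitionPathResult:
    """Committors, net reactive flux and ranked pathways on the coarse chain.

    The backward committor uses the time-reversed chain
    ``P~_ij = pi_j P_ji / pi_i`` so nonreversible dynamics are handled.
    Pathways are extracted greedily: repeatedly take the widest
    (max-bottleneck) source-to-target path through the net-flux graph,
    record its bottleneck capacity as its flux, and subtract it.
    """
    P = np.asarray(chain.P_cg, float)
    pi = np.asarray(chain.pi, float)
    n = P.shape[0]
    source = tuple(sorted(set(int(s) for s in source)))
    target = tuple(sorted(set(int(t) for t in target)))
    if not source or not target or set(source) & set(target):
        raise ValueError("source and target must be disjoint nonempty sets")

    q_plus = _committor_forward(P, source, target)
    pi_safe = np.maximum(pi, 1e-300)
    P_rev = P.T * pi_safe[None, :] / pi_safe[:, None]  # P~_ij = pi_j P_ji / pi_i
    # q_minus: probability of having come from source; committor of the
    # reversed chain toward the source set
    q_minus = _committor_forward(P_rev, target, source)

    f = pi[:, None] * q_minus[:, None] * P * q_plus[None, :]
    np.fill_diagonal(f, 0.0)
    fnet = np.maximum(f - f.T, 0.0)
    rate = float(fnet[list(source), :].sum() - fnet[:, list(source)].sum())
    rate = max(rate, 0.0)

    result = TransitionPathResult(
        source=source, target=target, q_plus=q_plus, q_minus=q_minus,
        flux_matrix=fnet, gross_flux=f, rate=rate,
    )
    if rate <= 0:
        result.unreachable = True
        return result

    # greedy widest-path decomposition
    F = fnet.copy()
    paths = []
    remaining = rate
    for _ in range(max_paths):
        path, cap = _widest_path(F, source, target)
        if path is None or cap <= max(1e-14 * rate, 0.0):
            break
        for a, b in zip(path[:-1], path[1:]):
            F[a, b] -= cap
        paths.append((tuple(path), cap / rate))
        remaining -= cap
        if remaining <= 1e-12 * rate:
            break
    result.paths = paths
    return result


def _widest_path(F: np.ndarray, source, target):
    """Maximum-bottleneck path from any source to any target state."""
    n = F.shape[0]
    width = np.full(n, -np.inf)
    prev = np.full(n, -1, dtype=int)
    width[list(source)] = np.inf
    visited = np.zeros(n, dtype=bool)
    for _ in range(n):
        u = -1
        best = -np.inf
        for i in range(n):
            if not visited[i] and width[i] > best:
                best, u = width[i], i
        if u < 0 or best <= 0:
            break
        visited[u] = True
        for v in range(n):
            if F[u, v] > 0 and not visited[v]:
                w = min(width[u], F[u, v])
                if w > width[v]:
                    width[v] = w
                    prev[v] = u
    best_t = max(target, key=lambda t: width[t])
    if not np.isfinite(width[best_t]) or width[best_t] <= 0:
        return None, 0.0
    path = [best_t]
    while path[-1] not in source:
        path.append(int(prev[path[-1]]))
        if path[-1] < 0:
            return None, 0.0
    return path[::-1], float(width[best_t])


# ---------------------------------------------------------------------------
# streamline projection
# ---------------------------------------------------------------------------

def project_streamlines(
    V_u: np.ndarray, V_s: np.ndarray, U: np.ndarray, S: np.ndarray,
    embedding: np.ndarray, graph: NeighborGraph, mode: str = "nonlinear",
    softmax_scale: float = 10.0,
) -> np.ndarray:
    """Project joint-space velocities into a 2-D embedding as arrows.

    ``linear`` mode projects the joint velocity ``(V_u, V_s)`` through
    the least-squares loadings of the embedding on the joint state.
    ``nonlinear`` mode (scVelo-style, cosine kernel) converts cosine
    similarities between a cell's velocity and its neighbor displacement
    vectors into transition probabilities and returns the expected
    embedded displacement minus the uniform-baseline displacement.
    """
    U = np.asarray(U, float); S = np.asarray(S, float)
    X = np.hstack([U, S])
    V = np.hstack([np.asarray(V_u, float), np.asarray(V_s, float)])
    E = np.asarray(embedding, float)
    if mode == "linear":
        Xc = X - X.mean(axis=0)
        Ec = E - E.mean(axis=0)
        L, *_ = np.linalg.lstsq(Xc, Ec, rcond=None)
        return V @ L
    if mode != "nonlinear":
        raise ValueError("mode must be 'linear' or 'nonlinear'")
    idx = graph.indices
    dX = X[idx] - X[:, None, :]                     # (n, k, 2g)
    nrm = np.linalg.norm(dX, axis=2) * np.maximum(
        np.linalg.norm(V, axis=1)[:, None], 1e-300
    )
    cos = np.einsum("nkg,ng->nk", dX, V) / np.maximum(nrm, 1e-300)
    W = np.exp(softmax_scale * cos)
    W = W / W.sum(axis=1, keepdims=True)
    dE = E[idx] - E[:, None, :]                     # (n, k, 2)
    arrows = np.einsum("nk,nkd->nd", W, dE) - dE.mean(axis=1)
    arrows[np.linalg.norm(V, axis=1) == 0] = 0.0
    return arrows
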