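"""Fuzzy coarse-graining of the cellular random walk (GPCCA-style).

A row-stochastic matrix ``P`` (generally nonreversible) is decomposed
into ``K`` metastable macrostates.  The top-K real Schur vectors of
``P`` (sorted by eigenvalue modulus) span the slow invariant subspace;
a linear map ``A`` rotates them into the probability simplex, giving a
membership matrix ``chi = X A`` with nonnegative rows summing to one.
``A`` is initialized by the inner-simplex (index-search) algorithm and
refined by maximizing the crispness objective
``trace(diag(1/A[0,:]) A^T A)`` subject to the feasibility constraints
(Roeblitz-Weber construction).  The coarse-grained chain is the
membership-projected transition matrix
``P_cg = (chi^T D chi)^{-1} chi^T D P chi`` with ``D = diag(pi)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.optimize as spo
import scipy.sparse as sp
import scipy.sparse.linalg as spla

DENSE_SCHUR_LIMIT = 5000


@dataclass
class Membership:
    """Row-simplex attractor memberships with per-cell entropy."""

    rho: np.ndarray  # (n_cells, K)

    def __post_init__(self):
        r = self.rho
        if r.min() < -1e-10:
            raise ValueError("membership entries must be nonnegative")
        if np.abs(r.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("membership rows must sum to 1")

    @property
    def n_attractors(self) -> int:
        return self.rho.shape[1]

    @property
    def hard_assignment(self) -> np.ndarray:
        """Argmax per cell; ties broken toward the lowest attractor index."""
        return self.rho.argmax(axis=1)

    @property
    def entropy(self) -> np.ndarray:
        return entropy(self)


@dataclass
class CoarseChain:
    """K x K coarse transition matrix with its stationary distribution."""

    P_cg: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        if np.abs(self.P_cg.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("coarse chain rows must sum to 1")


def entropy(m: Membership) -> np.ndarray:
    """Transitional entropy ``-sum_c rho_c ln rho_c`` (0 ln 0 := 0)."""
    r = np.clip(m.rho, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(r > 0, r * np.log(r), 0.0)
    return -t.sum(axis=1)


def averaged_velocity(tensor: np.ndarray, m: Membership):
    """Membership-weighted average of the transition tensor over attractors.

    ``V[k, layer, g] = sum_c rho[k, c] v[k, layer, c, g]``; returns the
    (unspliced, spliced) pair of (n_cells, n_genes) matrices.
    """
    if tensor.shape[2] != m.n_attractors:
        raise ValueError("tensor attractor axis does not match membership")
    V = np.einsum("klcg,kc->klg", tensor, m.rho)
    return V[:, 0, :], V[:, 1, :]


def stationary_distribution(P) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalized."""
    n = P.shape[0]
    if sp.issparse(P) and n > 50:
        vals, vecs = spla.eigs(P.T.tocsc().astype(float), k=1, which="LM")
        pi = np.real(vecs[:, 0])
    else:
        Pd = P.toarray() if sp.issparse(P) else np.asarray(P, float)
        vals, vecs = np.linalg.eig(Pd.T)
        pi = np.real(vecs[:, np.argmax(np.real(vals))])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Schur subspace
# ---------------------------------------------------------------------------

def _eig_moduli_from_schur(T: np.ndarray) -> np.ndarray:
    return np.abs(np.linalg.eigvals(T))


def _sorted_schur_dense(P: np.ndarray, K: int):
    """Top-K real Schur basis of P, eigenvalues sorted by modulus."""
    T0, _ = sla.schur(P, output="real")
    mods = np.sort(_eig_moduli_from_schur(T0))[::-1]
    thresh = mods[K - 1] - 1e-12
    T, Q, sdim = sla.schur(
        P, output="real", sort=lambda re, im: np.hypot(re, im) >= thresh
    )
    if sdim != K:
        warnings.warn(
            f"requested K={K} splits a complex Schur pair or tie; using K={sdim}",
            RuntimeWarning,
        )
        K = sdim
    return Q[:, :K], K


def _sorted_schur_sparse(P: sp.spmatrix, K: int):
    """Krylov approximation of the slow invariant subspace for large P."""
    vals, vecs = spla.eigs(P.tocsc().astype(float), k=K + 2, which="LM")
    order = np.argsort(-np.abs(vals))
    vals, vecs = vals[order], vecs[:, order]
    # realify: a conjugate pair contributes its real and imaginary parts
    cols, used = [], set()
    for j in range(len(vals)):
        if len(cols) >= K or j in used:
            continue
        if abs(vals[j].imag) < 1e-12:
            cols.append(np.real(vecs[:, j]))
        else:
            cols.append(np.real(vecs[:, j]))
            cols.append(np.imag(vecs[:, j]))
            used.add(j + 1)
    B = np.column_stack(cols[:K]) if len(cols) >= K else np.column_stack(cols)
    if B.shape[1] != K:
        warnings.warn(
            f"complex pair at the K boundary; using K={B.shape[1]}", RuntimeWarning
        )
    Q, _ = np.linalg.qr(B)
    return Q, Q.shape[1]


def _schur_basis_with_ones(P, K: int):
    """Orthonormal basis X of the slow subspace with X[:, 0] == 1."""
    n = P.shape[0]
    if n <= DENSE_SCHUR_LIMIT:
        Pd = P.toarray() if sp.issparse(P) else np.asarray(P, float)
        Q, K = _sorted_schur_dense(Pd, K)
    else:
        Q, K = _sorted_schur_sparse(sp.csr_matrix(P), K)
    M = np.column_stack([np.ones(n), Q])
    Qr, _ = np.linalg.qr(M)
    X = Qr[:, :K] * np.sqrt(n)
    if X[0, 0] < 0:
        X[:, 0] *= -1
    if np.abs(X[:, 0] - 1.0).max() > 1e-6:
        # constant vector not exactly in span (Krylov path); force it
        X[:, 0] = 1.0
    return X, K


# ---------------------------------------------------------------------------
# simplex rotation (inner-simplex init + crispness refinement)
# ---------------------------------------------------------------------------

def _index_search(X: np.ndarray) -> np.ndarray:
    """Rows of X spanning the largest simplex (vertex candidates)."""
    n, K = X.shape
    ortho = X.copy()
    idx = np.zeros(K, dtype=int)
    for j in range(K):
        norms = np.linalg.norm(ortho, axis=1)
        idx[j] = int(np.argmax(norms))
        v = ortho[idx[j]] / max(norms[idx[j]], 1e-300)
        ortho = ortho - np.outer(ortho @ v, v)
    return idx


def _fill_matrix(alpha: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Feasible rotation matrix from its free (K-1)x(K-1) block."""
    K = X.shape[1]
    A = np.zeros((K, K))
    A[1:, 1:] = alpha.reshape(K - 1, K - 1)
    A[1:, 0] = -A[1:, 1:].sum(axis=1)
    inner = X[:, 1:] @ A[1:, :]                      # (n, K)
    A[0, :] = -inner.min(axis=0)
    total = A[0, :].sum()
    if total <= 0:
        raise FloatingPointError("degenerate rotation matrix")
    return A / total


def _crispness(A: np.ndarray) -> float:
    return float(np.sum(A ** 2 / np.maximum(A[0, :], 1e-300)[None, :]))


def _optimize_rotation(X: np.ndarray) -> np.ndarray:
    K = X.shape[1]
    vertices = _index_search(X)
    A0 = np.linalg.pinv(X[vertices])
    alpha0 = A0[1:, 1:].ravel()
    A_init = _fill_matrix(alpha0, X)

    if K == 1:
        return np.ones((1, 1))

    def neg_obj(alpha):
        try:
            return -_crispness(_fill_matrix(alpha, X))
        except FloatingPointError:
            return 1e10

    try:
        res = spo.minimize(neg_obj, alpha0, method="Nelder-Mead",
                           options={"maxiter": 2000, "xatol": 1e-10,
                                    "fatol": 1e-10})
        A_opt = _fill_matrix(res.x, X)
        if _crispness(A_opt) >= _crispness(A_init):
            return A_opt
    except FloatingPointError:
        pass
    warnings.warn(
        "rotation refinement did not improve; using inner-simplex init",
        RuntimeWarning,
    )
    return A_init


def gpcca_decompose(P, K: int, pi: np.ndarray | None = None):
    """Decompose a cellular random walk into K fuzzy attractors.

    Parameters
    ----------
    P
        Row-stochastic (sparse or dense) transition matrix.
    K
        Requested number of macrostates (auto-adjusted if a complex
        Schur pair straddles the cut).
    pi
        Optional stationary distribution; computed if omitted.

    Returns
    -------
    (Membership, CoarseChain)
    """
    n = P.shape[0]
    if not (2 <= K <= n):
        raise ValueError(f"need 2 <= K <= n_cells; got K={K}, n={n}")
    X, K = _schur_basis_with_ones(P, K)
    A = _optimize_rotation(X)
    chi = X @ A
    chi = np.clip(chi, 0.0, 1.0)
    chi = chi / chi.sum(axis=1, keepdims=True)
    m = Membership(rho=chi)

    if pi is None:
        pi = stationary_distribution(P)
    # floor the projection weights so states outside the support of a
    # non-unique stationary distribution (disconnected chains) still
    # project; does not perturb irreducible chains beyond 1e-10
    pi = pi + 1e-10
    pi = pi / pi.sum()
    D = sp.diags(pi)
    W = chi.T @ (D @ chi)
    PD = P @ chi if not sp.issparse(P) else P.dot(chi)
    T = chi.T @ (D @ PD)
    P_cg = np.linalg.solve(W + 1e-300 * np.eye(K), T)
    P_cg = np.clip(P_cg, 0.0, None)
    P_cg = P_cg / P_cg.sum(axis=1, keepdims=True)
    pi_cg = stationary_distribution(P_cg)
    return m, CoarseChain(P_cg=P_cg, pi=pi_cg)


def match_columns(rho_new: np.ndarray, rho_old: np.ndarray) -> np.ndarray:
    """Column permutation of ``rho_new`` maximizing overlap with ``rho_old``.

    Hungarian assignment on the column-overlap matrix; keeps attractor
    labels stable across iterations.  Returns the permuted ``rho_new``.
    """
    from scipy.optimize import linear_sum_assignment

    K = rho_old.shape[1]
    if rho_new.shape[1] != K:
        return rho_new  # K changed; no stable matching possible
    overlap = rho_old.T @ rho_new
    _, cols = linear_sum_assignment(-overlap)
    return rho_new[:, cols]
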