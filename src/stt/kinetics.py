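"""Attractor-wise splicing kinetics: closed-form estimation, loss, tensor.

Model per gene (degradation rate fixed to 1 by scale invariance):

    dU/dt = alpha_c - beta * U        (attractor-dependent transcription)
    dS/dt = beta * U - S

Given soft attractor memberships ``rho`` (rows on the K-simplex) the
regularized least-squares loss is

    J(alpha, beta) = sum_c sum_k (alpha_c - beta U_k)^2 rho_kc
                   + sum_k (beta U_k - S_k)^2
                   + lam * sum_c alpha_c^2 + lam * beta^2.

J is a convex quadratic in (alpha_1..alpha_K, beta), so the minimizer is
closed-form: eliminating alpha_c = m_c * beta with
``m_c = sum_k U_k rho_kc / (sum_k rho_kc + lam)`` and solving the scalar
normal equation gives

    beta* = sum_k U_k S_k /
            ( sum_k U_k^2 + sum_kc (U_k - m_c)^2 rho_kc + lam (1 + sum_c m_c^2) ).

With one-hot memberships and lam = 0 this reduces to the per-cluster
indicator-function estimator.  Genes are estimated independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class KineticParams:
    """Per-gene splicing rates and per-attractor transcription rates."""

    alpha: np.ndarray          # (K, n_genes)
    beta: np.ndarray           # (n_genes,)
    lam: float = 0.0
    degenerate: np.ndarray = field(default=None)  # per-gene flag

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros(self.beta.shape[0], dtype=bool)

    @property
    def n_attractors(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_genes(self) -> int:
        return self.alpha.shape[1]


@dataclass
class MultistabilityScores:
    """Per-gene goodness-of-fit of the multistable kinetic model.

    ``score = 1 - J / (N_C (Var U + Var S))``; at most 1, equal to 1 only
    for a zero-loss fit, and ``-inf`` for genes constant in both layers.
    """

    score: np.ndarray
    threshold: float

    @property
    def selected_genes(self) -> np.ndarray:
        return np.flatnonzero(self.score > self.threshold)


def _check_rho(rho: np.ndarray, n_cells: int) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != n_cells:
        raise ValueError(f"rho must be ({n_cells}, K); got {rho.shape}")
    if rho.min() < -1e-12:
        raise ValueError("rho entries must be nonnegative")
    if not np.allclose(rho.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rho rows must sum to 1")
    return rho


def estimate_params(
    U: np.ndarray, S: np.ndarray, rho: np.ndarray, lam: float = 0.0
) -> KineticParams:
    """Closed-form minimizer of the membership-weighted splicing loss.

    Genes whose denominator vanishes (U identically zero with ``lam=0``)
    are flagged degenerate with ``alpha = beta = 0`` instead of raising.
    A negative closed-form beta (possible only on pathological input) is
    clipped to zero with a warning.
    """
    U = np.asarray(U, dtype=float)
    S = np.asarray(S, dtype=float)
    if U.shape != S.shape:
        raise ValueError("U and S must have identical shape")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n_cells, n_genes = U.shape
    rho = _check_rho(rho, n_cells)
    K = rho.shape[1]

    w_c = rho.sum(axis=0)                                  # (K,)
    m = (rho.T @ U) / (w_c[:, None] + lam)                 # (K, n_genes)
    # sum_kc (U_k - m_c)^2 rho_kc = sum_k U_k^2 - 2 sum_c m_c (rho^T U)_c
    #                               + sum_c m_c^2 w_c
    rtU = rho.T @ U
    spread = (U ** 2).sum(axis=0) - 2 * (m * rtU).sum(axis=0) + (m ** 2 * w_c[:, None]).sum(axis=0)
    spread = np.maximum(spread, 0.0)
    denom = (U ** 2).sum(axis=0) + spread + lam * (1.0 + (m ** 2).sum(axis=0))
    numer = (U * S).sum(axis=0)

    degenerate = denom <= 0
    beta = np.zeros(n_genes)
    ok = ~degenerate
    beta[ok] = numer[ok] / denom[ok]
    if np.any(beta < 0):
        warnings.warn("negative closed-form beta clipped to 0", RuntimeWarning)
        beta = np.maximum(beta, 0.0)
    alpha = m * beta[None, :]
    alpha[:, degenerate] = 0.0
    return KineticParams(alpha=alpha, beta=beta, lam=lam, degenerate=degenerate)


def loss(
    U: np.ndarray, S: np.ndarray, params: KineticParams, rho: np.ndarray
) -> np.ndarray:
    """Exact per-gene evaluation of the regularized loss J."""
    U = np.asarray(U, dtype=float)
    S = np.asarray(S, dtype=float)
    rho = _check_rho(rho, U.shape[0])
    a, b, lam = params.alpha, params.beta, params.lam
    # residual (alpha_c - beta U_k): shape (n_cells, K, n_genes)
    res_u = a[None, :, :] - b[None, None, :] * U[:, None, :]
    term_u = np.einsum("kcg,kc->g", res_u ** 2, rho)
    term_s = ((b[None, :] * U - S) ** 2).sum(axis=0)
    reg = lam * (a ** 2).sum(axis=0) + lam * b ** 2
    return term_u + term_s + reg


def build_tensor(U: np.ndarray, S: np.ndarray, params: KineticParams) -> np.ndarray:
    """Four-dimensional transition tensor ``v[cell, layer, attractor, gene]``.

    Layer axis is ordered (unspliced, spliced):
    ``v[k,0,c,g] = alpha[c,g] - beta[g] U[k,g]`` and
    ``v[k,1,c,g] = beta[g] U[k,g] - S[k,g]`` (attractor-independent).
    """
    U = np.asarray(U, dtype=float)
    S = np.asarray(S, dtype=float)
    if U.shape != S.shape:
        raise ValueError("U and S must have identical shape")
    if U.shape[1] != params.n_genes:
        raise ValueError(
            f"params cover {params.n_genes} genes but data has {U.shape[1]}"
        )
    n_cells, n_genes = U.shape
    K = params.n_attractors
    v = np.empty((n_cells, 2, K, n_genes))
    bu = params.beta[None, :] * U
    v[:, 0, :, :] = params.alpha[None, :, :] - bu[:, None, :]
    v[:, 1, :, :] = (bu - S)[:, None, :]
    return v


def multistability_score(
    U: np.ndarray,
    S: np.ndarray,
    params: KineticParams,
    rho: np.ndarray,
    threshold: float = 0.5,
) -> MultistabilityScores:
    """Score genes by how well the multistable model explains them.

    Evaluated on whatever cell subset (train or test fold) is passed in;
    variances are population variances over that subset.
    """
    U = np.asarray(U, dtype=float)
    S = np.asarray(S, dtype=float)
    n_cells = U.shape[0]
    J = loss(U, S, params, rho)
    var = U.var(axis=0) + S.var(axis=0)
    score = np.full(U.shape[1], -np.inf)
    pos = var > 0
    score[pos] = 1.0 - J[pos] / (n_cells * var[pos])
    return MultistabilityScores(score=score, threshold=threshold)
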