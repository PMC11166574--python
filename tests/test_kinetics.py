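"""Closed-form kinetic estimation against independent numerical oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

from stt.kinetics import (build_tensor, estimate_params, loss,
                          multistability_score)


def numerical_minimizer(U, S, rho, lam):
    """Generic numerical minimizer of the loss for one gene (oracle)."""
    K = rho.shape[1]

    def obj(theta):
        from stt.kinetics import KineticParams

        p = KineticParams(
            alpha=theta[:K].reshape(K, 1), beta=theta[K:], lam=lam
        )
        return loss(U, S, p, rho)[0]

    best = None
    for x0 in ([0.5] * (K + 1), [1.5] * (K + 1), [0.1] * (K + 1)):
        r = minimize(obj, x0, method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        if best is None or r.fun < best.fun:
            best = r
    return best.x[:K], best.x[K]


def one_hot(labels, K):
    rho = np.zeros((len(labels), K))
    rho[np.arange(len(labels)), labels] = 1.0
    return rho


class TestClosedForm:
    def test_perfect_steady_state(self):
        # all cells at U=S=c: m=c, beta=1, alpha=c, zero residuals
        c = 2.5
        U = np.full((8, 1), c)
        S = np.full((8, 1), c)
        rho = np.ones((8, 1))
        p = estimate_params(U, S, rho, lam=0.0)
        assert p.beta[0] == pytest.approx(1.0)
        assert p.alpha[0, 0] == pytest.approx(c)
        v = build_tensor(U, S, p)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    @pytest.mark.parametrize("K", [1, 2, 3])
    @pytest.mark.parametrize("lam", [0.0, 0.1, 1.0])
    def test_matches_numerical_minimizer(self, K, lam):
        """Closed form equals a generic optimizer of the loss (oracle)."""
        rng = np.random.default_rng(K * 10 + int(lam * 10))
        for rep in range(4):
            n = int(rng.integers(10, 50))
            U = rng.uniform(0.1, 3.0, (n, 1))
            S = rng.uniform(0.1, 3.0, (n, 1))
            rho = rng.dirichlet(np.ones(K), size=n)
            p = estimate_params(U, S, rho, lam=lam)
            a_num, b_num = numerical_minimizer(U, S, rho, lam)
            assert p.beta[0] == pytest.approx(b_num, rel=1e-6, abs=1e-8)
            np.testing.assert_allclose(
                p.alpha[:, 0], a_num, rtol=1e-5, atol=1e-6
            )
            # and the closed form never evaluates above the numerical optimum
            J_closed = loss(U, S, p, rho)[0]
            from stt.kinetics import KineticParams
            J_num = loss(U, S, KineticParams(
                alpha=a_num.reshape(K, 1), beta=np.array([b_num]), lam=lam
            ), rho)[0]
            assert J_closed <= J_num + 1e-10

    def test_one_hot_reduces_to_indicator_formulas(self):
        """Soft formulas with one-hot rho equal the per-cluster estimator."""
        rng = np.random.default_rng(5)
        n, K = 40, 2
        labels = rng.integers(0, K, n)
        U = rng.uniform(0.1, 3, (n, 1))
        S = rng.uniform(0.1, 3, (n, 1))
        rho = one_hot(labels, K)
        p = estimate_params(U, S, rho, lam=0.0)
        # indicator-function closed form computed independently
        m = np.array([U[labels == c, 0].mean() for c in range(K)])
        spread = sum(
            ((U[labels == c, 0] - m[c]) ** 2).sum() for c in range(K)
        )
        beta = (U[:, 0] * S[:, 0]).sum() / ((U[:, 0] ** 2).sum() + spread)
        assert p.beta[0] == pytest.approx(beta, rel=1e-12)
        np.testing.assert_allclose(p.alpha[:, 0], m * beta, rtol=1e-12)

    def test_lambda_shrinks_beta(self):
        rng = np.random.default_rng(2)
        U = rng.uniform(0.5, 2, (30, 1))
        S = rng.uniform(0.5, 2, (30, 1))
        rho = rng.dirichlet(np.ones(2), size=30)
        betas = [estimate_params(U, S, rho, lam=l).beta[0]
                 for l in (0.0, 0.5, 1.0, 2.0)]
        assert all(b1 > b2 for b1, b2 in zip(betas, betas[1:]))

    def test_degenerate_gene_flagged_not_crashed(self):
        U = np.zeros((10, 1))
        S = np.zeros((10, 1))
        p = estimate_params(U, S, np.ones((10, 1)), lam=0.0)
        assert p.degenerate[0]
        assert p.beta[0] == 0.0 and p.alpha[0, 0] == 0.0

    def test_genes_estimated_independently(self):
        rng = np.random.default_rng(3)
        U = rng.uniform(0.1, 3, (20, 3))
        S = rng.uniform(0.1, 3, (20, 3))
        rho = rng.dirichlet(np.ones(2), size=20)
        full = estimate_params(U, S, rho, lam=0.1)
        for g in range(3):
            single = estimate_params(U[:, [g]], S[:, [g]], rho, lam=0.1)
            assert full.beta[g] == pytest.approx(single.beta[0], rel=1e-12)


class TestLoss:
    def test_zero_residual_zero_loss(self):
        U = np.full((5, 1), 2.0)
        S = np.full((5, 1), 2.0)
        p = estimate_params(U, S, np.ones((5, 1)), lam=0.0)
        assert loss(U, S, p, np.ones((5, 1)))[0] == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_three_cell_instance(self):
        # U=(1,2,3), S=(2,3,4), rho rows (1,0),(0,1),(.5,.5)
        # alpha=(1, 2), beta=1, lam=0
        U = np.array([[1.0], [2.0], [3.0]])
        S = np.array([[2.0], [3.0], [4.0]])
        rho = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        from stt.kinetics import KineticParams

        p = KineticParams(alpha=np.array([[1.0], [2.0]]), beta=np.array([1.0]),
                          lam=0.0)
        # unspliced: c=0: (1-1)^2*1 + (1-2)^2*0 + (1-3)^2*.5 = 2
        #            c=1: (2-1)^2*0 + (2-2)^2*1 + (2-3)^2*.5 = 0.5
        # spliced: (1-2)^2 + (2-3)^2 + (3-4)^2 = 3
        assert loss(U, S, p, rho)[0] == pytest.approx(5.5)

    def test_local_minimality_in_beta(self):
        rng = np.random.default_rng(7)
        U = rng.uniform(0.1, 3, (25, 1))
        S = rng.uniform(0.1, 3, (25, 1))
        rho = rng.dirichlet(np.ones(2), size=25)
        p = estimate_params(U, S, rho, lam=0.1)
        J0 = loss(U, S, p, rho)[0]
        for delta in (1e-3, -1e-3):
            from stt.kinetics import KineticParams

            q = KineticParams(alpha=p.alpha * (1 + delta / p.beta[0]),
                              beta=p.beta + delta, lam=0.1)
            # perturb beta along with its induced alpha: loss must not drop
            assert loss(U, S, q, rho)[0] >= J0 - 1e-12


class TestTensor:
    def test_spliced_layer_attractor_independent(self, rng):
        U = rng.uniform(0, 3, (12, 4))
        S = rng.uniform(0, 3, (12, 4))
        rho = rng.dirichlet(np.ones(3), size=12)
        p = estimate_params(U, S, rho, lam=0.0)
        v = build_tensor(U, S, p)
        for c in range(1, 3):
            np.testing.assert_array_equal(v[:, 1, c, :], v[:, 1, 0, :])

    def test_reconstruction_invariant(self, rng):
        U = rng.uniform(0, 3, (10, 2))
        S = rng.uniform(0, 3, (10, 2))
        rho = rng.dirichlet(np.ones(2), size=10)
        p = estimate_params(U, S, rho, lam=0.1)
        v = build_tensor(U, S, p)
        np.testing.assert_allclose(
            v[:, 0, 1, :], p.alpha[1][None, :] - p.beta[None, :] * U
        )
        np.testing.assert_allclose(v[:, 1, 0, :], p.beta[None, :] * U - S)
        v2 = build_tensor(U, S, p)
        np.testing.assert_array_equal(v, v2)

    def test_fixed_point_annihilation(self):
        # cell exactly at attractor-c steady state has zero velocity there
        from stt.kinetics import KineticParams

        p = KineticParams(alpha=np.array([[2.0]]), beta=np.array([0.5]), lam=0.0)
        U = np.array([[4.0]])          # alpha/beta
        S = np.array([[2.0]])          # beta*U
        v = build_tensor(U, S, p)
        np.testing.assert_allclose(v[0, :, 0, 0], 0.0, atol=1e-12)


class TestMultistabilityScore:
    def test_perfect_fit_scores_one(self):
        U = np.concatenate([np.full((5, 1), 1.0), np.full((5, 1), 3.0)])
        S = U.copy()
        rho = np.zeros((10, 2))
        rho[:5, 0] = 1.0
        rho[5:, 1] = 1.0
        p = estimate_params(U, S, rho, lam=0.0)
        sc = multistability_score(U, S, p, rho)
        assert sc.score[0] == pytest.approx(1.0)

    def test_zero_variance_gene_never_selected(self):
        U = np.ones((6, 1))
        S = np.ones((6, 1))
        p = estimate_params(U, S, np.ones((6, 1)), lam=0.0)
        sc = multistability_score(U, S, p, np.ones((6, 1)), threshold=-1e9)
        assert sc.score[0] == -np.inf
        assert len(sc.selected_genes) == 0

    def test_score_never_exceeds_one(self, rng):
        U = rng.uniform(0, 3, (30, 5))
        S = rng.uniform(0, 3, (30, 5))
        rho = rng.dirichlet(np.ones(2), size=30)
        p = estimate_params(U, S, rho, lam=0.1)
        sc = multistability_score(U, S, p, rho)
        assert np.all(sc.score <= 1.0)

    def test_circuit_genes_beat_permuted_decoys(self, toggle_sim):
        """On toggle data, real genes outscore column-permuted decoys."""
        ds = toggle_sim.dataset
        rng = np.random.default_rng(0)
        U = np.asarray(ds.U)
        S = np.asarray(ds.S)
        perm = rng.permutation(U.shape[0])
        # decoys destroy the U-S and cell-cluster coupling
        U_all = np.hstack([U, U[perm]])
        S_all = np.hstack([S, S[rng.permutation(U.shape[0])]])
        from stt.model import initialize_membership

        m, _ = initialize_membership(ds.initial_labels)
        p = estimate_params(U_all, S_all, m.rho, lam=0.0)
        sc = multistability_score(U_all, S_all, p, m.rho)
        assert sc.score[:2].min() > sc.score[2:].max()
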