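import numpy as np
import pytest
import scipy.sparse as sp

from stt.kernels import (CellRandomWalk, KernelConfigurationError,
                         NeighborGraph, assert_row_stochastic,
                         build_neighbor_graph, combine_kernels,
                         similarity_kernel, spatial_kernel, velocity_kernel)

from conftest import random_row_stochastic


def chain_graph(n, k=2):
    """Ring-free path graph: each cell's neighbors are its k nearest indices."""
    idx = []
    for i in range(n):
        cand = sorted(range(n), key=lambda j: (abs(j - i), j))
        idx.append([j for j in cand if j != i][:k])
    return NeighborGraph(indices=np.array(idx), basis="expression_pca")


class TestNeighborGraph:
    def test_self_loops_rejected(self):
        with pytest.raises(ValueError, match="self-loops"):
            NeighborGraph(indices=np.array([[0], [0]]), basis="x")

    def test_build_excludes_self(self, rng):
        U = rng.uniform(0, 2, (20, 3))
        S = rng.uniform(0, 2, (20, 3))
        g = build_neighbor_graph(U, S, n_neighbors=5, n_pcs=4)
        assert g.indices.shape == (20, 5)
        assert all(i not in g.indices[i] for i in range(20))

    def test_union_with_spatial(self, rng):
        U = rng.uniform(0, 2, (15, 3))
        S = rng.uniform(0, 2, (15, 3))
        xy = rng.uniform(0, 1, (15, 2))
        g = build_neighbor_graph(U, S, n_neighbors=3, n_pcs=4,
                                 spatial=xy, n_neighbors_spatial=3)
        assert g.basis == "union"
        ge = build_neighbor_graph(U, S, n_neighbors=3, n_pcs=4)
        for i in range(15):
            assert set(ge.indices[i]) <= set(g.indices[i])


class TestVelocityKernel:
    def test_zero_velocity_gives_uniform_rows(self, rng):
        n = 8
        U = rng.uniform(0, 2, (n, 3))
        S = rng.uniform(0, 2, (n, 3))
        g = chain_graph(n, k=3)
        Pv = velocity_kernel(np.zeros((n, 3)), np.zeros((n, 3)), U, S, g)
        for i in range(n):
            row = Pv[[i], :].toarray().ravel()
            nz = row[row > 0]
            np.testing.assert_allclose(nz, 1.0 / len(nz))

    def test_single_neighbor_gets_probability_one(self, rng):
        n = 4
        U = rng.uniform(0, 2, (n, 2))
        S = rng.uniform(0, 2, (n, 2))
        g = chain_graph(n, k=1)
        Pv = velocity_kernel(rng.normal(size=(n, 2)), rng.normal(size=(n, 2)),
                             U, S, g)
        np.testing.assert_allclose(Pv.max(axis=1).toarray().ravel(), 1.0)

    def test_three_cell_hand_softmax(self):
        # cell 0 at origin; neighbors 1 and 2 displaced by dU=(1,0)/(0,1),
        # dS=0; V_u=(1,2), V_s=0 -> logits 1 and 2
        U = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        S = np.zeros((3, 2))
        g = NeighborGraph(indices=np.array([[1, 2], [0, 2], [0, 1]]), basis="x")
        Vu = np.array([[1.0, 2.0], [0.0, 0.0], [0.0, 0.0]])
        Pv = velocity_kernel(Vu, np.zeros((3, 2)), U, S, g)
        e1, e2 = np.exp(1.0), np.exp(2.0)
        np.testing.assert_allclose(
            Pv[[0], :].toarray().ravel()[1:],
            [e1 / (e1 + e2), e2 / (e1 + e2)], rtol=1e-12,
        )

    def test_row_stochastic(self, rng):
        n = 30
        U = rng.uniform(0, 3, (n, 4))
        S = rng.uniform(0, 3, (n, 4))
        g = build_neighbor_graph(U, S, n_neighbors=6, n_pcs=4)
        Pv = velocity_kernel(rng.normal(size=(n, 4)), rng.normal(size=(n, 4)),
                             U, S, g)
        assert_row_stochastic(Pv)


class TestSimilarityAndSpatialKernels:
    def test_equidistant_neighbors_equal_probability(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [5.0, 5.0]])
        g = NeighborGraph(
            indices=np.array([[1, 2], [0, 3], [0, 3], [1, 2]]), basis="spatial"
        )
        Ps = spatial_kernel(xy, g)
        row = Ps[[0], :].toarray().ravel()
        assert row[1] == pytest.approx(row[2])

    def test_lattice_nearest_two_equal_half(self):
        x = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        # interior site 2: neighbors 1 and 3 at distance 1
        g = NeighborGraph(
            indices=np.array([[1, 2], [0, 2], [1, 3], [2, 4], [3, 5], [4, 3]]),
            basis="spatial",
        )
        Ps = spatial_kernel(x, g, bandwidth=0.8)
        row = Ps[[2], :].toarray().ravel()
        assert row[1] == pytest.approx(0.5, abs=1e-6)
        assert row[3] == pytest.approx(0.5, abs=1e-6)

    def test_shrinking_bandwidth_concentrates_mass(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        g = NeighborGraph(indices=np.array([[1, 2], [0, 2], [1, 0]]), basis="s")
        probs = []
        for bw in (2.0, 0.5, 0.1):
            Ps = spatial_kernel(xy, g, bandwidth=bw)
            probs.append(Ps[0, 1])
        assert probs[0] < probs[1] < probs[2]
        assert probs[-1] == pytest.approx(1.0, abs=1e-6)

    def test_dense_oracle_agreement(self, rng):
        """Sparse spatial kernel equals a dense Gaussian-normalize computation."""
        n = 4
        xy = rng.uniform(0, 1, (n, 2))
        # fully connected (all others are neighbors)
        idx = np.array([[j for j in range(n) if j != i] for i in range(n)])
        g = NeighborGraph(indices=idx, basis="spatial")
        bw = 0.7
        Ps = spatial_kernel(xy, g, bandwidth=bw).toarray()
        D = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        W = np.exp(-(D ** 2) / bw ** 2)
        np.fill_diagonal(W, 0.0)
        expected = W / W.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(Ps, expected, atol=1e-12)

    def test_similarity_kernel_row_stochastic_and_symmetric_pattern(self, rng):
        U = rng.uniform(0, 3, (25, 3))
        S = rng.uniform(0, 3, (25, 3))
        g = build_neighbor_graph(U, S, n_neighbors=5, n_pcs=4)
        Pc = similarity_kernel(U, S, g, n_pcs=4)
        assert_row_stochastic(Pc)
        A = (Pc > 0).astype(int)
        assert (A != A.T).nnz == 0  # symmetrized sparsity

    def test_absent_spatial_is_configuration_error(self):
        g = chain_graph(4)
        with pytest.raises(KernelConfigurationError, match="spatial"):
            spatial_kernel(None, g)


class TestCombineKernels:
    def test_degenerate_mixture_w1_equals_pv(self, rng):
        P1 = sp.csr_matrix(random_row_stochastic(rng, 6))
        P2 = sp.csr_matrix(random_row_stochastic(rng, 6))
        walk = combine_kernels(P1, P2, None, w1=1.0, w2=0.0)
        np.testing.assert_allclose(walk.P.toarray(), P1.toarray())

    def test_idempotent_on_equal_components(self, rng):
        P = sp.csr_matrix(random_row_stochastic(rng, 5))
        walk = combine_kernels(P, P, P, w1=1 / 3, w2=1 / 3)
        np.testing.assert_allclose(walk.P.toarray(), P.toarray())

    def test_convexity_entrywise(self, rng):
        Pv = random_row_stochastic(rng, 7)
        Pc = random_row_stochastic(rng, 7)
        Ps = random_row_stochastic(rng, 7)
        w1, w2 = 0.5, 0.3
        walk = combine_kernels(
            sp.csr_matrix(Pv), sp.csr_matrix(Pc), sp.csr_matrix(Ps), w1, w2
        )
        P = walk.P.toarray()
        assert np.all(P >= w1 * Pv - 1e-15)
        assert np.all(P >= w2 * Pc - 1e-15)
        np.testing.assert_allclose(P, w1 * Pv + w2 * Pc + 0.2 * Ps, atol=1e-14)

    def test_invalid_weights_rejected(self, rng):
        P = sp.csr_matrix(random_row_stochastic(rng, 4))
        with pytest.raises(KernelConfigurationError):
            combine_kernels(P, P, P, w1=0.8, w2=0.4)
        with pytest.raises(KernelConfigurationError):
            combine_kernels(P, P, P, w1=-0.1, w2=0.4)

    def test_nonspatial_mixture_folds_weight_into_similarity(self, rng):
        Pv = random_row_stochastic(rng, 5)
        Pc = random_row_stochastic(rng, 5)
        walk = combine_kernels(sp.csr_matrix(Pv), sp.csr_matrix(Pc), None,
                               w1=0.5, w2=0.3)
        np.testing.assert_allclose(walk.P.toarray(), 0.5 * Pv + 0.5 * Pc)


class TestMarkovInvariants:
    def test_all_kernels_row_stochastic_on_random_instances(self, rng):
        for rep in range(3):
            n = int(rng.integers(15, 40))
            U = rng.uniform(0, 3, (n, 3))
            S = rng.uniform(0, 3, (n, 3))
            xy = rng.uniform(0, 1, (n, 2))
            g = build_neighbor_graph(U, S, n_neighbors=5, n_pcs=4,
                                     spatial=xy, n_neighbors_spatial=3)
            Pv = velocity_kernel(rng.normal(size=(n, 3)),
                                 rng.normal(size=(n, 3)), U, S, g)
            Pc = similarity_kernel(U, S, g, n_pcs=4)
            Ps = spatial_kernel(xy, g)
            walk = combine_kernels(Pv, Pc, Ps, w1=0.5, w2=0.3)
            for M in (Pv, Pc, Ps, walk.P):
                assert_row_stochastic(M, tol=1e-10)

    def test_velocity_kernel_follows_true_drift(self, toggle_sim):
        """One-step expected displacement under Pv aligns with the drift.

        Statistical check away from fixed points: mean cosine similarity
        between E_P[x'-x] and the ground-truth drift is positive.
        """
        ds = toggle_sim.dataset
        U, S = ds.dense()
        g = build_neighbor_graph(U, S, n_neighbors=10, n_pcs=4)
        Pv = velocity_kernel(toggle_sim.true_velocity_u,
                             toggle_sim.true_velocity_s, U, S, g)
        X = np.hstack([U, S])
        drift = np.hstack([toggle_sim.true_velocity_u,
                           toggle_sim.true_velocity_s])
        disp = Pv @ X - X
        speed = np.linalg.norm(drift, axis=1)
        away = speed > np.median(speed)      # cells away from fixed points
        cos = np.einsum("ij,ij->i", disp, drift) / (
            np.linalg.norm(disp, axis=1) * speed + 1e-300
        )
        assert cos[away].mean() > 0.3
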