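import numpy as np
import pytest

import stt


@pytest.fixture(scope="session")
def toggle_sim():
    """Small bistable toggle-switch dataset with ground truth."""
    return stt.simulate_toggle_switch(n_cells=300, seed=1)


@pytest.fixture(scope="session")
def toggle_fit(toggle_sim):
    """Fitted transition-tensor model on the toggle dataset."""
    model = stt.STTModel(toggle_sim.dataset, n_neighbors=15)
    return model.fit(max_iter=5, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_simplex_rows(rng, n, k):
    """Random membership matrix with rows on the k-simplex."""
    r = rng.dirichlet(np.ones(k), size=n)
    return r


def random_row_stochastic(rng, n):
    M = rng.uniform(0.05, 1.0, (n, n))
    return M / M.sum(axis=1, keepdims=True)
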