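import numpy as np
import pytest

from netphi import (
    ConnectomeConfig,
    GaussianTransitionModel,
    RosslerParams,
    brain_like_network,
    master_stability_coupling,
    simulate_rossler,
)


def stable_var_model(seed: int, n: int = 4, scale: float = 0.2):
    """A random stable VAR(1) model with its analytic covariances."""
    rng = np.random.default_rng(seed)
    while True:
        A = rng.normal(scale=scale, size=(n, n))
        if np.max(np.abs(np.linalg.eigvals(A))) < 0.95:
            return GaussianTransitionModel.from_var_coefficients(A)


@pytest.fixture(scope="session")
def small_rossler_dataset():
    """One brain-like 12-node network with 25,000 recorded oscillator
    samples — shared by the tests that need realistic dynamics."""
    graph = brain_like_network(ConnectomeConfig(n=12, seed=99))
    sigma = master_stability_coupling(graph)[2]
    ts = simulate_rossler(
        graph,
        RosslerParams(sigma=sigma, n_points=25_000, record_every=100, seed=99),
    )
    return graph, ts
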