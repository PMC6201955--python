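import numpy as np
import pytest

from cogmap.response_analysis import StimulusProtocol
from cogmap.synthetic_data import (
    PopulationSpec,
    TraceNoiseSpec,
    default_protocols,
    generate_population,
)


def floyd_warshall_efficiency(adjacency: np.ndarray) -> float:
    """Brute-force global efficiency: O(K^3) all-pairs shortest paths."""
    K = adjacency.shape[0]
    dist = np.where(adjacency > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(K):
        for i in range(K):
            for j in range(K):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    total = 0.0
    for i in range(K):
        for j in range(K):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (K * (K - 1))


def random_graph(K: int, p: float, rng: np.random.Generator):
    """Symmetric hollow Erdos-Renyi adjacency matrix."""
    A = (rng.uniform(size=(K, K)) < p).astype(int)
    A = np.triu(A, 1)
    return A + A.T


@pytest.fixture(scope="session")
def fw_efficiency():
    return floyd_warshall_efficiency


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise-free, drift-free rendering for exact reconstruction checks."""
    return TraceNoiseSpec(
        drift_amplitude=0.0, gaussian_noise_sd=0.0, subthreshold_amplitude=0.0
    )


@pytest.fixture(scope="session")
def small_population():
    """A 30-neuron high-SNR population with 2 trials, shared across tests."""
    spec = PopulationSpec(n_neurons=30, seed=7)
    noise = TraceNoiseSpec()  # kernel amplitude 10 x noise sd = SNR 10
    traces, truth = generate_population(
        spec, noise, default_protocols(), n_trials=2, seed=7
    )
    return spec, noise, traces, truth


@pytest.fixture()
def iv_protocol():
    return StimulusProtocol(condition="IV", pulse_rate=40.0)
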