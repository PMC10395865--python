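import numpy as np
import pytest

from hybridpc import NetworkConfig, init_weights


@pytest.fixture
def small_config():
    """Mixed-activation three-link net, small enough for brute force."""
    return NetworkConfig(layer_sizes=[10, 8, 6, 4], seed=0)


@pytest.fixture
def small_net(small_config):
    theta, phi = init_weights(small_config, seed=0)
    return small_config, theta, phi


def random_state(config, rng, clamp_data=True, clamp_top=False):
    """Random beliefs conforming to a config (batch of 1)."""
    from hybridpc import NetworkState
    mu = [rng.standard_normal((1, d)) * 0.5 for d in config.layer_sizes]
    clamped = [clamp_data] + [False] * (config.n_links - 1) + [clamp_top]
    return NetworkState(mu=mu, clamped=clamped)


def numerical_free_energy_grad(state, theta, config, wrt_layer, h=1e-5):
    """Central finite-difference gradient of the free energy with respect
    to the beliefs of one layer (independent oracle)."""
    from hybridpc import compute_errors, free_energy

    base = state.copy()
    mu = base.mu[wrt_layer]
    grad = np.zeros_like(mu)
    for idx in np.ndindex(mu.shape):
        for sgn in (+1, -1):
            pert = base.copy()
            pert.mu[wrt_layer] = mu.copy()
            pert.mu[wrt_layer][idx] += sgn * h
            f = free_energy(compute_errors(pert, theta, config), config)
            grad[idx] += sgn * f
    return grad / (2 * h)
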