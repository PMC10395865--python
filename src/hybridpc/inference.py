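"""Inference: amortized sweep, iterative free-energy descent, readouts.

Inference on an input proceeds in two phases.  In hybrid mode a single
bottom-up pass through the amortized weights initializes the beliefs at
every layer; in standard predictive-coding mode the unclamped beliefs
start at zero (or a seeded random draw).  The iterative phase then
performs gradient descent on the free energy with step size kappa,
optionally truncated when the summed per-layer mean squared prediction
error falls below the perceptual-certainty threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import (
    AmortizedWeights,
    ErrorState,
    GenerativeWeights,
    NetworkConfig,
    NetworkState,
    activation,
    activation_deriv,
    bottom_up_predict,
    compute_errors,
    error_statistic,
    free_energy,
)

__all__ = [
    "InferenceResult",
    "amortized_sweep",
    "iterative_step",
    "run_inference",
    "classify",
    "generate",
    "label_entropy",
    "top_layer_distribution",
]


@dataclass
class InferenceResult:
    """Outcome of one inference phase.

    ``energy_trace`` has ``n_iters_used + 1`` entries: the free energy of
    the initial state followed by the value after each iterative step.
    """

    state_star: NetworkState
    sweep_state: NetworkState
    n_iters_used: int
    energy_trace: list
    stopped_by: str  # "threshold" | "iteration_cap"


def amortized_sweep(phi: AmortizedWeights, x: np.ndarray,
                    config: NetworkConfig) -> NetworkState:
    """Single bottom-up pass: clamp the data layer to ``x`` and fill every
    higher layer from the one below through the amortized weights."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[-1] != config.layer_sizes[0]:
        raise ValueError(f"input length {x.shape[-1]} != data layer size "
                         f"{config.layer_sizes[0]}")
    mu = [x.copy()]
    for i in range(config.n_links):
        mu.append(bottom_up_predict(phi.matrices[i], mu[-1],
                                    config.amo_activation[i]))
    clamped = [True] + [False] * config.n_links
    return NetworkState(mu=mu, clamped=clamped)


def _belief_gradients(state: NetworkState, errs: ErrorState,
                      theta: GenerativeWeights, config: NetworkConfig) -> list:
    """dF/dmu_i for every layer (batched); clamped layers get None."""
    L = config.n_links
    grads: list = [None] * (L + 1)
    for i in range(L + 1):
        if state.clamped[i]:
            continue
        if i < L:
            g = errs.eps[i] / config.sigma_l
        elif errs.eps_top is not None:
            g = errs.eps_top / config.sigma_p
        else:
            g = np.zeros_like(state.mu[i])
        if i > 0:
            # backpressure from the layer below through theta_i
            tag = config.gen_activation[i - 1]
            gprime = activation_deriv(tag, state.mu[i])
            g = g - gprime * (errs.eps[i - 1] @ theta.matrices[i - 1]) / config.sigma_l
        grads[i] = g
    return grads


def iterative_step(state: NetworkState, theta: GenerativeWeights,
                   config: NetworkConfig,
                   errs: Optional[ErrorState] = None) -> NetworkState:
    """One gradient-descent step on the free energy for every unclamped
    layer.  Default schedule is simultaneous (Jacobi): all layers move
    using the errors of the start-of-step state.  The sequential variant
    updates layers in ascending order, recomputing errors in between."""
    if config.update_schedule == "sequential":
        new = state.copy()
        for i in range(config.n_links + 1):
            if new.clamped[i]:
                continue
            e = compute_errors(new, theta, config)
            g = _belief_gradients(new, e, theta, config)[i]
            new.mu[i] = new.mu[i] - config.kappa * g
        return new

    if errs is None:
        errs = compute_errors(state, theta, config)
    grads = _belief_gradients(state, errs, theta, config)
    new_mu = [m if g is None else m - config.kappa * g
              for m, g in zip(state.mu, grads)]
    return NetworkState(mu=new_mu, clamped=list(state.clamped))


def _init_state(x: np.ndarray, phi: AmortizedWeights,
                config: NetworkConfig) -> NetworkState:
    if config.use_amortized:
        return amortized_sweep(phi, x, config)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[-1] != config.layer_sizes[0]:
        raise ValueError("input length does not match the data layer")
    b = x.shape[0]
    if config.pc_init == "random":
        rng = np.random.default_rng(config.seed)
        mu = [x.copy()] + [rng.standard_normal((b, d)) * 0.01
                           for d in config.layer_sizes[1:]]
    else:
        mu = [x.copy()] + [np.zeros((b, d)) for d in config.layer_sizes[1:]]
    return NetworkState(mu=mu, clamped=[True] + [False] * config.n_links)


def _iterate(state: NetworkState, theta: GenerativeWeights,
             config: NetworkConfig, sweep_state: NetworkState) -> InferenceResult:
    errs = compute_errors(state, theta, config)
    trace = [free_energy(errs, config)]
    n_used = 0
    stopped = "iteration_cap"
    any_unclamped = not all(state.clamped)
    for _ in range(config.n_iters_max):
        if config.adaptive_stop and error_statistic(errs, config) < config.threshold_beta:
            stopped = "threshold"
            break
        if not any_unclamped:
            break
        state = iterative_step(state, theta, config, errs)
        errs = compute_errors(state, theta, config)
        trace.append(free_energy(errs, config))
        n_used += 1
    else:
        if config.adaptive_stop and error_statistic(errs, config) < config.threshold_beta:
            stopped = "threshold"
    return InferenceResult(state_star=state, sweep_state=sweep_state,
                           n_iters_used=n_used, energy_trace=trace,
                           stopped_by=stopped)


def run_inference(x: np.ndarray, theta: GenerativeWeights,
                  phi: AmortizedWeights, config: NetworkConfig,
                  clamp_top_to: Optional[np.ndarray] = None) -> InferenceResult:
    """Full inference phase: initialize (amortized sweep or zeros), then
    refine by iterative free-energy descent up to ``n_iters_max`` steps,
    stopping early at the certainty threshold if ``adaptive_stop``."""
    state = _init_state(x, phi, config)
    sweep_state = state.copy()
    if clamp_top_to is not None:
        top = np.atleast_2d(np.asarray(clamp_top_to, dtype=float))
        if top.shape[-1] != config.layer_sizes[-1]:
            raise ValueError("clamp_top_to length does not match the top layer")
        if top.shape[0] == 1 and state.batch_size > 1:
            top = np.broadcast_to(top, (state.batch_size, top.shape[1])).copy()
        state.mu[-1] = top
        state.clamped[-1] = True
    return _iterate(state, theta, config, sweep_state)


def classify(result: InferenceResult) -> np.ndarray:
    """Predicted labels: argmax over the top layer of the converged state
    (ties resolved toward the lowest index, numpy's argmax rule)."""
    return np.argmax(result.state_star.mu[-1], axis=-1)


def generate(theta: GenerativeWeights, label: int,
             config: NetworkConfig) -> np.ndarray:
    """Generate a data-layer image for ``label`` by clamping the top layer
    to the one-hot label, zero-initializing all lower layers (the data
    layer included, unclamped), and running iterative inference."""
    dL = config.layer_sizes[-1]
    if not 0 <= int(label) < dL:
        raise ValueError(f"label {label} out of range [0, {dL})")
    onehot = np.zeros((1, dL))
    onehot[0, int(label)] = 1.0
    mu = [np.zeros((1, d)) for d in config.layer_sizes[:-1]] + [onehot]
    clamped = [False] * config.n_links + [True]
    state = NetworkState(mu=mu, clamped=clamped)
    result = _iterate(state, theta, config, state.copy())
    return result.state_star.mu[0][0]


def top_layer_distribution(z: np.ndarray, normalization: str = "sum") -> np.ndarray:
    """Normalize top-layer activity to a probability vector.

    ``"sum"`` rectifies negative activities and divides by the total
    (uniform fallback when nothing is positive) — near one-hot beliefs
    map to near-delta distributions.  ``"softmax"`` is available but is
    insensitive at sub-unit activity scales, where it stays near
    uniform regardless of the activity pattern."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if normalization == "softmax":
        z = z - np.max(z, axis=-1, keepdims=True)
        p = np.exp(z)
        return p / np.sum(p, axis=-1, keepdims=True)
    if normalization == "sum":
        p = np.clip(z, 0.0, None)
        s = np.sum(p, axis=-1, keepdims=True)
        uniform = np.full_like(p, 1.0 / p.shape[-1])
        return np.where(s > 0, p / np.where(s > 0, s, 1.0), uniform)
    raise ValueError(f"unknown normalization {normalization!r}")


def _entropy(p: np.ndarray) -> np.ndarray:
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -np.sum(plogp, axis=-1)


def label_entropy(result: InferenceResult, state: str = "converged",
                  normalization: str = "sum") -> np.ndarray:
    """Shannon entropy (nats) of the normalized top-layer activity;
    ``state`` selects the converged beliefs or the amortized sweep."""
    st = result.state_star if state == "converged" else result.sweep_state
    return _entropy(top_layer_distribution(st.mu[-1], normalization))
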