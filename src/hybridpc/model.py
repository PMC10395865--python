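"""Core data model for hierarchical predictive-coding networks.

A network is a stack of layers 0..L, where layer 0 carries the sensory
data and layer L the (label) causes.  Two weight stacks connect the
layers:

* generative (top-down) weights ``theta``: ``theta[i]`` maps layer *i*
  activity to a prediction of layer *i - 1*, as ``W @ g(mu_i)`` with the
  nonlinearity applied to the presynaptic activity;
* amortized (bottom-up) weights ``phi``: ``phi[i]`` maps layer *i - 1*
  activity to a prediction of layer *i*, as ``h(V @ mu_{i-1})`` in the
  usual feedforward-classifier convention.

Beliefs are the per-layer posterior means ``mu``; inference minimises
the Gaussian variational free energy, which with fixed precisions is a
precision-weighted sum of squared top-down prediction errors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "GenerativeWeights",
    "AmortizedWeights",
    "NetworkState",
    "ErrorState",
    "init_weights",
    "top_down_predict",
    "bottom_up_predict",
    "compute_errors",
    "free_energy",
    "error_statistic",
    "normalize_weights",
    "save_weights",
    "load_weights",
    "activation",
    "activation_deriv",
]


# ---------------------------------------------------------------------------
# activations

def activation(tag: str, x: np.ndarray) -> np.ndarray:
    """Apply the elementwise nonlinearity named by ``tag``."""
    if tag == "tanh":
        return np.tanh(x)
    if tag == "identity":
        return x
    raise ValueError(f"unknown activation tag: {tag!r}")


def activation_deriv(tag: str, x: np.ndarray) -> np.ndarray:
    """Derivative of the nonlinearity, evaluated at pre-activation ``x``."""
    if tag == "tanh":
        return 1.0 - np.tanh(x) ** 2
    if tag == "identity":
        return np.ones_like(x)
    raise ValueError(f"unknown activation tag: {tag!r}")


# ---------------------------------------------------------------------------
# configuration

class ConfigurationError(ValueError):
    """Raised when a NetworkConfig violates its invariants."""


@dataclass
class NetworkConfig:
    """Hyper-parameters of a layered predictive-coding network.

    ``layer_sizes[0]`` is the data layer.  ``gen_activation[i]`` tags the
    top-down link that predicts layer *i* from layer *i + 1*; by default
    tanh everywhere except the link into the data layer.
    ``amo_activation[i]`` tags the bottom-up link into layer *i + 1*;
    tanh everywhere except the link into the top layer.
    """

    layer_sizes: Sequence[int] = (784, 500, 500, 10)
    gen_activation: Optional[Sequence[str]] = None  # per link i=1..L
    amo_activation: Optional[Sequence[str]] = None  # per link i=1..L
    kappa: float = 0.01          # inference step size
    alpha: float = 0.01          # learning rate
    n_iters_max: int = 100       # iterative-inference cap per input
    threshold_beta: float = 0.005  # perceptual-certainty stop (summed layer MSE)
    sigma_l: float = 1.0         # likelihood variance
    sigma_p: float = 1.0         # prior variance
    top_prior: str = "none"      # "none" | "gaussian"
    top_prior_mean: float | Sequence[float] = 0.0
    mode: str = "hybrid"         # "hybrid" | "standard_pc"
    adaptive_stop: bool = False
    seed: int = 0
    # implementation switches
    update_schedule: str = "jacobi"       # "jacobi" | "sequential"
    amortized_enabled: Optional[bool] = None  # None -> follows mode
    amortized_presynaptic: str = "sweep"  # "sweep" | "converged"
    weight_norm: bool = True
    optimizer: str = "adam"               # "adam" | "sgd"
    pc_init: str = "zeros"                # "zeros" | "random"

    def __post_init__(self) -> None:
        self.layer_sizes = [int(s) for s in self.layer_sizes]
        if len(self.layer_sizes) < 2 or any(s < 1 for s in self.layer_sizes):
            raise ConfigurationError("layer_sizes must list >= 2 sizes, all >= 1")
        if self.kappa <= 0 or self.alpha <= 0:
            raise ConfigurationError("kappa and alpha must be > 0")
        if self.n_iters_max < 0:
            raise ConfigurationError("n_iters_max must be >= 0")
        if self.threshold_beta <= 0:
            raise ConfigurationError("threshold_beta must be > 0")
        if self.sigma_l <= 0 or self.sigma_p <= 0:
            raise ConfigurationError("variances must be > 0")
        if self.top_prior not in ("none", "gaussian"):
            raise ConfigurationError("top_prior must be 'none' or 'gaussian'")
        if self.mode not in ("hybrid", "standard_pc"):
            raise ConfigurationError("mode must be 'hybrid' or 'standard_pc'")
        if self.update_schedule not in ("jacobi", "sequential"):
            raise ConfigurationError("update_schedule must be 'jacobi' or 'sequential'")
        if self.amortized_presynaptic not in ("sweep", "converged"):
            raise ConfigurationError("amortized_presynaptic must be 'sweep' or 'converged'")
        L = self.n_links
        if self.gen_activation is None:
            # no activation on the link that predicts the data layer
            self.gen_activation = ["identity"] + ["tanh"] * (L - 1)
        else:
            self.gen_activation = list(self.gen_activation)
        if self.amo_activation is None:
            # no activation on the link into the (label) top layer
            self.amo_activation = ["tanh"] * (L - 1) + ["identity"]
        else:
            self.amo_activation = list(self.amo_activation)
        if len(self.gen_activation) != L or len(self.amo_activation) != L:
            raise ConfigurationError(f"activation tag lists must have length {L}")
        for tag in list(self.gen_activation) + list(self.amo_activation):
            if tag not in ("tanh", "identity"):
                raise ConfigurationError(f"unknown activation tag {tag!r}")

    # -- derived quantities ------------------------------------------------
    @property
    def n_links(self) -> int:
        """Number of links L (= number of layers minus one)."""
        return len(self.layer_sizes) - 1

    @property
    def use_amortized(self) -> bool:
        if self.amortized_enabled is not None:
            return self.amortized_enabled
        return self.mode == "hybrid"

    def prior_mean_vector(self) -> np.ndarray:
        dL = self.layer_sizes[-1]
        mu_bar = np.asarray(self.top_prior_mean, dtype=float)
        if mu_bar.ndim == 0:
            mu_bar = np.full(dL, float(mu_bar))
        if mu_bar.shape != (dL,):
            raise ConfigurationError("top_prior_mean length must equal the top layer size")
        return mu_bar

    def with_(self, **kw) -> "NetworkConfig":
        """Copy with fields replaced (activation defaults re-derived if sizes change)."""
        if "layer_sizes" in kw and "gen_activation" not in kw:
            kw.setdefault("gen_activation", None)
            kw.setdefault("amo_activation", None)
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "gen_activation": list(self.gen_activation),
            "amo_activation": list(self.amo_activation),
            "kappa": self.kappa, "alpha": self.alpha,
            "n_iters_max": self.n_iters_max, "threshold_beta": self.threshold_beta,
            "sigma_l": self.sigma_l, "sigma_p": self.sigma_p,
            "top_prior": self.top_prior,
            "top_prior_mean": (list(np.atleast_1d(self.top_prior_mean))
                               if not np.isscalar(self.top_prior_mean)
                               else self.top_prior_mean),
            "mode": self.mode, "adaptive_stop": self.adaptive_stop,
            "seed": self.seed, "update_schedule": self.update_schedule,
            "amortized_enabled": self.amortized_enabled,
            "amortized_presynaptic": self.amortized_presynaptic,
            "weight_norm": self.weight_norm, "optimizer": self.optimizer,
            "pc_init": self.pc_init,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# weights and state containers

@dataclass
class GenerativeWeights:
    """Top-down stack: matrices[i-1] is theta_i with shape (d_{i-1}, d_i)."""

    matrices: list

    def __post_init__(self) -> None:
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]

    def copy(self) -> "GenerativeWeights":
        return GenerativeWeights([m.copy() for m in self.matrices])

    def validate(self, config: NetworkConfig) -> None:
        sizes = config.layer_sizes
        if len(self.matrices) != config.n_links:
            raise ValueError("wrong number of generative matrices")
        for i, m in enumerate(self.matrices, start=1):
            if m.shape != (sizes[i - 1], sizes[i]):
                raise ValueError(f"theta_{i} has shape {m.shape}, "
                                 f"expected {(sizes[i - 1], sizes[i])}")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"theta_{i} contains non-finite entries")


@dataclass
class AmortizedWeights:
    """Bottom-up stack: matrices[i-1] is phi_i with shape (d_i, d_{i-1})."""

    matrices: list

    def __post_init__(self) -> None:
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]

    def copy(self) -> "AmortizedWeights":
        return AmortizedWeights([m.copy() for m in self.matrices])

    def validate(self, config: NetworkConfig) -> None:
        sizes = config.layer_sizes
        if len(self.matrices) != config.n_links:
            raise ValueError("wrong number of amortized matrices")
        for i, m in enumerate(self.matrices, start=1):
            if m.shape != (sizes[i], sizes[i - 1]):
                raise ValueError(f"phi_{i} has shape {m.shape}, "
                                 f"expected {(sizes[i], sizes[i - 1])}")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"phi_{i} contains non-finite entries")


@dataclass
class NetworkState:
    """Per-layer belief vectors.  Each ``mu[i]`` is (batch, d_i); a clamped
    layer's beliefs are never modified by inference."""

    mu: list
    clamped: list

    def __post_init__(self) -> None:
        self.mu = [np.atleast_2d(np.asarray(m, dtype=float)) for m in self.mu]
        self.clamped = [bool(c) for c in self.clamped]

    @property
    def batch_size(self) -> int:
        return self.mu[0].shape[0]

    def copy(self) -> "NetworkState":
        return NetworkState([m.copy() for m in self.mu], list(self.clamped))


@dataclass
class ErrorState:
    """Top-down prediction errors eps[i] = mu_i - prediction-from-above,
    for i = 0..L-1; ``eps_top`` is the top-layer prior error when a
    Gaussian prior is configured; ``eps_amo`` holds amortized errors."""

    eps: list
    eps_top: Optional[np.ndarray] = None
    eps_amo: Optional[list] = None


# ---------------------------------------------------------------------------
# operations

def init_weights(config: NetworkConfig, seed: int) -> tuple[GenerativeWeights, AmortizedWeights]:
    """Fan-in-scaled uniform initialization; independent streams for the
    generative and amortized stacks, deterministic given ``seed``."""
    ss = np.random.SeedSequence(seed)
    child_theta, child_phi = ss.spawn(2)
    rng_t = np.random.default_rng(child_theta)
    rng_p = np.random.default_rng(child_phi)
    sizes = config.layer_sizes
    theta, phi = [], []
    for i in range(1, len(sizes)):
        fan_in_t = sizes[i]
        theta.append(rng_t.uniform(-1, 1, size=(sizes[i - 1], sizes[i])) / np.sqrt(fan_in_t))
        fan_in_p = sizes[i - 1]
        phi.append(rng_p.uniform(-1, 1, size=(sizes[i], sizes[i - 1])) / np.sqrt(fan_in_p))
    return GenerativeWeights(theta), AmortizedWeights(phi)


def top_down_predict(theta_i: np.ndarray, mu_i: np.ndarray, activation_tag: str) -> np.ndarray:
    """Predict the layer below: ``theta_i @ g(mu_i)`` (activation on the
    presynaptic activity, matching the Hebbian weight update)."""
    theta_i = np.asarray(theta_i, dtype=float)
    mu_i = np.asarray(mu_i, dtype=float)
    g = activation(activation_tag, mu_i)
    if g.ndim == 1:
        return theta_i @ g
    return g @ theta_i.T


def bottom_up_predict(phi_i: np.ndarray, mu_below: np.ndarray, activation_tag: str) -> np.ndarray:
    """Predict the layer above: ``h(phi_i @ mu_below)`` (activation after
    the linear map, the feedforward-classifier convention)."""
    phi_i = np.asarray(phi_i, dtype=float)
    mu_below = np.asarray(mu_below, dtype=float)
    if mu_below.ndim == 1:
        pre = phi_i @ mu_below
    else:
        pre = mu_below @ phi_i.T
    return activation(activation_tag, pre)


def compute_errors(state: NetworkState, theta: GenerativeWeights,
                   config: NetworkConfig) -> ErrorState:
    """Top-down prediction errors at every layer below the top, plus the
    prior error at the top if a Gaussian prior is configured."""
    L = config.n_links
    eps = []
    for i in range(L):
        pred = top_down_predict(theta.matrices[i], state.mu[i + 1],
                                config.gen_activation[i])
        eps.append(state.mu[i] - pred)
    eps_top = None
    if config.top_prior == "gaussian":
        eps_top = state.mu[L] - config.prior_mean_vector()
    return ErrorState(eps=eps, eps_top=eps_top)


def free_energy(errs: ErrorState, config: NetworkConfig) -> float:
    """Gaussian variational free energy: precision-weighted sum of squared
    prediction errors plus the log-variance constant (zero at unit
    variances).  Batched inputs are averaged over examples."""
    total = 0.0
    for e in errs.eps:
        e2 = np.atleast_2d(e)
        total += np.mean(np.sum(e2 ** 2, axis=-1)) / (2.0 * config.sigma_l)
    if errs.eps_top is not None:
        e2 = np.atleast_2d(errs.eps_top)
        total += np.mean(np.sum(e2 ** 2, axis=-1)) / (2.0 * config.sigma_p)
    return float(total + 0.5 * np.log(config.sigma_l * config.sigma_p))


def error_statistic(errs: ErrorState, config: NetworkConfig) -> float:
    """Stopping statistic: sum over layers of the per-unit mean squared
    prediction error, averaged over the batch."""
    total = 0.0
    for e in errs.eps:
        e2 = np.atleast_2d(e)
        total += float(np.mean(np.mean(e2 ** 2, axis=-1)))
    if errs.eps_top is not None:
        e2 = np.atleast_2d(errs.eps_top)
        total += float(np.mean(np.mean(e2 ** 2, axis=-1)))
    return total


def normalize_weights(theta: GenerativeWeights,
                      targets=None) -> GenerativeWeights:
    """Divide each generative matrix by its mean absolute value
    (sign-preserving), i.e. rescale to unit mean-|W|.  ``targets`` may
    give a per-matrix (or scalar) target mean-|W| instead of 1 — the
    training loop uses each matrix's initialization scale as the target
    so that renormalization controls drift without changing the scale
    the inference dynamics were initialized at.  All-zero matrices are
    left untouched."""
    n = len(theta.matrices)
    if targets is None:
        targets = [1.0] * n
    elif np.isscalar(targets):
        targets = [float(targets)] * n
    out = []
    for i, (w, tgt) in enumerate(zip(theta.matrices, targets), start=1):
        scale = np.mean(np.abs(w))
        if scale == 0.0:
            logger.warning("normalize_weights: theta_%d is all zeros; skipped", i)
            out.append(w.copy())
        else:
            out.append(w * (tgt / scale))
    return GenerativeWeights(out)


# ---------------------------------------------------------------------------
# serialization

def save_weights(path, theta: GenerativeWeights, phi: AmortizedWeights,
                 config: NetworkConfig) -> None:
    """Archive both weight stacks plus the config as named arrays."""
    arrays = {}
    for i, m in enumerate(theta.matrices, start=1):
        arrays[f"theta_{i}"] = m
    for i, m in enumerate(phi.matrices, start=1):
        arrays[f"phi_{i}"] = m
    arrays["config_json"] = np.frombuffer(
        json.dumps(config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_weights(path) -> tuple[GenerativeWeights, AmortizedWeights, NetworkConfig]:
    with np.load(path) as npz:
        config = NetworkConfig.from_dict(
            json.loads(bytes(npz["config_json"].tobytes()).decode()))
        L = config.n_links
        theta = GenerativeWeights([npz[f"theta_{i}"] for i in range(1, L + 1)])
        phi = AmortizedWeights([npz[f"phi_{i}"] for i in range(1, L + 1)])
    theta.validate(config)
    phi.validate(config)
    return theta, phi, config
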