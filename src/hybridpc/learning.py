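"""Hebbian learning for both weight stacks, plus the training loop.

Generative weights follow the local rule "prediction error times
presynaptic activation" evaluated at the converged beliefs — the exact
gradient of the free energy with respect to the weights.  Amortized
weights descend the squared amortized prediction error (converged belief
minus sweep prediction) through each link's own activation, using only
layer-local quantities.  Parameters are updated by ADAM (or plain SGD)
once per batch, with the generative stack renormalized after every step
to hold each matrix's mean absolute weight at its starting scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    AmortizedWeights,
    GenerativeWeights,
    NetworkConfig,
    NetworkState,
    activation,
    activation_deriv,
    compute_errors,
    free_energy,
    init_weights,
    normalize_weights,
    top_down_predict,
)
from .inference import classify, run_inference

__all__ = [
    "AdamState",
    "TrainingTrace",
    "generative_grads",
    "amortized_grads",
    "adam_step",
    "sgd_step",
    "one_hot",
    "train_batch",
    "train",
    "evaluate",
]


@dataclass
class AdamState:
    """First/second-moment accumulators for one weight stack."""

    m: list
    v: list
    t: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps_hat: float = 1e-8

    @classmethod
    def for_stack(cls, matrices: list, **kw) -> "AdamState":
        return cls(m=[np.zeros_like(w) for w in matrices],
                   v=[np.zeros_like(w) for w in matrices], **kw)


@dataclass
class TrainingTrace:
    """Per-checkpoint training metrics."""

    checkpoints: list = field(default_factory=list)

    def append(self, **record) -> None:
        self.checkpoints.append(record)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.checkpoints)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if np.any(labels < 0) or np.any(labels >= n_classes):
        raise ValueError("label out of range")
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# gradients

def generative_grads(state_star: NetworkState, theta: GenerativeWeights,
                     config: NetworkConfig) -> list:
    """dF/dtheta_i at the converged beliefs: minus the outer product of the
    layer-(i-1) prediction error with the presynaptic activation g(mu_i),
    averaged over the batch."""
    errs = compute_errors(state_star, theta, config)
    b = state_star.batch_size
    grads = []
    for i in range(config.n_links):
        g_pre = activation(config.gen_activation[i], state_star.mu[i + 1])
        grads.append(-(errs.eps[i].T @ g_pre) / (b * config.sigma_l))
    return grads


def amortized_grads(sweep_state: NetworkState, state_star: NetworkState,
                    phi: AmortizedWeights, config: NetworkConfig) -> list:
    """Layer-local gradient of the squared amortized prediction error
    0.5 * ||mu*_i - h(phi_i mu_{i-1})||^2 with respect to phi_i.

    The presynaptic activity is the sweep-phase value by default (the
    sweep's own input to link i); the converged value is available via
    ``config.amortized_presynaptic``."""
    pres = sweep_state if config.amortized_presynaptic == "sweep" else state_star
    b = state_star.batch_size
    grads = []
    for i in range(config.n_links):
        mu_below = pres.mu[i]
        pre = mu_below @ phi.matrices[i].T
        pred = activation(config.amo_activation[i], pre)
        eps_phi = state_star.mu[i + 1] - pred
        delta = activation_deriv(config.amo_activation[i], pre) * eps_phi
        grads.append(-(delta.T @ mu_below) / b)
    return grads


# ---------------------------------------------------------------------------
# optimisers

def adam_step(matrices: list, grads: list, opt: AdamState,
              alpha: float) -> tuple[list, AdamState]:
    """One bias-corrected ADAM update opposing ``grads``."""
    t = opt.t + 1
    new_w, new_m, new_v = [], [], []
    for w, g, m, v in zip(matrices, grads, opt.m, opt.v):
        m = opt.beta1 * m + (1 - opt.beta1) * g
        v = opt.beta2 * v + (1 - opt.beta2) * g ** 2
        m_hat = m / (1 - opt.beta1 ** t)
        v_hat = v / (1 - opt.beta2 ** t)
        new_w.append(w - alpha * m_hat / (np.sqrt(v_hat) + opt.eps_hat))
        new_m.append(m)
        new_v.append(v)
    return new_w, AdamState(m=new_m, v=new_v, t=t, beta1=opt.beta1,
                            beta2=opt.beta2, eps_hat=opt.eps_hat)


def sgd_step(matrices: list, grads: list, opt: AdamState,
             alpha: float) -> tuple[list, AdamState]:
    """Plain gradient descent; the optimiser state only counts steps."""
    new_w = [w - alpha * g for w, g in zip(matrices, grads)]
    return new_w, AdamState(m=opt.m, v=opt.v, t=opt.t + 1, beta1=opt.beta1,
                            beta2=opt.beta2, eps_hat=opt.eps_hat)


def _optim(config: NetworkConfig):
    return adam_step if config.optimizer == "adam" else sgd_step


# ---------------------------------------------------------------------------
# training

def train_batch(images: np.ndarray, labels: np.ndarray,
                theta: GenerativeWeights, phi: AmortizedWeights,
                opt_theta: AdamState, opt_phi: AdamState,
                config: NetworkConfig, norm_targets=None):
    """One training step: clamp data and one-hot labels, infer, apply the
    Hebbian updates, renormalize the generative stack.

    Returns updated (theta, phi, opt_theta, opt_phi, metrics)."""
    images = np.atleast_2d(np.asarray(images, dtype=float))
    targets = one_hot(labels, config.layer_sizes[-1])
    if images.shape[0] != targets.shape[0]:
        raise ValueError("image/label batch sizes disagree")

    result = run_inference(images, theta, phi, config, clamp_top_to=targets)
    step = _optim(config)

    g_theta = generative_grads(result.state_star, theta, config)
    new_theta, opt_theta = step(theta.matrices, g_theta, opt_theta, config.alpha)
    theta = GenerativeWeights(new_theta)
    if config.weight_norm:
        theta = normalize_weights(theta, norm_targets)

    if config.use_amortized:
        g_phi = amortized_grads(result.sweep_state, result.state_star, phi, config)
        new_phi, opt_phi = step(phi.matrices, g_phi, opt_phi, config.alpha)
        phi = AmortizedWeights(new_phi)

    metrics = {
        "free_energy": result.energy_trace[-1],
        "n_iters": result.n_iters_used,
        "stopped_by": result.stopped_by,
    }
    return theta, phi, opt_theta, opt_phi, metrics


def evaluate(images: np.ndarray, labels: np.ndarray,
             theta: GenerativeWeights, phi: AmortizedWeights,
             config: NetworkConfig) -> dict:
    """Held-out metrics: accuracy of full inference (top layer free),
    accuracy of the amortized sweep alone, generative loss (MSE between
    the clamped data layer and the top-down prediction from layer 1 at
    the converged beliefs), and mean free energy."""
    labels = np.asarray(labels, dtype=int)
    result = run_inference(images, theta, phi, config)
    acc = float(np.mean(classify(result) == labels))
    if config.use_amortized:
        sweep_pred = np.argmax(result.sweep_state.mu[-1], axis=-1)
        amortized_acc = float(np.mean(sweep_pred == labels))
    else:
        amortized_acc = float("nan")
    pred0 = top_down_predict(theta.matrices[0], result.state_star.mu[1],
                             config.gen_activation[0])
    gen_loss = float(np.mean((result.state_star.mu[0] - pred0) ** 2))
    return {
        "accuracy": acc,
        "amortized_accuracy": amortized_acc,
        "generative_loss": gen_loss,
        "free_energy": result.energy_trace[-1],
        "result": result,
    }


def train(dataset, config: NetworkConfig, eval_dataset=None,
          checkpoint_every: int = 100, n_batches: int = 600,
          batch_size: int = 64,
          theta: Optional[GenerativeWeights] = None,
          phi: Optional[AmortizedWeights] = None,
          opt_theta: Optional[AdamState] = None,
          opt_phi: Optional[AdamState] = None,
          batch_offset: int = 0):
    """Train for ``n_batches`` batches over seeded shuffles of ``dataset``,
    evaluating on ``eval_dataset`` every ``checkpoint_every`` batches.

    Weights and optimiser states may be passed in to continue a run (the
    distribution-shift protocol trains in two stages).  Returns
    ``(trace, theta, phi, opt_theta, opt_phi)``.
    """
    from .data import batch_iterator  # local import to avoid a cycle

    images, labels = dataset
    if len(images) == 0:
        raise ValueError("empty training dataset")
    if theta is None or phi is None:
        theta, phi = init_weights(config, config.seed)
    if opt_theta is None:
        opt_theta = AdamState.for_stack(theta.matrices)
    if opt_phi is None:
        opt_phi = AdamState.for_stack(phi.matrices)
    # renormalize toward the entry scale the stack starts this run at
    norm_targets = [float(np.mean(np.abs(w))) for w in theta.matrices]

    trace = TrainingTrace()
    window_iters: list = []
    window_fe: list = []
    done = 0
    epoch = 0
    while done < n_batches:
        # reshuffle each pass through the data, seeded per epoch
        epoch_seed = (config.seed * 100003 + batch_offset + epoch) % (2 ** 31)
        for bx, by in batch_iterator(images, labels, batch_size, seed=epoch_seed):
            if done >= n_batches:
                break
            theta, phi, opt_theta, opt_phi, metrics = train_batch(
                bx, by, theta, phi, opt_theta, opt_phi, config,
                norm_targets=norm_targets)
            window_iters.append(metrics["n_iters"])
            window_fe.append(metrics["free_energy"])
            done += 1
            if done % checkpoint_every == 0:
                record = {
                    "batch_index": batch_offset + done,
                    "mean_iterations": float(np.mean(window_iters)),
                    "mean_free_energy": float(np.mean(window_fe)),
                }
                if eval_dataset is not None:
                    ev = evaluate(eval_dataset[0], eval_dataset[1],
                                  theta, phi, config)
                    record["hybrid_accuracy"] = ev["accuracy"]
                    record["amortized_accuracy"] = ev["amortized_accuracy"]
                    record["generative_loss"] = ev["generative_loss"]
                trace.append(**record)
                window_iters, window_fe = [], []
        epoch += 1
    return trace, theta, phi, opt_theta, opt_phi
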