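"""Experiment protocols: classification/generation, fast inference,
fixed-iteration budgets, limited data, and distribution shift.

Each driver is a pure function of (network config, dataset spec, seeds)
and returns an :class:`ExperimentReport` of tidy metric tables — one row
per (seed, checkpoint, condition) — so reruns with the same arguments
are bit-identical.  Default problem sizes are desk scale: 12x12 glyphs,
a [144, 192, 192, 10] network, batch 64, a checkpoint every 20 batches and
about 200 batches of training, which keeps every protocol in the
seconds-to-minutes range on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GlyphDatasetSpec, make_glyph_dataset, split_by_label
from .inference import classify, generate, label_entropy, run_inference
from .learning import AdamState, train
from .model import NetworkConfig, init_weights

__all__ = [
    "ExperimentReport",
    "desk_config",
    "desk_data_spec",
    "make_train_test",
    "exp_classify_and_generate",
    "exp_fast_inference",
    "exp_fixed_iterations",
    "exp_limited_data",
    "exp_distribution_shift",
    "entropy_refinement",
    "inference_entropy_trace",
    "write_report",
    "EXPERIMENTS",
]

DEFAULT_ITERATION_GRID = (10, 25, 50, 100)
DEFAULT_SIZE_GRID = (100, 500, 1000, 5000)


@dataclass
class ExperimentReport:
    name: str
    config: dict
    seeds: list
    tables: dict = field(default_factory=dict)


def desk_config(**overrides) -> NetworkConfig:
    """Desk-scale network matching the study architecture shape: data
    layer, two hidden layers, a 10-way label layer.  Hidden width 192
    keeps enough joint generative/amortized capacity for the residual
    prediction errors to fall below the certainty threshold on the glyph
    task (narrow desk nets plateau above it)."""
    kw = dict(layer_sizes=[144, 192, 192, 10])
    kw.update(overrides)
    return NetworkConfig(**kw)


def desk_data_spec(**overrides) -> GlyphDatasetSpec:
    kw = dict(image_side=12, n_classes=10, n_examples=2500,
              noise_sd=0.05, jitter=1, seed=0)
    kw.update(overrides)
    return GlyphDatasetSpec(**kw)


def make_train_test(data_spec: GlyphDatasetSpec, n_test: int = 500):
    """Generate one pool and split it by index into disjoint train / test
    sets (the same pool for every network seed)."""
    images, labels = make_glyph_dataset(data_spec)
    if n_test >= len(images):
        raise ValueError("n_test must leave at least one training example")
    train_set = (images[:-n_test], labels[:-n_test])
    test_set = (images[-n_test:], labels[-n_test:])
    return train_set, test_set


def _trace_df(trace, seed: int, **extra) -> pd.DataFrame:
    df = trace.to_dataframe()
    df.insert(0, "seed", seed)
    for k, v in extra.items():
        df[k] = v
    return df


# ---------------------------------------------------------------------------

def exp_classify_and_generate(config: NetworkConfig, data_spec: GlyphDatasetSpec,
                              seeds, n_batches: int = 200,
                              checkpoint_every: int = 20,
                              n_test: int = 500) -> ExperimentReport:
    """Train hybrid and standard predictive-coding models on the same data;
    record hybrid / amortized-sweep / standard-PC accuracies and the
    generative loss per checkpoint, and one generated image per class
    from each trained model."""
    train_set, test_set = make_train_test(data_spec, n_test)
    acc_rows, gen_rows = [], []
    for seed in seeds:
        frames = {}
        models = {}
        for mode in ("hybrid", "standard_pc"):
            cfg = config.with_(mode=mode, seed=int(seed))
            trace, theta, phi, *_ = train(
                train_set, cfg, eval_dataset=test_set,
                checkpoint_every=checkpoint_every, n_batches=n_batches)
            frames[mode] = trace.to_dataframe()
            models[mode] = (theta, phi, cfg)
        h, p = frames["hybrid"], frames["standard_pc"]
        merged = pd.DataFrame({
            "seed": seed,
            "batch_index": h["batch_index"],
            "hybrid_accuracy": h["hybrid_accuracy"],
            "amortized_accuracy": h["amortized_accuracy"],
            "pc_accuracy": p["hybrid_accuracy"],
            "generative_loss_hybrid": h["generative_loss"],
            "generative_loss_pc": p["generative_loss"],
            "mean_iterations_hybrid": h["mean_iterations"],
            "mean_iterations_pc": p["mean_iterations"],
        })
        acc_rows.append(merged)
        for mode, (theta, phi, cfg) in models.items():
            for label in range(cfg.layer_sizes[-1]):
                img = generate(theta, label, cfg)
                row = {"seed": seed, "model": mode, "label": label}
                row.update({f"p{j}": v for j, v in enumerate(img)})
                gen_rows.append(row)
    accuracy = pd.concat(acc_rows, ignore_index=True)
    summary = (accuracy.drop(columns="seed")
               .groupby("batch_index").agg(["mean", "std"]))
    summary.columns = ["_".join(c) for c in summary.columns]
    report = ExperimentReport("classify_generate", config.to_dict(), list(seeds))
    report.tables["accuracy"] = accuracy
    report.tables["accuracy_summary"] = summary.reset_index()
    report.tables["generated"] = pd.DataFrame(gen_rows)
    return report


def exp_fast_inference(config: NetworkConfig, data_spec: GlyphDatasetSpec,
                       seeds, n_batches: int = 200, checkpoint_every: int = 20,
                       n_test: int = 500) -> ExperimentReport:
    """Hybrid training under the adaptive certainty threshold; records
    accuracy and mean iterations-to-threshold per checkpoint."""
    if not config.adaptive_stop:
        config = config.with_(adaptive_stop=True)
    train_set, test_set = make_train_test(data_spec, n_test)
    rows = []
    for seed in seeds:
        cfg = config.with_(mode="hybrid", seed=int(seed))
        trace, *_ = train(train_set, cfg, eval_dataset=test_set,
                          checkpoint_every=checkpoint_every, n_batches=n_batches)
        rows.append(_trace_df(trace, seed))
    report = ExperimentReport("fast_inference", config.to_dict(), list(seeds))
    report.tables["iterations"] = pd.concat(rows, ignore_index=True)
    return report


def exp_fixed_iterations(config: NetworkConfig, data_spec: GlyphDatasetSpec,
                         seeds, iteration_grid=DEFAULT_ITERATION_GRID,
                         n_batches: int = 200, checkpoint_every: int = 20,
                         n_test: int = 500) -> ExperimentReport:
    """Hybrid vs standard PC at fixed iteration budgets (no threshold)."""
    if not iteration_grid:
        raise ValueError("iteration_grid must be non-empty")
    train_set, test_set = make_train_test(data_spec, n_test)
    rows = []
    for seed in seeds:
        for n_iters in iteration_grid:
            for mode in ("hybrid", "standard_pc"):
                cfg = config.with_(mode=mode, seed=int(seed),
                                   adaptive_stop=False, n_iters_max=int(n_iters))
                trace, *_ = train(train_set, cfg, eval_dataset=test_set,
                                  checkpoint_every=checkpoint_every,
                                  n_batches=n_batches)
                rows.append(_trace_df(trace, seed, n_iters=int(n_iters), model=mode))
    report = ExperimentReport("fixed_iterations", config.to_dict(), list(seeds))
    report.tables["accuracy"] = pd.concat(rows, ignore_index=True)
    return report


def exp_limited_data(config: NetworkConfig, data_spec: GlyphDatasetSpec,
                     seeds, size_grid=DEFAULT_SIZE_GRID,
                     n_batches: int = 200, checkpoint_every: int = 20,
                     n_test: int = 500) -> ExperimentReport:
    """Hybrid vs amortized-sweep accuracy as a function of training-set
    size, on a fixed held-out set disjoint from every training subset."""
    train_set, test_set = make_train_test(data_spec, n_test)
    pool_images, pool_labels = train_set
    if max(size_grid) > len(pool_images):
        raise ValueError("size_grid exceeds the available training pool")
    rows = []
    for seed in seeds:
        for size in size_grid:
            # subset drawn once per (seed, size)
            rng = np.random.default_rng(int(seed) * 7919 + int(size))
            idx = rng.choice(len(pool_images), size=int(size), replace=False)
            subset = (pool_images[idx], pool_labels[idx])
            cfg = config.with_(mode="hybrid", seed=int(seed))
            trace, *_ = train(subset, cfg, eval_dataset=test_set,
                              checkpoint_every=checkpoint_every,
                              n_batches=n_batches)
            rows.append(_trace_df(trace, seed, train_size=int(size)))
    report = ExperimentReport("limited_data", config.to_dict(), list(seeds))
    report.tables["accuracy"] = pd.concat(rows, ignore_index=True)
    return report


def exp_distribution_shift(config: NetworkConfig, data_spec: GlyphDatasetSpec,
                           seeds, checkpoint_every: int = 20,
                           max_batches_a: int = 300, n_batches_b: int = 100,
                           plateau_fraction: float = 0.1,
                           plateau_checkpoints: int = 3,
                           label_sets=((0, 1, 2, 3, 4, 5), (5, 6, 7, 8, 9)),
                           n_test: int = 500) -> ExperimentReport:
    """Train under the adaptive threshold on one label split until the
    mean iteration count plateaus (below ``plateau_fraction`` of the cap
    for ``plateau_checkpoints`` consecutive checkpoints, or the batch
    budget runs out), then switch to the second split and continue."""
    if not config.adaptive_stop:
        config = config.with_(adaptive_stop=True)
    train_set, test_set = make_train_test(data_spec, n_test)
    (train_a, train_b) = split_by_label(*train_set, label_sets)
    (test_a, test_b) = split_by_label(*test_set, label_sets)
    rows, meta_rows, entropy_rows = [], [], []
    for seed in seeds:
        cfg = config.with_(mode="hybrid", seed=int(seed))
        theta, phi = init_weights(cfg, cfg.seed)
        opt_t = AdamState.for_stack(theta.matrices)
        opt_p = AdamState.for_stack(phi.matrices)
        records = []
        done = 0
        plateau_run = 0
        while done < max_batches_a:
            trace, theta, phi, opt_t, opt_p = train(
                train_a, cfg, eval_dataset=test_a,
                checkpoint_every=checkpoint_every, n_batches=checkpoint_every,
                theta=theta, phi=phi, opt_theta=opt_t, opt_phi=opt_p,
                batch_offset=done)
            rec = trace.checkpoints[0]
            rec["phase"] = "pre_switch"
            records.append(rec)
            done += checkpoint_every
            if rec["mean_iterations"] < plateau_fraction * cfg.n_iters_max:
                plateau_run += 1
            else:
                plateau_run = 0
            if plateau_run >= plateau_checkpoints:
                break
        switch_batch = done
        post = 0
        while post < n_batches_b:
            trace, theta, phi, opt_t, opt_p = train(
                train_b, cfg, eval_dataset=test_b,
                checkpoint_every=checkpoint_every, n_batches=checkpoint_every,
                theta=theta, phi=phi, opt_theta=opt_t, opt_phi=opt_p,
                batch_offset=done + post)
            rec = trace.checkpoints[0]
            rec["phase"] = "post_switch"
            records.append(rec)
            post += checkpoint_every
        df = pd.DataFrame(records)
        df.insert(0, "seed", seed)
        rows.append(df)
        meta_rows.append({"seed": seed, "switch_batch": switch_batch})
        # per-iteration entropy over one inference phase on the new split
        ent = inference_entropy_trace(test_b[0][:64], theta, phi,
                                      cfg.with_(adaptive_stop=False))
        entropy_rows.append(pd.DataFrame({
            "seed": seed, "iteration": np.arange(len(ent)), "entropy": ent}))
    report = ExperimentReport("distribution_shift", config.to_dict(), list(seeds))
    report.tables["iterations"] = pd.concat(rows, ignore_index=True)
    report.tables["switch"] = pd.DataFrame(meta_rows)
    report.tables["entropy_trace"] = pd.concat(entropy_rows, ignore_index=True)
    return report


# ---------------------------------------------------------------------------
# readout helpers shared by experiments and acceptance checks

def inference_entropy_trace(images, theta, phi, config) -> np.ndarray:
    """Mean label entropy after the sweep and after each iterative step
    of a single inference phase (top layer unclamped)."""
    from .inference import _entropy, _init_state, iterative_step, top_layer_distribution
    state = _init_state(images, phi, config)
    def ent(s):
        return float(np.mean(_entropy(top_layer_distribution(s.mu[-1]))))
    trace = [ent(state)]
    for _ in range(config.n_iters_max):
        state = iterative_step(state, theta, config)
        trace.append(ent(state))
    return np.asarray(trace)


def entropy_refinement(images, labels, theta, phi, config):
    """Fraction of correctly classified items whose label entropy after
    iterative inference is <= the entropy of the amortized sweep."""
    result = run_inference(images, theta, phi, config)
    correct = classify(result) == np.asarray(labels)
    if not correct.any():
        return float("nan"), 0
    e_final = label_entropy(result, "converged")[correct]
    e_sweep = label_entropy(result, "sweep")[correct]
    return float(np.mean(e_final <= e_sweep)), int(correct.sum())


# ---------------------------------------------------------------------------
# report output

def _write_pgm(path, pixels: np.ndarray, side: int) -> None:
    img = np.clip(np.round(np.asarray(pixels).reshape(side, side) * 255), 0, 255)
    with open(path, "w") as fh:
        fh.write(f"P2\n{side} {side}\n255\n")
        for row in img.astype(int):
            fh.write(" ".join(str(v) for v in row) + "\n")


def write_report(report: ExperimentReport, out_dir, image_side: int | None = None) -> None:
    """Write report.json plus one CSV per table; rows of a ``generated``
    table are additionally written as PGM images."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump({"name": report.name, "config": report.config,
                   "seeds": [int(s) for s in report.seeds],
                   "tables": sorted(report.tables)}, fh, indent=2)
    for name, df in report.tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    gen = report.tables.get("generated")
    if gen is not None and image_side:
        for _, row in gen.iterrows():
            pix = row[[c for c in gen.columns if c.startswith("p") and c[1:].isdigit()]]
            _write_pgm(out / f"generated_{row['model']}_seed{row['seed']}_label{row['label']}.pgm",
                       pix.to_numpy(dtype=float), image_side)


EXPERIMENTS = {
    "classify_generate": exp_classify_and_generate,
    "fast_inference": exp_fast_inference,
    "fixed_iterations": exp_fixed_iterations,
    "limited_data": exp_limited_data,
    "distribution_shift": exp_distribution_shift,
}
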