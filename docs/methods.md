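# Methods

## Model

`hybridpc` implements a hierarchical Gaussian predictive-coding network
with an amortized (bottom-up) pathway. The network is a stack of layers
0..L; layer 0 carries the sensory data (a flattened grayscale image),
layer L the label causes. Beliefs are per-layer posterior means
μ_0..μ_L. Two weight stacks connect adjacent layers:

* **Generative (top-down) weights** θ_1..θ_L. Link *i* predicts layer
  *i−1* from layer *i* as θ_i·g(μ_i), with g = tanh on every link except
  the link into the data layer, which is linear. The activation is
  applied to the presynaptic activity so that the weight update is a
  plain Hebbian outer product (error × presynaptic activation).
* **Amortized (bottom-up) weights** φ_1..φ_L. Link *i* predicts layer
  *i* from layer *i−1* as h(φ_i·μ_{i−1}), tanh on every link except the
  link into the label layer — the standard feedforward-classifier
  convention, so the label readout is unsquashed.

With fixed unit variances the variational free energy reduces to half
the summed squared top-down prediction errors,

    F = Σ_i (1/2σ_l) ‖ε_i‖²,   ε_i = μ_i − θ_{i+1}·g(μ_{i+1}),

plus an optional top-layer prior term (disabled by default; a Gaussian
prior with mean μ̄ and variance σ_p can be switched on, which is how the
closed-form linear-Gaussian tests pin the dynamics down). The constant
½·ln(σ_l σ_p) vanishes at unit variances. Batched inputs are averaged
over examples.

**Inference** runs in two phases. In hybrid mode a single bottom-up
sweep through φ initializes every layer's beliefs from the clamped data;
in standard predictive-coding mode unclamped beliefs start at zero. The
iterative phase then performs gradient descent on F with step size
κ = 0.01:

    μ_i ← μ_i + κ·( g'(μ_i) ⊙ (θ_iᵀ ε_{i−1}) − ε_i ),

for every unclamped layer, up to N = 100 steps. All layers are updated
simultaneously from start-of-step errors (Jacobi scheduling), which
makes the step an exact gradient-descent step on F and keeps runs
deterministic; a layer-sequential (Gauss–Seidel) variant is available
via `update_schedule="sequential"`. When `adaptive_stop` is on,
iteration halts as soon as the summed per-layer per-unit mean squared
prediction error, averaged over the batch, falls below the perceptual
certainty threshold β = 0.005.

**Learning** is local. After inference converges to μ*, the generative
update is the negative free-energy gradient Δθ_i ∝ ε_{i−1} ⊗ g(μ*_i)ᵀ.
The amortized update descends the squared amortized prediction error
εφ_i = μ*_i − h(φ_i·μ_{i−1}) through the link's own activation, with the
sweep-phase value as the presynaptic factor (the converged value can be
selected via `amortized_presynaptic="converged"`). Both stacks are
stepped once per batch by ADAM (β1 = 0.9, β2 = 0.999, ε = 1e−8 —
conventional defaults; the optimiser is interchangeable and a plain-SGD
option exists) with learning rate α = 0.01. During training the data
layer is clamped to the image and the label layer to the one-hot label;
at test time only the data layer is clamped and the predicted label is
the argmax of the top layer.

## Weight normalization

The generative stack is renormalized after every optimiser step by
dividing each matrix by its mean absolute entry — a sign-preserving
rescaling that stops the weight magnitudes from drifting during
training, which otherwise degrades classification in the pure
predictive-coding network. The exposed `normalize_weights` op rescales
to unit mean-|W| by default; the training loop passes each matrix's
*initialization* mean-|W| as the target instead, because rescaling
fan-in-initialized weights all the way to unit mean-|W| inflates
predictions by a factor of order the fan-in and makes the inference
dynamics diverge. Drift control, not scale change, is what the
procedure needs.

## Initialization and randomness

Weights are drawn from a zero-centred uniform distribution scaled by
1/√fan-in, with independent seeded streams for θ and φ. Every source of
randomness (weight init, batch shuffling, glyph rendering, subset
draws) flows from explicit integer seeds, so training traces and
experiment reports are bit-reproducible.

## Synthetic glyph data

The bundled generator renders one fixed binary seven-segment glyph per
class (ten distinct templates) onto a 12×12 canvas, applies integer
translation jitter (default ±1 px) and additive Gaussian pixel noise,
and clips to [0, 1]. It emulates the essential features of a small
handwritten-digit task: grayscale images with a dark background, a
deterministic class-conditional shape, and nuisance variation
(position, noise) that the top layer cannot predict. It does **not**
emulate stroke-style variability, class overlap, or heavy-tailed pixel
statistics, so passing results here demonstrate the mechanics of the
algorithm — amortization, adaptive computation, data efficiency — not
performance on real handwriting.

Default noise is σ = 0.05. The stopping threshold (0.005, a mean
squared error) must sit above the irreducible per-pixel noise floor σ²
for adaptive stopping ever to engage; σ = 0.05 leaves the floor at
0.0025, half the threshold, mirroring real digit images whose
near-binary pixels have an effectively negligible noise floor.

## Desk-scale experiment defaults

Experiments run on a [144, 192, 192, 10] network (data layer, two
hidden layers, 10 label units), batch size 64, a checkpoint every 20
batches and on the order of a few hundred batches, with 2 000 training
and 500 held-out examples. Hidden width matters: the adaptive threshold
is only reachable once the generative and amortized stacks are jointly
expressive enough that residual cross-layer prediction errors fall
below β; 64-wide hidden layers plateau around 0.013–0.014 and never
stop early, while 192-wide layers cross the threshold within ~750
batches and iteration counts collapse to zero, reproducing the
fast-inference phenomenology. The width-to-class ratio (192:10) is also
closer to the reference architecture (500:10).

The distribution-shift protocol trains on the label split {0..5} until
the per-checkpoint mean iteration count stays below 10 % of the
iteration cap for three consecutive checkpoints (or a batch budget runs
out), then switches to {5..9}; the split deliberately shares label 5,
and a disjoint split is available. The plateau rule is this package's
choice — the protocol only requires "trained until fast".

## Numerical choices and degenerate inputs

* Classification ties break toward the lowest label index (argmax).
* Label entropy uses a softmax normalization of the top layer: raw
  activities can be negative, so plain division by the sum is not a
  distribution; softmax is monotone in the activities and makes the
  uniform and near-delta limits exact.
* All-zero generative matrices are skipped by normalization (with a
  warning) rather than divided by zero.
* `n_iters_max = 0` returns the initialization unchanged; a network
  whose initialization already satisfies the threshold reports zero
  iterations with `stopped_by="threshold"`.
* During generation the top layer is clamped to the one-hot label and
  every lower layer (data layer included) starts at zero and relaxes
  freely; zeros are the natural "no evidence" initialization.
* IDX files are parsed big-endian with strict magic-number and payload
  length checks; images are scaled from bytes to [0, 1].

## The standard predictive-coding baseline at desk scale

With fan-in-scaled (drift-controlled) generative weights, the
backpressure term g′⊙(θᵀε) in the belief update is small, so zero-
initialized iterative inference propagates label evidence slowly: the
standard-PC baseline needs far more than 100 steps of size κ = 0.01 to
commit its top layer, learns much more slowly than the hybrid model,
and its test accuracy can decline over training while its generative
loss still improves — the same training instability the hybrid
architecture is reported to avoid at constrained iteration budgets.
Rescaling the weights to unit mean absolute value would speed the
dynamics but violates the step-size stability bound κ·λmax(θᵀθ) < 2 at
these layer widths and makes inference diverge outright. The package
therefore presents standard PC as a like-for-like baseline under
identical κ and N rather than a tuned competitor; the hybrid/PC
comparisons (iteration budgets, adaptive computation) are unaffected.

## Known limitations

* Precisions σ_l, σ_p are fixed, never learned; there is no
  precision-weighting schedule.
* The approximate posterior is a point mass in practice (means only).
* Static images only — no temporal stimuli or multi-rate updating.
* The glyph task is linearly separable; it cannot probe the regime
  where iterative refinement must resolve genuinely ambiguous inputs.
* Weight normalization interacts with ADAM's per-parameter step sizes;
  the combination is stable in all protocols here but is not a
  projection-consistent optimiser in the strict sense.
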