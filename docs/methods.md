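# Methods

## Generative models

All simulators emit a `Trajectory`: exactly `N` positions at times `i·Δt`
(`Δt = 1/30 s`), starting at the origin, coordinates in micrometres. The
absolute start position carries no information for any downstream
computation — the encoder re-centres every trajectory — so it is fixed at
the origin.

**Normal diffusion.** Each step has an isotropic direction
φ ~ U[0, 2π) and a Rayleigh-distributed length with density
`P(u) = (2u/4DΔt)·exp(−u²/4DΔt)`, so `E[u²] = 4DΔt` matches the 2-D
Brownian MSD per frame. Sampling is by inverse CDF,
`u = sqrt(−4DΔt·ln(1−U))`, which is exact and reproducible given the same
uniform stream.

**Directed motion.** A normal-diffusion step plus the deterministic drift
`(vΔt·cos β, vΔt·sin β)`; β is drawn once per trajectory. The sampled
control is the active-motion-to-diffusion ratio `R = v²T/(4D)` with
`T = NΔt`, inverted to `v = sqrt(4DR/T)`.

**Confined diffusion.** Each frame is divided into 100 sub-steps at
`Δt′ = Δt/100` with the diffusion coefficient unchanged. A sub-step is
accepted only if the proposed position lies strictly inside the circle of
radius `r_c` centred on the start position; a rejected sub-step leaves the
particle in place. Rejection per sub-step (rather than discarding the whole
frame) is the standard reflecting-boundary surrogate and avoids step-scale
artifacts. The control is the boundedness `B`, inverted to
`r_c = sqrt(DNΔt/B)`. Containment is exact by construction: every recorded
position is within `r_c` of the origin.

**Fractional Brownian motion.** x and y are independent exact FBM paths
scaled by `sqrt(2D)`, so the 2-D ensemble MSD is `4DΔ^α` with `α = 2H`.
Increments are sampled by Davies–Harte circulant embedding (exact
covariance; FFT cost); if the embedding is not non-negative definite the
sampler falls back to a Cholesky factorization of the increment covariance,
which is always exact. Subdiffusion restricts `H ∈ (0, 1/2)`; `H ≥ 1/2` is
available behind an explicit override for testing the Brownian limit.

**Localization noise.** i.i.d. N(0, σ²) on every coordinate with
`σ = sqrt(DΔt)/Q` (ND, CD, FBM) or `σ = sqrt(DΔt + (vΔt)²)/Q` (DM). The
SNR `Q` is a sampled per-trajectory parameter.

**Sampling distributions.** The source conditions state only ranges, not
distributions; all continuous parameters are uniform on their ranges and
`N` is uniform over integers. A root seed spawns one child stream per
trajectory (numpy `SeedSequence`), so corpora are bit-reproducible and
order-independent.

## Corpus and encoding

Default corpus: 5,000 noisy trajectories per class (20,000 total),
stratified 70/15/15 into train/validation/test with largest-remainder
rounding per class (ties resolved in split order), giving 3,500/750/750 per
class per split at the default size.

Network inputs are fixed-size one-channel vectors: the trajectory is
translated so it starts at the origin, the `(2, L)` coordinate block is
flattened row-major (`[x_0..x_L, y_0..y_L]`) and each coordinate block is
zero-padded to `fixed_length = 600` frames (vector length 1,200). The true
length is retained. Inter-leaving the coordinates instead of concatenating
them is supported but trains noticeably worse; a two-channel layout exists
behind a flag for experiments (it changes the parameter count by +40 and is
therefore not the default). No per-feature standardization is applied —
each convolution is immediately followed by a normalization layer, which
absorbs the input scale.

## Architecture

Stem of three convolutions with widths `(x0/4, x0, x0)` (first one stride
2), max-pool 3/2; `depth` stages of two residual units each with widths
`x_i = x0·2^{i−1}`; each unit is conv–norm–act–conv–norm plus a skip, the
first unit of stages 2+ downsampling by stride 2 with an
average-pool + 1×1-conv + norm projection shortcut. Global average pooling
feeds a single dense layer of 4 units; softmax is applied by the loss and
the predictor. A plain variant (single kernel-7 stem convolution, strided
1×1 projection shortcuts) covers the unmodified baseline; a 2-D variant
treats the trajectory as a one-channel `2×L` array.

Every normalization layer holds three trainable per-channel vectors: scale
γ, shift β, and an activation threshold θ that is subtracted from the
normalized output, so the following activation fires only above a learned
level. θ exists on every norm layer (including projection shortcuts, where
it merges with the shift) — this placement is what makes the analytic
per-layer budget close at exactly 399,556 parameters for the default
configuration, the number the whole layout is calibrated against. The
committed golden manifest (`anomdiff/data/final_architecture_layers.json`)
freezes that per-layer budget; tests compare the built network against it
and against an independent closed-form count.

Two deliberate defaults differ from the classic recipe:

* **No zero-initialization of the final norm scale in residual branches.**
  The mechanism is implemented (`zero_init_residual=True`) and keeps each
  unit an exact identity at initialization, but at the fixed learning rate
  3·10⁻⁴ the zeroed scales grow by only ~lr per optimizer step, so the
  branches stay effectively dead for the first several hundred steps and
  short training runs stall. With ordinary unit scales the same runs learn
  promptly.
* **Masked global pooling** (`masked_pooling=True`): the pooled average is
  restricted to positions backed by real samples, tracked through the
  stride-2 reductions. Plain pooling would dilute a 30-frame trajectory's
  features ~20-fold with padding zeros. The padding scheme is not fixed by
  the source conditions; masking is parameter-free and switchable.

Optional inputs: any subset of the four auxiliary scalars joins the pooled
vector before the dense layer (+4 parameters each, +16 for all four);
step-autocorrelation values at lags 8, 16, 24 can join as three tiled input
channels (+120 parameters). The printed budget delta reported for the
autocorrelation variant in the source (+2,316) does not correspond to any
input-channel arithmetic under this layout; the tensor shape of that
variant is underdetermined and the scalar-per-lag reading is used.

## Training

Squared error between softmax outputs and one-hot targets (sum over the 4
classes, mean over the batch); cross-entropy available. Adam (β = 0.9/0.999,
ε = 10⁻⁸) at learning rate 3·10⁻⁴ — the optimizer itself is not fixed by
the source conditions; Adam is the community default at this rate. Batch
512 at full scale. Training always runs to `max_epochs` (default 70) and
restores the weights of the best validation epoch; accuracies are
end-of-epoch re-evaluations in inference mode.

Selective backprop recomputes its selection per batch from that batch's
forward losses: `loss_coverage(f)` keeps the shortest descending-loss
prefix reaching a fraction `f` of the batch loss, `top_fraction(f)` keeps
the `⌈fn⌉` highest losses; unselected samples still contribute to the
forward statistics but not to the gradient. Epoch-level fractions are
aggregates of the per-batch selections.

## Evaluation

Confusion matrices use rows = true, columns = predicted, class order FBM,
CD, DM, ND everywhere. Per-class precision, recall and F1 come from the
matrix; aggregate values are unweighted (macro) means — with class-balanced
test splits macro and micro accuracy coincide. A never-predicted class gets
precision 0 with a flag. The coarse three-way report folds FBM and CD into
subdiffusion, ND into normal diffusion, DM into superdiffusion.
`metrics_over_instances` trains k independent seeds and bands each metric
trajectory as mean ± 1.96·sd/√k (normal approximation; the CI method is not
fixed by the source conditions).

## Problem sizes used by the test suite

The training-dependent tests share one scaled-down study: 500 trajectories
per class (2,000 total) under the default parameter ranges, the final
architecture, 10 epochs. The batch size shrinks with the corpus, to 32:
a proportional batch (512·2000/14000 ≈ 73) leaves each epoch with
one-seventh of the full study's unique data but a comparable step count,
which demonstrably under-trains at the fixed epoch budget; batch 32 keeps
~44 optimizer steps per epoch, the same order as the full study's ~27.
Under these conditions the model reaches ≈0.87 validation accuracy with the
subdiffusive classes recalled best. Statistical simulator checks run at
their stated sizes (e.g. 2,000 trajectories for ensemble MSDs, 500 per
exponent for FBM recovery). BLAS is pinned to one thread in the suite so
results are bit-reproducible across machines.

What desk-scale results do and do not show: the scaled corpus preserves the
parameter ranges, noise model and class balance of the full study, so
moment identities and qualitative orderings transfer; absolute accuracies
do not — headline-level accuracy (≈0.90) requires the full 20,000-trajectory
corpus (`examples/full_reproduction.py`). The synthetic corpus itself
emulates idealized SPT data: uniform frame intervals, Gaussian localization
noise of constant per-trajectory level, exactly one motion mode per
trajectory, no blinking, drift of the stage, or mode switching — real
trajectories violate several of these, so synthetic accuracy is an upper
bound.

## Numerical choices and degenerate inputs

float32 arithmetic throughout the network; convolutions via im2col and one
BLAS product per layer; batch-norm eps 10⁻⁵, running-stat momentum 0.1.
Stride-2 reductions use ceiling length arithmetic everywhere (the shortcut
average-pool runs in ceil mode so both branches agree on odd lengths).
Degenerate cases are errors, not silent results: trajectories shorter than
2 points, TAMSD lags beyond the trajectory, zero-variance trajectories in
the autocorrelation, all-zero losses under coverage selection (returns the
full batch), empty splits, non-finite losses (reported with the epoch).
Selection ties break on the original sample index, stratified-rounding ties
in split order — both deterministic.

## Known limitations

* The numpy engine is single-device and unaccelerated; the full-scale run
  takes hours where a GPU framework takes minutes.
* The 2-D architecture variant exists for parameter-count ablations and
  small forward/backward checks; it has not been trained at scale.
* Irregular sampling, 3-D trajectories and mode-switching trajectories are
  out of scope; user-supplied CSVs must be uniformly sampled.
* The classifier's probabilities are uncalibrated; the coarse three-way
  proportions inherit any class-level bias of the underlying model.
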