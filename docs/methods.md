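# Methods

## Model

`bayesenc` fits convolutional encoders that map visual stimuli
x (channels × height × width) to non-negative predicted responses
r̂ = f_w(x) of a recorded neuron population. The shared architecture is

    conv(k₁×k₁, valid, stride 1) → ReLU → conv(k₂×k₂, valid, stride 1) → ReLU
    → flatten → fully connected → exp

The exponential output guarantees strictly positive rates, matching the
Poisson observation model

    −log P(D | w) = Σ_l  r̂_l − r_l log r̂_l ,

summed over neurons and stimuli (no log r! term — responses are real-valued
calcium signals, and the term would be constant in w anyway).

In the **variational** variant every weight and bias carries an independent
Gaussian posterior q(w_k | θ) = N(μ_k, σ_k²) with σ = log(1 + exp(ρ))
(Bayes by backprop). The prior is a zero-mean scale mixture of two
Gaussians, π N(0, σ₁²) + (1 − π) N(0, σ₂²), with defaults π = 0.5, σ₁ = 1,
σ₂ = exp(−6) for all layers; the narrow component acts as a spike at zero
and induces sparsity in the learned means. Training minimizes the tempered
Monte-Carlo bound

    L ≈ (1/n) Σ_i  β_v · kl_scale · (log q(w⁽ⁱ⁾|θ) − log P(w⁽ⁱ⁾))
                   + PoissonNLL(D | w⁽ⁱ⁾)

with reparameterized draws w⁽ⁱ⁾ = μ + σ·ε. β_v is the Lagrangian KL
multiplier: β_v = 1 is the untempered bound, β_v < 1 the cold-posterior
regime that empirically predicts best, and large β_v forces the posterior
toward the prior (sparse, underfit weights). n = 1 sample per training step
by default; results were insensitive to n in pilot fits.

**Control variants** share the forward map: an unregularized baseline;
L2 (conv) + L1 (FC) penalties; a MAP model (likelihood + scaled log-prior,
no entropy term); MC dropout with one rate in every layer, active during
training *and* prediction; and a seed ensemble of L2+L1 models averaged at
prediction time.

## Objective weighting conventions

The Poisson NLL is *summed* over the stimuli in a batch, and KL/prior
penalties are multiplied by `kl_scale = 1 / n_batches`, so each is counted
exactly once per pass over the training data. Under this pairing the
per-epoch objective equals the dataset-level bound and **β_v is invariant
to the batch size**. Averaging the NLL over the batch instead would
silently rescale the effective β_v by the batch size; we verified that under
that convention β_v loses its documented meaning (no performance collapse
at β_v = 10 on the synthetic conditions). The L2+L1 penalty is scaled by
`kl_scale` for the same reason, so λ₂ and λ₁ are dataset-level
coefficients.

Gradients are assembled analytically. For a fixed noise draw ε the
KL-term derivatives reduce to

    ∂/∂μ (log q − log P) = −∂ log P/∂w ,
    ∂/∂ρ (log q − log P) = sigmoid(ρ) · (−∂ log P/∂w · ε − 1/σ) ,

because the explicit and pathwise dependencies of log q on μ cancel; the
likelihood part backpropagates through w = μ + σ·ε as usual. All gradients
(including the convolution backward passes) are verified against central
finite differences at relative tolerance 1e-4 in the test suite.

## Training and evaluation protocol

Adam, learning rate 3e-4, up to 200 epochs (defaults); minibatches of 64
trials in a seeded random order. After every epoch the mean-over-neurons
validation Pearson correlation (CC) is computed — with 10 Monte-Carlo
draws for stochastic variants — and the checkpoint at the best validation
CC is returned. Every run is a pure function of (dataset, TrainConfig):
a single seed fans out to named sub-streams (init, batches, MC, validation,
subsampling, MEI starts) via `derive_rng`, so stages are independently
reproducible and two runs with the same seed are bit-identical.

Test metrics are computed against repeat-averaged test responses: CC (per
neuron, then averaged; constant neurons are excluded with a warning), RMSE
over all cells, and a Poisson predictive log-likelihood. For stochastic
models the log-likelihood is the posterior-predictive
log mean_s P(obs | rate_s) over 100 weight samples (log-sum-exp); for
deterministic models the plug-in rate is used. This estimator is a package
convention — self-consistent across variants, summed over neurons and
averaged over trials.

Repeat reliability uses QI = Var[E[C]_r]_t / E[Var[C]_t]_r on the
(stimuli × repeats) response matrix of each neuron; identical repeats give
QI = 1, pure noise gives ≈ 1/r, and neurons are conventionally kept at
QI > 0.3. Data-fraction experiments take a seeded random subsample of
training trials (not a temporal prefix) to avoid stimulus-ordering bias.

Model comparisons use a two-sided paired sign-flip permutation test
(statistic: mean paired difference; add-one-corrected p; 10,000 flips by
default), pairing by seed for model-level and by neuron for neuron-level
comparisons.

## MEIs and their uncertainty

A most exciting input is found by projected gradient ascent on a neuron's
predicted activation: 100 steps, step size 10, starting from seeded
Gaussian noise, re-normalizing the image to the training set's per-channel
mean and std after every step, and returning the iterate (start included)
with the highest activation. Ascent operates in raw pixel space.

For stochastic encoders an MEI *stack* draws one weight sample (or dropout
mask) per optimization run, frozen for all 100 steps, seeded
`base_seed + i`. Start noise comes from an independent seed stream so that
weight uncertainty — not initialization — drives the spread; a
`share_start` switch isolates the initialization contribution. The per-pixel
variance across the stack (population convention, divide by s — fixed and
used consistently, so cross-condition trends are convention-invariant)
summarizes epistemic uncertainty; its pixel mean is the neuron's **MEI
variance**, and the mean over neurons the model's overall MEI variance.

Pixelwise significance maps test the stack mean against zero with a
one-sample two-sided sign-flip permutation test (10,000 flips, independent
per pixel, add-one correction), masked at raw p < 0.01 by default; a
Bonferroni option exists but is off, matching the convention of reporting
uncorrected maps. In-silico activation experiments feed each neuron's MEI
to all neurons and row-normalize the response matrix by its maximum. The
ensemble protocol produces 5·(100 + 1) + 1 = 506 variational MEIs (100
sampled + 1 mean-weight MEI per seed, plus the re-normalized average of the
five mean MEIs) against 5 + 1 = 6 L2+L1 MEIs.

## Calibration and sparsity diagnostics

Calibration compares nominal central credible levels q (grid 0, 0.05, …,
0.95, 1) with the empirical coverage of observed responses, pooled over all
(trial, neuron) cells; intervals are empirical [(1−q)/2, (1+q)/2] quantiles
of the Monte-Carlo predictive samples rather than Gaussian μ ± z·σ, which
avoids distributional assumptions, and nested quantiles make the curve
monotone by construction. A per-neuron aggregation is exposed as an option.
Weight sparsity is the fraction of posterior means with |μ| ≤ k·σ₂,
k ∈ {2, 3, 4}, over all weight (not bias) tensors. Partial correlation
regresses both variables on the confound (with intercept) and correlates
residuals; p-values use the t distribution with n − 3 degrees of freedom.

## Synthetic study conditions

The bundled generator produces linear–nonlinear–Poisson populations with
known ground truth: unit-norm Gabor (or difference-of-Gaussians) receptive
fields whose envelopes sit well inside the image, rate =
gain · exp(⟨filter, stimulus⟩ + bias) clipped at 50, and Poisson draws per
repeat. Default conditions: 20 neurons, single-channel 18×18
Gaussian-white stimuli standardized per channel, 2,000 training and 200
validation single trials, 50 test stimuli × 10 repeats, gain 1, bias 0.
With unit-norm filters this yields mean rates ≈ 1.7 and median repeat QI
≈ 0.7 — a reliability regime comparable to neurons passing the QI > 0.3
inclusion rule. These sizes keep a full variational fit at a few CPU
minutes while remaining structured like a real recording.

The generator emulates the *structure* of the recorded data (single-trial
training, repeated test block, Poisson-like noise, localized RFs), not its
full complexity: no calcium-indicator dynamics, no noise correlations, no
behavioral-state modulation, a true LNP generative family that the CNN can
realize exactly, and exact Poisson noise. Passing trend tests therefore
demonstrates that the machinery behaves as designed under its own
assumptions — not that the same effect sizes would appear on recorded
cortical data.

## Numerical choices

- σ = softplus(ρ) computed as max(ρ, 0) + log1p(exp(−|ρ|)); no overflow for
  large ρ, positive down to ρ ≈ −700 (double-precision underflow floor).
- Mixture prior log-density via log-sum-exp; naive summation underflows at
  σ₂ = exp(−6) for moderate |w|. Gradients use responsibilities computed
  with a logistic of the log-density gap.
- Initialization: μ ~ N(0, 0.1²), ρ = −5 (σ ≈ 0.0067) so training starts
  near-deterministic; point variants use the same weight initialization.
  Biases start at zero and are treated exactly like weights (same posterior
  family and prior) — the bias treatment is a package decision.
- Pre-activations are clamped at ±20 before the exponential output (with
  zero gradient outside), and predictions floored at 1e-8 before logs.
- Deterministic variants report predictive std 0 with a `single_sample`
  flag; QI, CC and correlation analyses flag (NaN + warning) degenerate
  constant inputs instead of erroring.
- Checkpoints are NPZ tensor archives with a JSON sidecar; round-trips are
  bit-exact.

## Problem sizes used in the shipped checks

The acceptance-style analyses (`tests/test_acceptance.py`,
`scripts/acceptance.py`) run the default synthetic conditions with
scaled-down optimization: 40 epochs for the β_v grid
{0.1, 1, 3, 10} and the 25%/100% data-fraction comparison, 80 epochs for
the filter-recovery fit, 12-sample MEI stacks at 60 ascent steps on a
7-neuron subsample for the data-fraction trend, and 999-flip permutation
tests inside the 2,000-replicate size simulation. These sizes are the
package's chosen desk-scale defaults; the qualitative results (sparsity
monotone in β_v, performance collapse at large β_v, recovery cosine > 0.5,
MEI variance shrinking with data) are stable across seeds at this scale.

## Known limitations

- Mean-field posterior only: no weight correlations, no mixture posteriors.
- The Poisson likelihood ignores over/under-dispersion of real calcium
  signals; the calibration analysis exists precisely to expose the
  resulting overconfidence.
- MEI ascent is non-convex; different starts can reach different optima for
  multimodal tuning, which the fixed-start-seed convention makes
  reproducible but does not eliminate.
- CPU-only numpy implementation: the published full-size architectures
  (e.g. 161 neurons × 52,800 features) build and run, but training them to
  convergence is slow; the package is sized for desk-scale studies.
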