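# Methods

## Setting

A binary patch classifier for metastasis detection emits a tumour-class
softmax score `s ∈ [0, 1]` per patch. Uncertainty estimation methods
produce `T` such scores per patch — by stochastic forward passes (MC
dropout), by independently trained replicas (deep ensembles), or by
predictions on randomly augmented copies (test-time augmentation) — and
the spread of those scores carries information the single score does not.
`uqpath` computes that information, fuses it back into the classification
score, and evaluates both uses: boosting predictive robustness and
detecting mispredictions.

## Samplers

All three samplers return an `N × T` matrix with entries in [0, 1].
Reproducibility is structural: every `(patch i, pass t)` pair gets its own
random stream spawned from a root seed, so appending patches or passes
never perturbs existing entries, and identical inputs give bit-identical
matrices.

* **MC dropout** requires the user's predictor to declare
  `stochastic_mode=True`; a deterministic predictor is rejected (its rows
  would be constant and every spread metric identically zero) unless
  explicitly overridden. The reference configuration this emulates is a
  network with a dropout layer (p = 0.5) before the logits kept active at
  inference, `T = 50` passes.
* **Deep ensembles** applies each of `T` deterministic members to each
  patch; the conventional size is 5.
* **TTA** draws, per pass, one augmentation from the configured family and
  predicts on the transformed patch (`T = 50`). Whether each pass should
  draw a fresh augmentation or reuse a fixed bank of `T` transforms is a
  genuinely open choice; fresh per-pass draws were chosen as the cleaner
  Monte-Carlo estimator.

### Augmentation family

Defaults follow standard histopathology training augmentation: horizontal
flip (p = 0.5), rotation by k·90°, isotropic scale in [0.8, 1.2], additive
hue/saturation shifts in [−0.1, 0.1], multiplicative brightness in
[0.65, 1.35] and contrast in [0.5, 1.5] (about the per-channel mean),
additive Gaussian noise and Gaussian blur with σ ∈ [0, 0.1]. Values are
clamped to [0, 1] after each colour-altering step.

Choices the family's usual description leaves open, fixed here:

* **Order**: geometric (flip, rotate, scale) → colour (HSV, brightness,
  contrast) → noise → blur. Fixed order makes draws replayable: the drawn
  parameter set is a first-class object and `apply_augmentation` is a pure
  function of (patch, parameters).
* **Scale boundary handling**: after rescaling, the patch is centre-cropped
  (scale > 1) or reflect-padded (scale < 1) back to the original H × W, so
  predictors always see the original shape.
* **Hue** lives on a [0, 1) wheel and shifts wrap around; saturation
  shifts clip.
* All variates are drawn in a fixed order even when a range is degenerate,
  so narrowing one range never changes the draws of the others.

## Uncertainty metrics

With row mean `s̄ = (1/T) Σ_t s_t`:

| metric | formula | range |
|---|---|---|
| sample mean uncertainty | `u_s = 1 − 2(s̄ − 0.5)²` | [0, 1] |
| sample variance | `(1/T) Σ_t (s_t − s̄)²` | [0, 0.25] |
| entropy | `H(s̄) = −[s̄ ln s̄ + (1−s̄) ln(1−s̄)]` | [0, ln 2] |
| mutual information | `H(s̄) − (1/T) Σ_t H(s_t)` | [0, ln 2] |
| baseline | `u_base = 1 − 2(s − 0.5)²` on a single score | [0, 1] |

Conventions: natural logarithms throughout (all downstream evaluation is
rank-based, so the base is immaterial); `0·log 0 ≡ 0`, implemented by
clamping probabilities to `[1e-12, 1 − 1e-12]` inside logs and zeroing the
entropy of degenerate inputs; population variance (divide by `T` — the
`T/(T−1)` factor cannot change any ranking); MI values within `1e-9` below
zero (Jensen guarantees non-negativity exactly) are set to 0, anything
further below raises. The two-class predictive-entropy double sum over
classes and passes reduces algebraically to `H(s̄)`; the closed form is
what is computed, and the test suite holds it against a literal
term-by-term evaluation of the double sum.

Note a deliberate literalism: `u_s` is 0.5, not 0, at `s̄ ∈ {0, 1}`. The
transform is implemented exactly as defined (no renormalisation to
[0, 1]); since every use is either rank-based or normalised by `P_u`, the
floor is harmless for detection but matters for fusion — see below.

## Score fusion

`f(u, s) = ((u/P_u)^y + s^y)^(1/y)` with the shape exponent fixed at
`y = 10` and `P_u` the 99th percentile (linear interpolation) of the
uncertainty values of the dataset being scored. Fitting `P_u` on the
evaluation set is the default and is recorded in the returned config, which
can be frozen and reused to score other datasets. A prediction is positive
iff `f(u, s) > t`, strictly; `f(0, s) = s` exactly, so zero-uncertainty
inputs reduce to plain softmax thresholding. The implementation factors
out the larger argument before exponentiating, which is exact on the axes
and stable at large `y`. An all-zero uncertainty vector makes `P_u = 0`
and is rejected with the advice to use softmax-only scoring.

Which metric feeds `f` is the caller's choice. The library default is
`sample_mean_uncertainty`; the reference pipeline uses **entropy**. The
reason is the `u_s` floor: `u_s ≥ 0.5` everywhere, so `u_s/P_u ≳ 0.5` and
every input — including confidently healthy ones — receives a fused score
around 0.5 or higher, which destroys the low-threshold half of the
accuracy curve. Entropy vanishes for confident predictions and preserves
it. This is a known limitation of fusing with `u_s`, not of `u_s` as a
detection metric (where only ranks matter).

## Evaluation protocol

* Positivity is `score > threshold` (strict) everywhere; boundary scores
  are negative.
* ROC curves enumerate all distinct score thresholds; the AUC is the
  trapezoidal area, which equals the Mann–Whitney statistic with midrank
  (half-credit) tie handling. PR curves use the step-wise
  average-precision summary. Both are delegated to scikit-learn behind
  this module's interface and cross-checked in the tests against
  brute-force pairwise and precision-at-rank oracles.
* Accuracy sweeps use 201 evenly spaced thresholds in [0, 1] by default
  (the fused score is swept on a grid of the same spacing extended to its
  maximum, so plateau widths are comparable). The **plateau width** is the
  threshold span of the contiguous run of grid points containing the peak
  whose accuracy stays within one percentage point of the peak, plus one
  grid spacing (a single-point plateau has width one spacing). It is this
  package's operationalisation of "how forgiving is the operating-point
  choice".
* **Misprediction detection**: at a fixed classification threshold, inputs
  the single-model prediction got wrong form the positive class, and the
  uncertainty score is scored by ROC-AUC against that labelling (higher
  uncertainty should rank errors first, so informative uncertainty gives
  AUC > 0.5). A perfect classifier leaves nothing to detect and raises.
* Undefined quantities — precision with no positive predictions, recall
  with no positives, any AUC with one class — raise a dedicated error and
  are never silently reported as 0.

## Synthetic generator

`generate_samples` draws, per input, a latent "true score" and then `T`
observed scores around it:

1. **Latent logits.** `z ~ Normal(m_c, σ_c)` with `m_healthy = −0.6·sep`,
   `m_tumour = +0.4·sep`, `σ_healthy = 1.0`, `σ_tumour = 2.8`, and
   `sep = 8` by default; the latent score is `μ = sigmoid(z)`. The
   asymmetry encodes how a well-trained metastasis detector behaves:
   healthy tissue is the easy, tightly clustered class, while tumour
   patches range from obvious to barely-tumour (small tumour fraction),
   giving the characteristic slow decay of accuracy as the threshold
   rises. The defaults yield a single-model ROC-AUC ≈ 0.99.
2. **Domain shift.** `centre` subtracts `severity · m_c` from every input
   (both classes drift toward the boundary, spreads unchanged);
   `subtype` subtracts `severity · sep` from tumour inputs only, emulating
   a subtype whose tumour signal is weaker (at severity 1 the tumour mean
   coincides with the healthy mean). Additive mean shifts were chosen
   deliberately: compressing logits multiplicatively also shrinks the
   tumour spread and *raises* AUC, which is the opposite of what a hard
   subtype does.
3. **Samples.** `s_t ~ Beta(μκ, (1−μ)κ)` with concentration
   `κ = dispersion / b(μ)`, where
   `b(μ) = 1 + (boost − 1)·exp(−((μ−0.5)/0.15)²)`. Beta keeps the support
   in [0, 1] with mean `μ`; the boost (default 6, on a base dispersion of
   60) widens the spread exactly where the classifier is near-undecided,
   mirroring how sampling-based disagreement concentrates on boundary
   cases. Infinite dispersion collapses rows to a point mass. Column 0 of
   the matrix serves as "the single model" wherever one is needed.

The default spec (2000 per class, `T = 50`, seed-controlled) is the
**reference scenario**. On it, the three qualitative findings the
evaluation protocol is designed to surface all hold: entropy-fused scoring
widens the accuracy plateau ≈ 2.7× over softmax-only; misprediction AUC
rises (≈ 0.72 → 0.90 → 0.98) while accuracy falls (≈ 0.98 → 0.94 → 0.81)
as the classification threshold moves through 0.1/0.5/0.9; and
subtype-shifted data is harder both to classify (ROC-AUC ≈ 0.90 vs 0.99)
and to detect mispredictions on (AUC at t = 0.5 ≈ 0.73 vs 0.90).

What the generator does **not** emulate: image content (scores are drawn,
not predicted), correlations between inputs from the same slide, label
noise, class imbalance (datasets are balanced; the evaluation module takes
whatever labels it is given), and any specific absolute AUC of a real
scanner/centre pairing. Tests passing on this scenario show the machinery
is correct and that the qualitative phenomena are reproducible under the
stated generative assumptions — not that any particular clinical dataset
will show them at the same magnitudes.

`generate_patches` + `analytic_predictor` provide a genuinely image-based
path for exercising the samplers: toy tiles with hematoxylin-dark disks on
an eosin-pink background (dense for tumour, sparse for healthy), and a
closed-form predictor mapping dark-pixel fraction through a logistic. A
sharpness family stands in for an ensemble; a logit-space noise wrapper
stands in for a dropout-enabled network.

## Problem sizes

The shipped tests and the acceptance script run the reference scenario at
2000 inputs per class with `T = 50` (400 000 Beta draws per dataset),
which keeps the full suite under ~10 s while leaving Monte-Carlo error on
every asserted ordering far below the effect sizes involved. Formula-
fidelity checks use 1000 random rows; ROC oracle checks use 200 problems
of ≤ 50 inputs (pairwise enumeration is quadratic); independence checks
use 10 000 inputs.

## Known limitations

* Two classes only; the multi-class entropy/MI forms are out of scope.
* `P_u` fitted on the scored dataset leaks a little information across the
  train/evaluation boundary; freeze the config for strict separation.
* The `u_s` floor makes it a poor fusion metric (see above) even though it
  is a strong, shift-robust detection metric.
* The plateau-width statistic depends on the grid spacing at its
  resolution limit; compare widths only across sweeps with equal spacing.
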