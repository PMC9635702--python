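# Methods

## Problem and model

`otoage` estimates fish age from otolith images by regression. The response
for fish *i* is the expert-read age *y*<sub>i</sub> (years); predictors are the
otolith image *X*<sub>i</sub> and the recorded sex *z*<sub>i</sub> ∈ {male,
female, unknown}:

    y_i = f(X_i, z_i; θ) + ε_i .

*f* is a convolutional network: a pluggable backbone, global average pooling
(GAP), dropout, and a dense layer with **three** ReLU-activated output nodes —
one conditional age estimate per sex group. The final prediction is the dot
product of the three outputs with the one-hot sex code ([1,0,0] male,
[0,1,0] female, [0,0,1] unknown). The ReLU output activation guarantees a
non-negative age; we define ReLU(0) = 0 at the (measure-zero) kink. One
shared feature extractor serves all sexes, so each head benefits from the
whole dataset while still absorbing group-level differences in the age
distribution — the female head can sit several years above the male head even
when the image itself carries no sex cue.

Training minimizes the mean squared error of the sex-selected output plus an
L2 penalty on all trainable weights (biases and normalization offsets
exempt, as is conventional). The MSE is averaged rather than summed over the
batch; the minimizer is identical and the magnitude is batch-size invariant.
Optimization is Adam; data augmentation (train-time only) applies random
horizontal translation up to 10 % of the width and rotation up to a factor
0.1 of a full turn (36° either way). There is no vertical translation
because images are standardized on height. Early stopping monitors
validation MSE with patience 20 within a 100-epoch cap and restores the
weights of the best epoch.

### Backbones and hyperparameters

Two backbones are registered. `tiny` — three stride-2 conv/batch-norm/ReLU
blocks (8, 16, 32 channels) — is the desk-scale workhorse for 32–128 px
inputs and everything in the test-suite. `paper-scale` — five stride-2
blocks for 256 px inputs — exercises the same interface at the geometry used
with real images; fine-tuning a large pretrained feature extractor is out of
scope here, and the backbone registry is the hook where one would plug it in.

Defaults for the `tiny` configuration: learning rate 3e-3, batch 32, dropout
0.4 between GAP and the output layer, L2 weight 1e-2. The relatively strong
regularization (the paper-scale setting would be L2 1e-5 with learning rate
1e-4 under a pretrained backbone) keeps a from-scratch float32 network
well-conditioned: it shrinks the total variation of the network's
directional derivatives, which both regularizes the fit and keeps
gradient-based attributions numerically clean (see "Attribution" below). Output biases are initialized
at the per-group mean ages of the training set, which makes the untrained
model exactly the group-mean predictor and accelerates convergence.
Batch-normalization running statistics can be frozen (`freeze_normalization_
stats`), the right choice when adapting a pretrained backbone or when a
strictly affine normalization is wanted; the from-scratch tiny model trains
with live batch statistics by default.

Hyperparameter search (`random_search`) draws the dropout rate from the grid
{0, 0.1, …, 0.5} and the learning rate log-uniformly over 1e-6…1e-1, and
returns the trial with the lowest validation MSE.

## Cross-validation

The evaluation scheme is an early-stopping variant of exhaustive k*l-fold
cross-validation. Known-sex samples are dealt into *k* folds by
proportionate stratified allocation on read age: within each age stratum the
samples are shuffled and dealt round-robin, with the dealing pointer carried
across strata so fold sizes differ by at most one (3,540 samples and k = 10
give exactly 354 per fold). Trial *i* tests on fold *i*, early-stops on fold
*i*+1, and trains on the remaining k−2 folds. The validation index wraps
cyclically (trial *k* validates on fold 1), keeping all trials structurally
identical. Unknown-sex samples join every training set and are never
validated or tested. Each trial trains a fresh model; every known-sex sample
is tested exactly once per plan.

## Metrics

* **RMSE** in years, on the natural scale of the response.
* **Ageing-precision CV** per fish, the standard two-reading coefficient of
  variation applied to the pair (read age, predicted age): with
  ȳ = (y + ŷ)/2, CV = √((ŷ−ȳ)² + (y−ȳ)²) / ȳ, which equals
  |ŷ−y| / (√2·ȳ). The mean CV averages this over fish and is reported as a
  percentage. (A typesetting note: the radical is part of the definition —
  dropping it would square the units and collapse the statistic to first
  order; the square-root form is what reproduces the ~10 % precision levels
  reported for this kind of data.)
* **0-off / 1-off percentages**: share of fish whose prediction, rounded
  half-away-from-zero, equals / is within one year of the read age.
* **Distribution agreement**: KL divergence D(P‖Q) between the KDE of read
  ages (P) and of predicted ages (Q), per sex. Densities use a Gaussian
  kernel with Silverman's rule-of-thumb bandwidth
  0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated on a 512-point grid spanning the
  samples ±3 bandwidths; the integral is trapezoidal, with Q floored at
  1e-12 before logs. These choices are defaults, overridable per call.
* **Residual SD by age**: empirical SD (ddof = 1) of residuals grouped by
  read age; ages with fewer than two residuals are omitted and logged.

## Length baseline and fusion

A linear regression E(Y) = β₀ + β₁·x + β₂·x·1[male] maps length *x* (cm) to
age, with a common intercept for the two sexes because male and female fish
share the same expected length at birth. It is fitted by least squares on
rows with known sex and length. Image and length estimates are fused as
ŷ = α·ŷ_image + (1−α)·ŷ_length, with α obtained by regressing
(y − ŷ_length) on (ŷ_image − ŷ_length) without intercept — the constrained
sum-to-one parameterization; Least-squares optimality makes the fused RMSE
no worse than either input on the fitting sample. α is clipped to [0, 1]
(clips are logged) and, following the study protocol, is fitted on pooled
test-fold predictions; honest nested fitting is a caller-side choice since
`fit_alpha` accepts any prediction vectors.

## Attribution

Five gradient methods attribute the sex-selected output to input pixels:
gradient saliency, baseline gradients, integrated gradients (IG), guided
backpropagation, and integrated guided gradients. Path methods integrate
along the straight line from a non-informative baseline (all-black by
default) to the input using the midpoint Riemann rule with 64 steps by
default. Heatmaps take the absolute value, reduce channels by max, and
normalize to [0, 1]; path methods also retain raw signed attributions so the
IG completeness identity Σ attributions = f(x) − f(baseline) can be checked.

Because the network is piecewise linear along the path, the completeness
error of an m-step Riemann sum is governed by the total variation of the
directional derivative divided by m. Two design choices keep it small.
First, the strong default regularization (dropout 0.4, L2 1e-2) flattens
the derivative's variation; weakly regularized models are several times
rougher. Second, the integrator is clamp-aware: with a ReLU output and a
black baseline, a model trained with the baseline class is identically zero
on an initial stretch of the path, where the gradient vanishes and nothing
accrues to the integral. The integrator locates that stretch with
forward-only probes and spends the whole step budget on the active segment
— an exact reformulation, not an approximation. With both in place the
per-image relative completeness error at 128 steps is typically a few
tenths of a percent, with occasional images (and hence some panels)
around 1–1.5 % depending on the local kink structure of the trained
network.

A naively trained regressor maps an all-black image near the mean response,
which poisons baseline-referenced attributions. The training device
`add_baseline_class` appends 50 all-black images labelled age 0 (sexes drawn
uniformly so all three heads see them) to the training set only; after
training, the model's output at the baseline is pushed toward zero.
Baseline rows never enter validation or test folds, and age 0 is permitted
only for them.

## Synthetic populations

The generator emulates the study system so every stage runs without the real
archive:

* **Composition**: sexes drawn with probabilities 0.345 / 0.489 / 0.166
  (male / female / unknown); ages per group from truncated normals with
  means 10 / 12 / 11 yr and SDs 3.3 / 4.4 / 5.4 yr on [1, 26], rounded to
  integers. Lengths follow length = 8 + slope·age + N(0, 7 cm), slope
  4.5 cm/yr for females and 3.5 cm/yr for males (shared intercept; the
  growth coefficients and the Gaussian noise structure are package choices,
  exposed in `LengthParams`). The 7 cm scatter makes length a usable but
  clearly weaker age signal than the images — the ordering characteristic
  of the emulated system, where image-based estimates beat length
  regression and the fusion weight favours the images. Unknown-sex fish carry no length by default,
  mirroring data where length accompanies exactly the sexed fish.
* **Morphology**: a bright convex blob (polar radius profile of an ellipse
  plus low-order irregularity) whose aspect ratio widens with age; marginal
  "fingers" on the upper margin appearing from age 5, growing in number
  (capped at 6 so protrusions stay resolvable) and length (capped at 12 px);
  and a dark core whose relative vertical position drifts downward with age.
  Rendering is standardized so the foreground's vertical extent is a fixed
  fraction of the canvas — absolute size is deliberately not an age cue,
  as with the height-standardized real images.
* **Reproducibility**: each record derives its own counter-based substream
  of the master seed, so record *i* is bit-identical regardless of how many
  records are drawn.
* **No sex cue in images**: morphology depends on age only. The group
  differences live entirely in the age distributions, which is precisely the
  setting needed to show that the sex-conditional head exploits the sex code
  as prior information. (For the same reason no latent-sex device is needed
  when rendering unknown-sex fish.)

What the generator does **not** emulate: annual growth zones (not reliably
visible in low-resolution real images and not required by the age cues
tested here), photographic artefacts, lighting variation, occlusions, or
reader disagreement — the read age is the generative age, so "read-age
uncertainty" is absent. Passing tests on synthetic data therefore
demonstrate that the pipeline's machinery (conditioning, cross-validation,
metrics, attribution) is correct and that the model can recover a strong
morphological age signal; they do not certify performance on real otoliths.

## Desk-scale study sizes

The standard recovery study (`otoage.studies.run_recovery_study`) uses 600
images at 64 × 64 px, ages 1–16, male/female mean ages 6 / 10 yr (SD 2.5),
a k = 5 stratified split (fold 1 test, fold 2 validation, the rest plus
unknowns and 50 black baseline images for training), and the tiny backbone.
Distributional checks (sex proportions, truncated-normal moments) use 10,000
metadata-only draws; the KDE/KL oracle checks use 2·10⁴–10⁵ normal samples.
These sizes keep the full suite comfortably on a single CPU while leaving
clear margins on every statistical assertion.

## Numerical and degenerate-input conventions

* Height standardization segments the otolith by Otsu's threshold on the
  green channel; constant or empty images are rejected.
* Augmentation fills exposed pixels by nearest-edge values; bilinear
  interpolation keeps intensities inside the input range.
* Sex strings are normalized case-insensitively with whitespace trimmed;
  anything outside {male, female, unknown} is an error.
* Grayscale inputs are replicated to three channels.
* `cv_single` is undefined at ȳ = 0 and rejects it; `fit_alpha` rejects
  identical input estimates (α would be unidentifiable).
* Rounding for off-percentages is half-away-from-zero.
* KDE requires n ≥ 2; a zero-spread sample falls back to a small positive
  bandwidth.
* Forward passes at inference use running normalization statistics and no
  dropout, so predictions are bit-reproducible for fixed weights.

## Known limitations

* The numpy network is single-threaded and float32; it is sized for
  desk-scale studies, not for 4,000-image archives at 256 px.
* The synthetic morphology is a three-cue caricature (width, fingers, core
  position); heatmaps on it should be read as smoke tests, not as evidence
  about which features matter in real otoliths.
* IG completeness at the default 64 steps is approximate (percent-level);
  raise `steps` when the check matters.
* α fitted on pooled test predictions (the study protocol) is mildly
  optimistic relative to nested fitting.
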