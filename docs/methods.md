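# Methods

`sersdx` implements an end-to-end analysis chain for label-free SERS
spectra of serum exosomes: cohort simulation, Raman preprocessing, a
hybrid CNN + MLP spectral classifier evaluated under grouped
cross-validation, per-sample probability aggregation, and an
interpretability layer. This note records the models, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Synthetic cohorts

Real serum-exosome SERS archives are not publicly deposited, so the
package ships a generator whose statistical structure mirrors what the
analysis assumes. A spectrum is

    I(v) = j * sum_b A_b f_b(v) + baseline(v) + eps(v) + spikes(v),  clipped at 0

on a shared wavenumber axis (default 400–1800 cm⁻¹ at 1 cm⁻¹ → 1401
channels; instruments vary and no canonical range exists for this assay,
so the axis is simply chosen to cover every band the analysis uses).

* **Bands** `f_b`: Gaussian by default (Lorentzian available), specified
  by center, FWHM and amplitude in arbitrary units. All classes share a
  base set of ten bands with centers at common serum Raman positions;
  the global maximum sits at 1004 cm⁻¹ (phenylalanine) so per-spectrum
  min–max scaling is not pinned to a marker band.
* **Disease signal**: every cancer class adds a signed amplitude offset
  to two marker bands — positive at 1080 cm⁻¹ (dATP, elevated in cancer
  exosomes) and negative at 1380 cm⁻¹ (phosphatidylserine, reduced).
  Defaults are +0.15 / −0.10 on a maximum band amplitude of 1.0. These
  are synthetic desk-scale effect sizes, not estimates of the real
  assay. The 643 cm⁻¹ band amplitude is identical across classes by
  construction (and enforced by validation), because it serves as the
  internal-reference denominator downstream.
* **Cancer types**: the eleven-class vocabulary (breast, thyroid,
  esophageal, kidney, pancreatic, duodenal, lung, colorectal, ovarian,
  gastric, non_cancer) distinguishes types by two extra minor bands per
  type (amplitude 0.30) at centers chosen away from the shared bands.
* **Artifacts**: additive Gaussian noise (SD 0.03); a random cubic
  baseline in normalized wavenumber with coefficient ranges
  (0.2–0.8, ±0.3, ±0.3, ±0.2); per-spectrum lognormal amplitude jitter
  (CV 10%), modelling exosome-sampling heterogeneity — the reason
  hundreds of spectra are acquired per sample; and Poisson-count
  one-channel cosmic-ray spikes (default rate 0.05/spectrum, amplitudes
  1–5, constrained to exceed 10× the noise SD so ground-truth spikes
  are unambiguous in oracle tests).
* **Staging**: cancer samples cycle deterministically through TNM-like
  stage labels (T1N0M0, T2N0M0, T3N1M0, T4N2M1) so the early-stage
  filtering task is exercisable; the stage does not modulate the
  spectral effect. This is a deliberate simplification — real
  early-stage biology is presumably subtler.
* Every quantity flows from one integer seed through NumPy's
  `SeedSequence`; ground truth (spike channels, jitter, planted offsets)
  travels with the dataset for testing.

What the generator does **not** emulate: plasmonic enhancement physics,
hot-spot geometry, wavenumber miscalibration, detector nonlinearity,
batch effects between acquisition sessions, or biological covariance
between bands. Passing tests on these cohorts therefore demonstrates
that the pipeline recovers the structure it assumes — not that the
real assay attains any particular accuracy.

## Preprocessing

Four composable steps, default order despike → baseline → smooth →
normalize. The despiker runs first because a cosmic ray distorts an
asymmetric-least-squares fit; the order is configurable.

* **Cosmic-ray removal**: candidate channels are flagged by the modified
  z-score of the second difference (threshold 8); a candidate is
  confirmed only when its residual above a rolling median (window 11)
  clears the same threshold on a MAD scale. The confirmation step
  excludes the two flanking channels that the second difference of a
  one-channel spike also excites — without it, single-channel precision
  could not exceed ~1/3. Flagged channels are replaced by linear
  interpolation from the nearest clean neighbours. Robust scales are
  floored at 10⁻³ of the maximum deviation so noise-free input cannot
  produce a zero MAD.
* **Baseline**: asymmetric least squares (Eilers), λ = 1e5, p = 0.01,
  10 iterations, solved per spectrum with a banded Cholesky
  factorization (O(n) per iteration). Exact for constant and linear
  backgrounds; bias under an isolated unit peak is below 2% of the peak
  amplitude at these settings. Negative post-baseline values are
  retained — clipping would bias the ratio statistics.
* **Smoothing**: Gaussian kernel, σ = 2 channels, truncated at 4σ and
  renormalized to unit sum, reflect boundary. σ = 2 preserves the
  ~10 cm⁻¹ FWHM bands while suppressing channel noise.
* **Normalization**: per-spectrum min–max to [0, 1] (each spectrum is
  scaled individually, matching how the classifier consumes spectra).
  A constant spectrum maps to zeros with a warning.

## Classifier

A 1-D CNN classifies individual spectra: valid convolution with 64
filters of kernel 3 (stride 1) → ReLU → dropout (rate 0.25) →
max-pooling (size 2, stride 2) → flatten → one fully connected hidden
layer of 64 with ReLU → softmax output. On the default 1401-channel
axis the shapes are 1399 → 699 → 44 736 flattened features. The stack
is implemented in NumPy (float32, seeded), with gradients propagated to
the input for saliency analysis.

On the default 1401-channel axis the flattened dense layer holds ~2.9M
parameters — orders of magnitude more than a desk-scale cohort has
spectra — and two safeguards proved necessary for stable optimization:
the dense hidden activation is a leaky ReLU (α = 0.01), because a hard
ReLU after that layer can switch off for every input simultaneously and
never recover; and gradients are clipped to a global norm of 1.0, which
prevents the first few Adam steps from slamming the hidden layer into
that dead region.

Training: Adam (lr 1e-3), cross-entropy (optionally inverse-frequency
class-weighted for imbalanced cohorts), batch size 64, up to 50 epochs,
reduce-on-plateau scheduler (patience 5, factor 0.5). A grouped monitor
split (15% of training samples, stratified; never the validation fold)
drives the scheduler and early stopping: training stops once monitor
accuracy has not reached a new best for 4 epochs (after a minimum of
5). Two guards matter on small cohorts: the scheduler and the stopper
are inert until monitor accuracy clears the majority-class baseline by
more than its own sampling noise — otherwise the scheduler decays the
learning rate during warmup and the model locks at chance — and
stopping is driven by accuracy rather than loss, because on easily
separable cohorts the loss keeps creeping toward zero long after the
decision function has converged. The weights returned are those of the
best monitored epoch (highest accuracy, ties broken by loss), not the
last one — with only a handful of batches per epoch the late epochs
oscillate, and returning the final state measurably hurt held-out
accuracy.

**Stacked refinement.** The CNN's class probabilities feed an MLP
(n_classes → 64 → 64 → n_classes, ReLU hidden, softmax) trained by
stacked generalization: under k-fold cross-validation each spectrum
receives an out-of-fold CNN probability, and the refiner applied to
fold f trains only on out-of-fold probabilities of spectra outside f.
A guard raises if any training example was produced by the held-out
fold's CNN. The refiner is initialized as a sharpened identity map on
the probability simplex (the first n_classes hidden units copy the
input; the output layer scales it by 8), so before training it
reproduces the CNN's decisions and gradient descent departs from that
map only where the stacking loss improves; 20% of the stacking examples
are held out to stop refinement early. This makes "no change" the
refiner's floor — without it, an MLP trained from random initialization
measurably degraded an already-calibrated boundary on confusable-class
cohorts.

**Cross-validation** is stratified at the sample level: every spectrum
of a serum sample shares its fold, because spectrum-level splits would
leak sample identity into training and inflate accuracy. Fold
assignment, batch order, dropout and initialization all derive from the
configuration seed; identical seeds give byte-identical metrics on one
machine.

## Diagnosis and evaluation

A sample's diagnosis is the unweighted mean of its spectra's refined
probability vectors. Calls are argmax (lowest class index on ties), or
for the binary task a threshold (default 0.5) on the mean cancer
probability. Evaluation reports the integer confusion matrix, accuracy,
one-vs-rest sensitivity and specificity per class, ROC curves by
threshold sweep on the mean probabilities, and trapezoidal AUC (macro
average across classes for multiclass). Probability heatmaps (spectrum
× class, grouped by sample) can subsample a fixed number of spectra per
sample to mirror published figure layouts.

## Interpretability

* **Feature importance**: the default is gradient × input saliency —
  per spectrum, the gradient of the winning-vs-rest logit contrast with
  respect to the input, multiplied by the input (a first-order Taylor
  attribution); attributions are averaged over spectra **with their
  sign**, so channels the model uses consistently reinforce while
  incoherent noise cancels, and the magnitude is normalized to percent
  of total. Plain mean-|gradient| saliency proved markedly noisier at
  desk scale.
  A data-free alternative ("weight") chains absolute weights from the
  output layer back through the dense stack, pooling and convolution
  kernel onto input channels. Saliency is the default because it is
  model-faithful and architecture-agnostic; the weight projection is
  retained as the literal weight-distribution reading. Band scores sum
  channel percents within ±10 cm⁻¹ of a named center; top-band ranking
  greedily selects non-overlapping windows.
* **Differential spectra**: channelwise mean(class) − mean(control) on
  preprocessed spectra; antisymmetric under group swap by construction.
* **Peak ratios**: per spectrum, intensity at the channel nearest
  1080 (or 1380) cm⁻¹ divided by the 643 cm⁻¹ internal-reference
  channel. Ratios are computed on despiked, baseline-corrected,
  smoothed but **un-normalized** intensities — min–max scaling would
  distort a ratio of two channels — and the ratio itself cancels
  per-spectrum scale (jitter). Spectra with non-positive reference
  intensity are excluded with a log line; more than 5% of them
  invalidates the reference band and raises. Groups are compared with
  Welch's unequal-variance t-test, annotated with the conventional
  star codes (0.05/0.01/0.001/0.0001). Band-to-molecule attribution
  (dATP, phosphatidylserine) is cited context, not something the
  package computes.

## Problem sizes and numerical choices

Shipped analyses run on one CPU at desk scale: the presence task uses
2 × 40 samples × 50 spectra, the typing task 11 × 15 × 30 (test suite)
or 11 × 8 × 20 (acceptance script), the early-stage task a 30-sample
binary cohort filtered to early stages; despiking calibration uses
≥1000 planted spikes; ratio statistics use 25 spectra per group;
type-I calibration uses 100 seeded null replicates. The NumPy network
trains at roughly 6 s per epoch on the 4000-spectrum presence cohort.

Degenerate inputs have defined behaviour: constant spectra normalize to
zeros (warning); an all-flagged despike, a single-class training split,
a class with fewer samples than folds, unknown labels, duplicate
spectrum IDs and non-finite intensities raise informative errors.
Argmax ties break to the lowest class index. Probability vectors are
validated to sum to 1 within 1e-6.

## Known limitations

* Synthetic effect sizes are favourable; headline accuracies near 1.0
  on these cohorts say nothing quantitative about real serum.
* The refiner's value is bounded on cohorts whose CNN probabilities are
  already well calibrated; its contract here is "never worse, sometimes
  better" at the spectrum-argmax level. Because the softmax head acts as
  a monotone sharpener of probabilities, sample-level *mean*
  probabilities can shift near the binary 0.5 threshold on very small
  cohorts even when every spectrum-level decision is preserved.
* The weight-projection importance ignores activations and is
  flat-biased for the convolution layer; use saliency unless the
  literal weight reading is wanted.
* ALS baseline bias grows for bands much wider than ~30 cm⁻¹; λ would
  need retuning for instruments with very different resolution.
* Per-spectrum determinism holds within one BLAS build; bit-identical
  reproduction across different BLAS libraries is not guaranteed.
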