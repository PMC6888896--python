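# Methods

## Data model and preparation

A 24-2 visual field is represented by its 52 informative total-deviation
(TD) values in dB (negative = loss), stored in the reading order of the
right-eye chart. The 24-2 lattice (rows of 4/6/8/9/9/8/6/4 points on a
6° grid, nasal extension to 27°, minus the two blind-spot points at
(+15°, ±3°)) is embedded in a 12×12 frame at rows 2–9 / columns 1–10, so a
left-eye field mirrors into right-eye order by the column map c → 11 − c.
All fields are converted to right-eye orientation before modelling.

Reliability filtering keeps a test unless fixation losses exceed 33% or
false-positive errors exceed 15% (strict inequalities). When a baseline
visit is removed, the series is re-anchored so time zero is the first kept
visit.

For the image model, TD is mapped affinely from **[−38, +6] dB to [0, 1]**
with clipping, and pad cells are exactly 0. The range is fixed rather than
data-driven so the mapping is identical across folds and invertible without
per-fold state; −38 dB is beyond any recordable SAP loss and +6 dB covers
supra-normal sensitivity. Note one consequence of padding *in normalized
space*: a pad value of 0 coincides numerically with td_min. The
reconstruction loss is computed over all 144 pixels, so the network also
learns the constant pads; a masked-loss variant was considered and rejected
to keep the loss the plain pixel MSE.

MD is computed as the unweighted mean of the 52 TD values and PSD as their
sample standard deviation. These are surrogates: device-reported MD/PSD use
eccentricity weights and normative variances that are not reproduced here.
Their role — a one-number global summary and a localization index — is
preserved.

Dataset splits assign each *patient* independently to train/validation/test
with probabilities 0.8/0.1/0.1 (so realized fractions fluctuate), and
k-fold cross-validation shuffles patients once and rotates k groups so each
patient is a test patient exactly once.

## The autoencoder

Architecture (all kernels 3×3):

    encoder: conv s2 (1→32) → ReLU → conv s2 (32→64) → ReLU
             → flatten (3·3·64) → dense → z ∈ R^L            (identity)
    decoder: dense (L→3·3·64) → ReLU → reshape
             → deconv s2 (64→32) → ReLU → deconv s2 (32→32) → ReLU
             → conv s1 (32→1) → sigmoid

Spatial sizes follow 12 → 6 → 3 → L → 3 → 6 → 12. Stride-2 "same"
convolutions use the TensorFlow padding convention (one extra row/column at
bottom/right), and each transposed convolution is the exact adjoint of the
corresponding stride-2 map, which makes the 3 → 6 → 12 doubling exact. The
output head is a stride-1 sigmoid convolution so reconstructions live
strictly in (0, 1). Channel counts (32, 64) are conventional small-image
defaults and configurable.

The encoder is deterministic — there is no per-point reparameterized
sampling. Regularization acts on the *aggregate* latent distribution: the
loss on a batch B is

    L(B) = MSE(B, decode(encode(B)))  +  λ · MMD²(encode(B), S),

where S is a fresh standard-normal sample of batch size, and MMD² is the
biased (V-statistic) squared maximum mean discrepancy under a Gaussian
kernel k(a,b) = exp(−‖a−b‖²/2σ²). Defaults: **λ = 1000** and **σ² = L**.
λ is large because squared-MMD magnitudes are tiny relative to pixel MSE;
with these defaults, training at realistic scale (≈10⁴ images, ≥ 2,000 Adam
steps) drives reconstruction MSE below 0.005 while the latent per-dimension
SD approaches 1, i.e. the prior is effectively enforced. At very small
scale (a few hundred gradient steps) the latent spread lags behind — the
MMD repulsion force vanishes near the origin — so demonstration runs should
use on the order of a thousand patients, not dozens.

Training uses Adam (lr 1e−4 by default, β = 0.9/0.999), batch size 100,
100 epochs by default; per-epoch training loss is the running mean over the
epoch's batches and validation loss is a full pass; the parameters from the
epoch with minimal validation total loss are restored. Runs are exactly
reproducible from the config seed; divergence (non-finite loss) aborts with
a diagnostic. A latent-dimension sweep trains one model per L ∈ 1..15 with
a shared seed. The whole network and its backpropagation are implemented in
numpy (float64, NHWC, nine BLAS products per convolution); gradient
correctness is verified against central finite differences in the test
suite.

## Progression statistics

Encoded trajectories are analysed by one stacked regression per patient
with feature-specific intercepts, a shared global slope, and sum-to-zero
interaction deviations (see README for the formula). The global slope β is
then literally the mean rate of change across features; its two-sided
t-test uses the residual variance pooled across features (homoscedasticity
across latent dimensions is assumed — reasonable once the MMD prior
homogenizes feature scales). The non-linear variant adds (γ + η_l)·t² with
the same coding and tests H0: β = γ = 0 by the nested-RSS F statistic with
(2, nL − 3L) degrees of freedom. Under a shared time grid the zero-sum fit
is a reparametrization of L separate per-feature fits, so β̂ equals the mean
of per-feature OLS slopes exactly — an identity the tests verify to 1e−9,
alongside agreement with a statsmodels fit of the same design matrix.

Degenerate inputs: fewer than 3 visits (4 for the quadratic model), rank
deficiency, or an (essentially) zero-residual perfect fit produce a
"no-test" result — rate reported, p undefined, not flagged, with a warning
— rather than a spuriously infinite t statistic. The degeneracy threshold
is relative (RSS ≤ 1e−12 · ‖y‖²).

The MD comparator regresses MD on time and flags when the slope is
significantly *negative*: one-sided p < 0.05, which both respects the
"significantly negative" definition and keeps the 95% specificity match
with the two-sided latent tests (whose nominal level is also 0.05).

Hit rate at a follow-up cutoff truncates each series to visits at or before
the cutoff, requires the method's minimum visit count (patients below it
are excluded from the denominator and counted), runs the test, and reports
the flagged fraction among glaucoma patients. Percentile bootstrap CIs
resample patients. Type-I calibration of all three tests is verified by
simulation (flag rate 0.05 ± 3 binomial SE on ≥ 2,000 stable series;
p-values pass a KS uniformity check under the null).

## Prediction

For a scenario (k, h): fit each latent dimension of the first k encoded
visits by OLS on time (plus time² for the quadratic trend), evaluate at the
*observed* time of visit k + h, decode, and denormalize. Predictions are
therefore bounded in [−38, +6] dB and spatially smooth. The pointwise
baseline fits the same polynomial independently at each of the 52 locations
and extrapolates **without clamping** (a `clamp` option exists); its
unboundedness is deliberate — it is the standard method's actual failure
mode at short series and long horizons. MAE is computed over exactly the 52
informative locations, never pad cells. Paired per-patient MAEs are
compared by a one-sided Wilcoxon signed-rank test (scipy: exact null for
small tie-free samples, normal approximation with continuity correction
otherwise; zero differences dropped; all-tied input returns p = 1 with a
warning), with significance declared at 0.05/900 ≈ 6e−05. The 900-test
divisor is taken as the comparison grid's printed size, not re-derived.

## The synthetic cohort

The simulator targets the published demographic profile of a tertiary-care
perimetry cohort: status mixture (0.17, 0.58, 0.25), mean 7.61 visits
(SD 7.35, shifted negative binomial with a minimum of 2), expected
follow-up 4.95 years (inter-visit gaps uniform within ±50% of their mean),
pooled baseline MD −3.55 dB. Status-specific baseline-MD components
(normal −0.5 ± 1.0, suspect −1.5 ± 2.5, glaucoma −10.38 ± 6.0, truncated to
[−30, 2]) were calibrated once so the mixture mean matches the pooled
target. Baseline patterns superpose per-location jitter (SD 0.5 dB), a
diffuse shift, and a loading on one defect archetype (superior/inferior
arcuate, nasal step, paracentral; unit mean over support); the localized
share is 70% of the deficit, capped so no location starts below the
recordable floor. Progression rates are min(0, N(μ_s, σ_s)) dB/year on the
MD scale (normal exactly 0, suspect −0.05 ± 0.05, glaucoma −0.5 ± 0.4),
spread over the patient's own archetype with the same 70% localized share
so the mean rate equals the drawn MD rate. Visits add iid N(0, 2²) dB noise
per location and clip to [−38, +6]. Reliability indices are Uniform(0, 0.1).

What this generator does *not* emulate — and what that implies for
interpreting results on it:

* **Test-retest noise is iid across locations.** Real SAP noise has a
  strong spatially correlated (session) component and grows with damage.
  Independent noise averages away in the 52-point mean, giving the MD slope
  an unrealistically small standard error (2/√52 ≈ 0.28 dB per visit), so
  the MD comparator is substantially *stronger* here than on clinical data.
  Hit-rate comparisons against MD on this simulator are therefore biased
  against the latent tests; prediction comparisons (against pointwise
  regression, which enjoys no such averaging) are unaffected.
* The signed mean of per-feature latent slopes can cancel: a patient can
  move quickly through latent space along a direction whose coordinates sum
  to ~0. The direction-agnostic joint-F variant does not suffer from this
  and empirically detects more progressors at early cutoffs.
* No learning or fatigue effects, media opacities, lid artifacts, or
  floor-driven heteroscedasticity; visit gaps are not clustered.

Zero-noise simulation is supported (noise_sd_dB = 0) and per-location OLS
on unclipped zero-noise series recovers the generating rate pattern to
1e−8, which is the package's parameter-recovery check.

## Problem sizes used by the test suite

The end-to-end checks run a 2,000-patient cohort (≈15,000 fields), an
L = 8 model trained for 30 epochs (close to the typical best-validation
epoch of ~35 reported for this architecture at full scale), and 2,000-series
null calibrations — sizes chosen so the full suite completes in minutes on
one CPU core while keeping binomial tolerances tight (±1.5% on a 95%
specificity target).

## Known limitations

* The latent linear "global rate" inherits the cancellation caveat above;
  a norm-based (speed) statistic would avoid it but would no longer admit
  the simple t-test calibration.
* MD/PSD surrogates are unweighted; absolute hit rates for the MD
  comparator are not comparable to device-reported MD analyses.
* The normalization range and padding convention are fixed; fields outside
  [−38, +6] dB are clipped.
* Checkpoints store raw float64 weights (.npz); no quantization or
  cross-version compatibility guarantees.
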