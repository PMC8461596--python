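# Methods

This note documents the models, parameters and numerical choices behind
`thermovae`, and what the synthetic experiments do and do not show.

## The detection problem

The package builds an *individual* model of normal facial skin
temperature (FST) across the day and flags images inconsistent with it.
Normality is learned, anomaly is everything else: training uses only
normal images, because abnormal physiological states are rare and
heterogeneous, while normal data is cheap to collect. The pipeline is

simulate (or load) → normalize/patch → train VAE → score → Hotelling
threshold → evaluate.

## Synthetic data generator

The generator stands in for an infrared thermography acquisition and is
first-class, tested code. One frame is

T(i, j) = T_bg outside the face mask, and inside the mask
T(i, j) = T_base + A sin(2π(h − φ)/24) + V(i, j) + s·Δ·w(i, j) + ε(i, j)

| parameter | default | meaning |
|---|---|---|
| T_bg | 22.1 °C | room/background temperature |
| T_base | 34.0 °C | facial baseline temperature |
| A | 0.3 °C | diurnal (circadian) amplitude |
| φ | 10 h | phase; gives a late-afternoon (16:00) peak |
| V | ridges of 0.3–0.6 °C, width 1–3 px | warm vascular texture |
| Δ | 0.8 °C | forced temperature change at full task response |
| w | periorbital Gaussian profile (or uniform) | spatial pattern of the response |
| ε | i.i.d. N(0, 0.05² °C) | sensor noise at the resolution bound |

Vessels are random smooth quadratic curves with Gaussian cross-sections,
combined as a ridge (pointwise maximum) so each vessel's crest equals its
amplitude. They exist because the patch VAE is supposed to learn fine
sub-patch vascular texture; without them the images would be learnable
by trivial statistics. The two subject profiles differ in crop size
(90×83 and 73×94 pixels) and vessel layout.

The protocol emits, per session hour (8–23), 120 rest frames labeled
Normal and 60 task frames whose anomaly strength follows a cubic
smoothstep ramp from 0 (before a 10 s onset) to 1 at task end; the last
20 s are labeled Anomaly, earlier task frames stay unlabeled because the
response is still developing. Counts are exact functions of the
configuration (16 × 120 = 1920 normal frames by default), and the whole
sequence is a pure function of the seeds.

The task response defaults to a **periorbital focus** rather than a
uniform facial shift: acute autonomic thermal responses are classically
concentrated in the periorbital/forehead region, and a spatially uniform
offset is largely removed by per-image min–max normalization, which
would make the simulated anomaly an artifact of the normalizer rather
than a physiological pattern. A `global_shift` profile is available.
The response magnitude Δ is a free parameter of the simulation (the
breath-hold literature quantifies it poorly); 0.8 °C is used as a
moderate default, clearly above the 0.3 °C diurnal amplitude yet small
against the ~12 °C face–background contrast.

What the generator does **not** emulate: real vascular anatomy, head
motion and registration error, emissivity/atmospheric effects, sensor
quantization and drift, and inter-day variability. Passing tests
therefore show the *method* is implemented correctly and behaves as the
theory predicts on data satisfying its assumptions — not that the
detector would reach the same operating characteristics on real faces.

## Preprocessing

Each cropped image is min–max normalized to [0, 1] independently
(affine, order-preserving; constant images are rejected). Patches are
8×8 sub-windows with corners drawn uniformly with replacement over the
valid-position grid; learning sets are expanded to an exact count by
cycling over source images (counts differ by at most one across
sources). The 1920 normal images split 90/10 into 1728 learning images
and a holdout from which 60 test images are subsampled; anomaly test
images are the 20 last-window frames of one randomly chosen session.
Coordinates are 0-based, row-major, half-open everywhere.

## The patch VAE

Architecture (latent dimension 6):

- encoder: Conv(16, 2×2, stride 2) → BatchNorm → ReLU →
  Conv(32, 2×2, stride 2) → BatchNorm → ReLU → FC → (μ_z, log σ²_z);
  spatial chain 8 → 4 → 2, no padding.
- decoder: FC → BatchNorm → ReLU → reshape 32×2×2 →
  ConvT(32, 2×2, stride 2) → BatchNorm → ReLU →
  ConvT(16, 2×2, stride 2) → BatchNorm → ReLU →
  two parallel ConvT(1, 4×4, stride 1, same-padding) heads emitting the
  per-pixel reconstruction mean μ_x and log-variance log σ²_x.

The two stride-1 heads are read as parallel output heads with **no**
activation after them: a trailing ReLU would forbid negative
log-variances and clip means at zero, and the anomaly score requires
both μ_x and σ²_x per pixel. This is the one reading of the layer table
that supplies both likelihood parameters; it is a design choice of this
package, not an asserted fact about the original network.

Training minimizes the negative ELBO

loss = Σᵢ [(μ_xi − xᵢ)²/(2σ²_xi) + ½ log σ²_xi]
     + ½ Σⱼ [μ_zj² + exp(log σ²_zj) − log σ²_zj − 1]

with the reparameterization z = μ_z + σ_z ⊙ ε in training only. Defaults:
15 epochs, batch 128, Adam(lr 1e-3, β 0.9/0.999, eps 1e-8), seeded weight
initialization (He) and shuffling. "Best model" selection trains 3
independent seeded initializations and keeps the lowest final epoch
loss. The network is implemented directly on numpy with hand-derived
backpropagation, verified against central finite differences in the test
suite; the stride-2 2×2 (de)convolutions have kernel = stride and reduce
exactly to per-block matrix products. Training runs in float32 (weights,
activations, optimizer state) for speed; inference upcasts with its
inputs. Everything is single-threaded deterministic: same seed and data
give an identical loss history.

Numerical choices: log σ²_x is clamped to [ln 1e-4, 10]. The lower floor
(variance floor 1e-4) keeps the inverse-variance score bounded — small
decoder variances otherwise make scores diverge; the upper clamp only
guards exp overflow. Clamped pixels pass no gradient. BatchNorm uses
eps 1e-5, momentum 0.1, biased batch variance, running statistics for
inference.

## Anomaly score and statistics

A patch is scored deterministically at the posterior mode (z = μ_z):
L(x) = Σᵢ (μ_xi − xᵢ)²/(2 σ²_xi) over the 64 pixels. A test image is
reduced to x′ = (ln mean, ln variance) of the scores of 100 random
patches (natural log; unbiased n−1 variance). Per-image statistics are
used because the model consumes patches but decisions are per image;
100 patches balance statistic stability against cost. Per-image patch
seeds derive from one master seed, so scoring a dataset is reproducible
and order-preserving.

## Hotelling detector

Normal x′ vectors get a maximum-likelihood Gaussian fit: μ̂ the sample
mean, Σ the covariance divided by n (no small-sample T² correction —
the χ² approximation is used directly). Degree of anomaly:
a(x′) = (x′ − μ̂)ᵀ Σ⁻¹ (x′ − μ̂). The threshold for a desired detection
probability P is the (1 − P) quantile of χ²_d. Decisions use strict
inequality; ties go to Normal.

Two open choices and their resolutions:

- **Degrees of freedom.** Hotelling theory for d-dimensional statistics
  yields χ²_d; x′ is 2-dimensional, so d = 2 is the default, with d = 1
  available as an option. (A χ²₁ description of a 2-D statistic appears
  in the source literature of this method; the discrepancy is noted, not
  resolved, and both are supported.)
- **Fitting population.** The null is fitted on the held-out *normal*
  statistics only, consistent with normal-only learning: the threshold
  then calibrates the false-positive rate under the normal model. The
  CLI exposes `--fit-on all` for comparison.

The "detection probability" P is implemented as the null tail mass,
i.e. the false-positive rate under the fitted normal model — under the
null exactly P of samples fall outside the contour (verified to ±0.3
percentage points at P = 5% on 100,000 draws).

## Evaluation

Shapiro–Wilk tests on the log-mean and log-variance samples gate the
Gaussian assumption (both p > 0.05 to pass); failure warns but does not
abort. ROC analysis ranks images by a(x′) — any strictly monotone
transform of the score, including the implied P, gives the same curve —
and AUC uses the Mann–Whitney rank formulation with half-credit ties,
which equals trapezoidal integration of the swept curve (asserted to
1e-12 in tests). The detection-plane figure scatters x′ by label and
overlays the nested probability ellipses (30…5% by default).

## Problem sizes used in tests and the acceptance script

The acceptance computation runs the full stated scale: 1920 normal
frames, 10,000 learning patches, 15 epochs, 60 + 20 test images with
100 patches each, three seeds per anomaly magnitude (0.8 °C and 1.5 °C)
reporting the median AUC, and 100,000 null draws for calibration. The
unit-test suite reuses reduced configurations (fewer sessions, smaller
patch sets, one training candidate) wherever the property under test
does not depend on scale; desk-scale training properties (decoder
variance tracking texture variance, constant-texture mean
reconstruction) state tolerances that reflect finite optimization, a
factor of two on variances and ~0.06 absolute on [0,1] means.

## Known limitations

- The synthetic anomaly is, by construction, detectable; the default
  0.8 °C periorbital response yields AUC near 1, higher than on real
  subjects where learning stability and individual differences matter.
- Min–max normalization makes the method blind to purely uniform
  temperature shifts (by design, it targets *patterns*); a global-shift
  anomaly is detected only through second-order contrast effects.
- The Gaussian null is an approximation; when the Shapiro–Wilk gate
  fails, χ² thresholds lose their calibration guarantee.
- Per-image score statistics ignore temporal structure; no sequential or
  multi-image decision rule is provided.
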