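# Methods

This note documents the models implemented in `mlifpet`, the tunable
parameters and their defaults, what the digital phantom does and does
not emulate, and the numerical and design choices that were genuinely
open.

## Signal model

A dynamic ¹⁵O-water brain scan is acquired over 10 min in 26 frames
(1×10, 8×5, 4×10, 2×15, 3×20, 2×30, 6×60 s). All curves are treated in
seconds and kBq/mL internally. Frame-based curves are assigned to frame
midpoints and linearly interpolated onto a uniform 1-s grid; before the
first midpoint the value ramps linearly from 0 at injection (no
pre-injection activity is fabricated), after the last midpoint the last
value is held. Analysis uses the closed window t ∈ [0, 360] s — 361
samples — because the late scan is noise-dominated for a 2-min
half-life tracer. The endpoint convention (inclusive) is a fixed array
shape choice, not physics.

## Blood chain

The wrist detector measures g(t) = (C_A ⊗ d)(t) with mono-exponential
dispersion d(t) = (1/τ)e^(−t/τ). The Laplace-domain inverse is exact:
C_A(t) = g(t) + τ·dg/dt.

- τ defaults to 15 s, a fixed population value for standard sampling
  lines; per-subject τ estimation is out of scope.
- The derivative uses central differences (second-order one-sided at
  the ends). `correct_dispersion` applies no smoothing by itself, but
  the composed pipeline (`RunConfig.blood_smooth_s`, default 5 s)
  applies a 5-s moving average before differentiating: the τ·dg/dt term
  amplifies 1-Hz detector noise by roughly an order of magnitude, and a
  5-s window is short against both τ and the bolus width, so it
  suppresses that amplification at negligible bias. Set it to 0 to
  reproduce the raw inversion.
- The forward operator (`apply_dispersion`, used by the phantom and in
  round-trip checks) is a trapezoid-rule causal convolution —
  second-order accurate with no half-sample lag; the apply-then-correct
  round trip on a smooth bolus errs ≈0.16% RMS of peak at 1 s and
  shrinks with grid refinement.
- Calibration scales the corrected curve so its mean over ±10 s around
  the single well-counter sample (drawn 5 min post injection) equals
  the sample concentration. The window suppresses residual 1-Hz noise
  at the single calibration point.
- Delay alignment shifts the AIF by the integer-second s ∈ [−30, +30]
  maximizing Σ_t aif(t−s)·idif₁₀(t), zero-padded outside the support.
  ±30 s covers physiologic arm-to-brain transit differences. Ties break
  toward the smallest |s| for determinism. The processing order —
  dispersion-correct, calibrate, align — is fixed for reproducibility;
  calibration is a pure scale, so its position relative to the
  dispersion correction is immaterial.

## Carotid IDIF extraction

The search volume drops 20 voxels from each x/y edge and 5 slices from
each z end (the trim is symmetric in z; edge artefacts motivate both
ends). The threshold frame is the first whose grey-matter summed
intensity strictly exceeds 25% of that graph's maximum — early enough
to catch the first pass, late enough to be above noise. The 10/100/1000
highest-intensity voxels of that single frame form three VOIs; ties at
the cutoff break by ascending linear voxel index. Per-frame VOI
medians (even counts: mean of the central pair) give robust IDIFs. The
three channels are the same blood signal at increasing partial-volume
dilution; the GP model absorbs the partial-volume relationship, so no
explicit PVE correction is performed.

## GP input-function model

Inputs are whole-curve vectors: the three IDIFs (361 samples each),
each channel divided by its training-cohort maximum peak, concatenated
to x ∈ R^1083. Training inputs land in [0, 1]; test inputs may exceed 1
— the normalization is a per-channel scale only, so between-subject
amplitude relations survive, and a held-out subject is always
normalized with training-fold constants (no test blood data enters
anywhere). Outputs y ∈ R^361 are the measured AIFs and are *not*
normalized: the output scale is what lets a predicted MLIF replace a
calibrated blood curve.

One isotropic Matérn-5/2 kernel over the 1083-dimensional input is
shared by all output time points (an N×N kernel matrix with an N×T
output matrix); cohorts of N ≈ 20 cannot support ARD over 10³
dimensions. The GP mean function is the empirical training-mean AIF
curve, and the kernel models residuals about it. A zero mean was tried
first and rejected: on strictly positive curves the marginal-likelihood
optimum degenerates — either a flat kernel (lengthscale at the upper
bound) or a diagonal one — and both predict the cohort-mean curve for
every test subject, destroying per-subject amplitude tracking
(pooled CBF r² 0.39 vs 0.93 on the phantom benchmark).

Hyperparameters (lengthscale ℓ, signal variance, noise variance σ_ε²;
σ_ε² is optimized, not fixed) maximize the log marginal likelihood
summed over output dimensions, via L-BFGS-B in log-parameter space.
Starting points are data-scaled — ℓ at the median pairwise input
distance, variances at the centred-output variance — with a fixed
three-point multi-start keeping the best optimum; fixed unit-scale
starts sit many orders of magnitude off the kBq/mL output scale and
strand the optimizer on a boundary. Training is deterministic given
the training set. All solves go through a cached Cholesky factor of
K + σ_ε²I with a 1e-10 jitter floor; the predictive variance (one value
per test input, shared across output time points) is clipped at zero
against roundoff. Self-consistency: data drawn from a Matérn-5/2 GP
with known ℓ returns ℓ within 25% at N = 40, T = 50.

The predictive variance is reported but not used as a quality gate; no
relationship between it and CBF accuracy is assumed.

## Kinetic model

C_T = K₁·(C_A ⊗ e^(−k₂t)), C_PET = (1−V_A)·C_T + V_A·C_A. The
convolution uses the trapezoid rule at 1 s with the exponential kernel
in consistent per-minute units (it reduces exactly to the cumulative
trapezoidal integral at k₂ = 0). Fitting is trust-region-reflective
least squares, uniform weighting over the 1-s grid (frame-duration
weighting available via the `weights` argument), bounds K₁ ∈ [0, 5]
mL·min⁻¹·g⁻¹, k₂ ∈ [0, 10] min⁻¹, V_A ∈ [0, 1], start (0.5, 1.0, 0.05),
tolerances 1e-10. Tissue density is taken as 1 g/mL so mL·min⁻¹·mL⁻¹ is
reported as mL·min⁻¹·g⁻¹. Optimizer failure is reported through the
`converged` flag, never silently. Whole-region CBF fits the mean
grey-matter TAC, not voxelwise maps.

## Evaluation battery

Curve agreement re-bins the 1-s curves onto the original frame grid by
frame-averaging (the re-binning operator is a choice; frame averages
are the natural inverse of midpoint interpolation) and fits orthogonal
(total-least-squares) regression, i.e. equal error variances in both
axes, computed from the SVD of the centred data matrix. Slopes more
than 3 scaled MADs (scale factor 1.4826, the normal-consistency
constant) from the median slope flag outlier scans; when the MAD is
zero the rule degenerates to flagging any value different from the
median (its limit behaviour). Value agreement uses two-sided paired
t-tests, mean per-pair ratios and Bland–Altman bias ± 1.96·SD limits.
Three designs are composed: per-condition leave-one-out models
(case 1), a transfer model trained on all baseline scans and tested on
challenge scans (case 2), and kinetic modelling driven directly by
IDIF₁₀ with no GP (case 3, used only for relative change).

## Digital phantom

Each subject has a systemic bolus — gamma-variate first pass
(amplitude ~N(60, 8) kBq/mL clipped ≥30, shape α ~U(2, 4), arrival
t₀ ~U(8, 14) s, time-to-peak ~U(8, 14) s) plus a recirculation tail
(12–20% of peak, 15–25 s rise, 200–300 s decay) — arriving at the
carotids after a brain delay of 3–7 s and at the wrist detector 8–14 s
later, dispersed with τ = 15 s and scaled by an arbitrary per-subject
detector gain (log-uniform in [0.5, 2]). True CBF is N(0.45, 0.05)
mL·min⁻¹·g⁻¹ at baseline and N(0.60, 0.07) after the vasodilator
challenge (truncated >0.2), with k₂ = CBF divided by a distribution
volume ~N(0.9, 0.05) mL/g and V_A = 0. The challenge also shortens the
brain delay by 3 s and increases the local bolus area by 15%,
emulating faster cerebral inflow; both conditions of a subject share
one random draw (common random numbers), so paired contrasts are
well-posed.

Images are 64×64×32 at 2 mm: two carotid tubes (radius 2 voxels)
carrying the local input function and an ellipsoidal grey-matter shell
carrying the one-tissue response, frame-averaged, blurred with a 5-mm
FWHM Gaussian PSF and degraded with zero-mean Gaussian noise of
variance ∝ (signal + floor) / frame duration (≈5% of the bolus peak
per voxel in a 5-s frame at the default noise scale of 1). The wrist
record gets signal-proportional-variance noise (1% of peak at the
peak), the count-statistics analogue for a 1-Hz detector. The
grey-matter mask handed to the pipeline is the PSF-safe core of the
shell (blurred indicator > 0.99), mirroring a conservative/eroded MRI
segmentation; without it the PSF dilutes the region mean by ~13%
uniformly, which is a partial-volume property of the phantom geometry,
not of the input-function method under test.

Ground truth is kept in separate sidecar records (`truth/` on disk)
that no pipeline stage reads.

What the phantom does **not** emulate: anatomy (no real vasculature,
cortex or skull), head motion, scatter/randoms or reconstruction
artefacts, spill-in from extracerebral tissue, subject-specific
dispersion constants, or pathology-driven AIF shape changes. Passing
phantom tests therefore demonstrates correctness of the algorithms
under the stated generative assumptions — not clinical performance.

## Problem sizes

The standard benchmark cohort is 20 paired subjects (40 scans) at the
default noise scale, and parameter-recovery statistics use 100
independent scan renders; both were chosen as the smallest sizes at
which the cohort-level statistics (paired t-tests, pooled regression)
are stable across seeds.

## Known limitations

- The whole-curve input encoding (one 3T-dimensional vector per scan)
  is one of two defensible readings of the model; a per-time-point
  encoding with time as an input feature is the alternative and is not
  implemented.
- The GP extrapolates poorly outside the training amplitude range
  (domain shift): transfer-model predictions for strongly altered
  physiology inherit this.
- Delay alignment is integer-second; sub-second residual delays remain
  and contribute ≲1% to fitted CBF.
- `fit_1tcm` assumes decay-corrected, motion-corrected input; neither
  correction is provided here.
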