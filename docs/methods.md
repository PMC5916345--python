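# Methods

This note records the models implemented in `petkin`, the numerical choices
behind them, what the synthetic generators do and do not emulate, and the
design decisions taken where the conventions in the field are genuinely
open. Nothing here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Kinetic models

### Reference Patlak

For an irreversibly trapped tracer with a reference-tissue input, tissue
activity beyond the pseudo-equilibrium time t\* satisfies

    C_T(t) / C_R(t) = Ki * (∫0..t C_R dτ) / C_R(t) + V.

`PatlakModel.fit` performs ordinary least squares of the transformed frames
whose midpoints fall in [t\*, end]. The running integral is the trapezoid
rule over frame midpoints with an implicit (0, 0) origin — the standard
discretisation for frame data, and the same rule the graphical-exact
simulator uses, which is why the round trip is exact to machine precision.
Defaults: t\* = 25 min on the 25-frame/90-min schedule, slope reported as
Ki in min⁻¹ scaled to the reference distribution volume. The scaling
convention for reference-input Patlak is not universal; the slope-of-
normalised-integral convention used here is documented rather than assumed
comparable to arterial-input Ki.

### Basis-function SRTM

The simplified reference tissue model assumes one apparent tissue
compartment, a reference region without specific binding, and equal
non-displaceable distribution volumes. Its operational equation

    C_T = θ1 * C_R + θ2 * (C_R ⊗ exp(-θ3 t)),   θ1 = R1, θ2 = k2 - R1 θ3

is linear in (θ1, θ2) at fixed θ3, so the fit is a 1-D search over a θ3
grid with a weighted linear solve per basis. Choices:

* **θ3 grid**: 128 log-spaced values in [0.006, 0.6] min⁻¹, bracketing
  plausible apparent clearances for reversible striatal tracers. Grid
  resolution is ±1.8 % in θ3, but because θ1 and θ2 re-optimise at each
  grid point the BP_ND error of a noiseless refit is far smaller — the
  suite measures ≤ 0.5 % across BP_ND ∈ [1, 5] and ≤ 0.31 % at the
  acceptance points.
* **Weights**: uniform by default; frame-duration weighting is available
  (`weights="frame_duration"`). Published basis-function implementations
  differ here and the choice is second-order at the noise levels studied.
* **Convolution**: the reference curve is reconstructed by linear
  interpolation through (0, 0) and the frame midpoints, held flat after
  the last midpoint, on a 0.1-min uniform grid. Convolution with
  exp(-θ3 t) uses a one-step recurrence that is exact for piecewise-linear
  inputs, then frame-averages. The forward simulator uses the same
  machinery, so simulator-vs-fitter error isolates grid resolution rather
  than quadrature.
* **Ties**: equal RSS resolves to the smaller θ3 (the smoother solution);
  with strictly increasing grids this is the first minimum encountered.
* **Degenerate inputs**: an identically zero reference or an all-NaN
  tissue raises; voxelwise fitting converts per-voxel precondition
  failures into NaN instead.

BP_ND = k2/θ3 − 1 throughout, equal to f_ND·B_avail/K_D at the receptor
level (`bpnd_from_receptors`).

### Release statistic

Dopamine release under a challenge drug is quantified as
100·(BP_placebo − BP_drug)/BP_placebo per subject, then averaged across
subjects. The mean of per-subject ratios is not the ratio of mean BP_ND
values (for the default cohort the two differ by ≈ 0.35 percentage
points); the per-subject convention is used everywhere.

## Synthetic data

The generators produce exactly the structures the analysis assumes, so
parameter recovery is a meaningful end-to-end check.

* **Plasma input**: a tri-exponential bolus (Feng form), zero at t = 0,
  sharp early peak, slow tail. It is never observed by any fitter — the
  analysis is reference-region based — so its only job is to drive
  realistic reference kinetics.
* **Reference region**: one-tissue kinetics with K1' = 0.1 mL/min/g,
  k2' = 0.1 min⁻¹ (plausible cerebellar-gray values; no downstream
  estimate depends on them — both models are invariant to common scaling
  and only see the resulting curve). Simulated at 0.01-min resolution.
* **Irreversible tissue**: `graphical_exact` mode builds the TAC at the
  frame level with the fitter's own integral rule, making the Patlak plot
  linear by construction — the right fixture for exactness tests.
  `compartmental` mode integrates the two-tissue irreversible system
  driven by the reference curve, producing the early transient that Patlak
  only linearises beyond t\*.
* **Reversible tissue**: the SRTM operational equation evaluated at the
  true (R1, k2, BP_ND); the drug scan uses BP_ND·(1 − release fraction).
* **Noise**: zero-mean Gaussian per frame with SD =
  scale·sqrt(activity/duration), the standard frame-weighted
  approximation to count statistics. The default cohort scale is 0.05
  (sub-percent noise on late striatal frames) — a low-noise regime chosen
  so cohort-level recovery isolates model error; no published TAC noise
  magnitude exists for these acquisitions to calibrate against.
* **Cohorts**: each subject draws one latent z per measure
  (Ki, baseline BP_ND, release, body weight) from a joint Gaussian with a
  configurable correlation matrix; each region's value is mean + SD·z with
  region-specific moments (defaults: healthy-adult striatal values — whole
  striatum Ki 0.015 ± 0.002 min⁻¹, BP_ND 2.19 ± 0.18, release
  8.78 ± 4.23 %, and corresponding subregion values). Release is mapped
  through a Gaussian copula onto a truncated normal on [0, 0.9] whose
  parameters are moment-matched so the truncated distribution has exactly
  the stated mean and SD (naive truncation would inflate the mean by
  ≈ 0.2 points). Body weight derives from a fixed 30 mg dose and an
  mg/kg distribution of 0.46 ± 0.08. The default cross-measure correlation
  sets Ki × BP_ND = 0.46, Ki × release = −0.01, weight independent.
  Latent factors are shared across regions, so between-region correlations
  are perfect in truth — adequate for per-region analyses, wrong for
  questions about regional independence. Reference TACs are shared and
  noiseless (the anatomical reference region is far larger than striatal
  ROIs and correspondingly better determined).
* **Phantoms**: labelled grids with piecewise-constant truth, blurred by
  an isotropic Gaussian PSF. The blur kernel integrates the Gaussian over
  each unit voxel (erf differences) rather than point-sampling it; for
  piecewise-constant images this equals the continuum blur to kernel
  truncation (6σ, tail ≈ 2×10⁻⁹), which is what makes the closed-form
  erf oracles in the tests meaningful at 10⁻⁶.

What the generators do **not** emulate: radioactive decay, scatter,
attenuation, metabolites, head motion, scanner geometry, inter-subject
anatomical variability or spatial normalisation, and any between-region
heterogeneity of kinetic parameters within subject beyond the target
values. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Imaging layer

* **Voxelwise fits** reuse the scalar models; the SRTM path solves the
  per-θ3 normal equations for all voxels at once.
* **Map smoothing** (`smooth_map`) uses a sampled-Gaussian kernel in mm
  with NaN-aware renormalisation (missing voxels excluded and the kernel
  mass renormalised over defined voxels); a constant map is unchanged and
  interior-supported images conserve their sum.
* **Group t-maps**: one-sample against zero or paired via the difference
  stack (the two coincide by construction); zero-variance or incompletely
  observed voxels are NaN; df = n − 1 rides along in metadata.
* **Cluster thresholding**: two-tailed cluster-forming p (default 0.001)
  on the t distribution, same-sign connected components under configurable
  connectivity (default 6/face adjacency, the AFNI NN1 convention; the NN
  level used by any given study is rarely stated), minimum extent k
  (default 55 voxels), peak at the largest |t| with ties to the lowest
  linear index. Sidedness of group tests is configurable because
  published contrasts often leave it implicit; defaults are two-tailed.
* **Monte-Carlo extent calibration** (`cluster_extent_mc`): smoothed
  Gaussian white-noise volumes, standardised within the search mask,
  |z|-thresholded; returns the smallest k whose null exceedance
  probability is ≤ α. Any published k for a specific scanner/mask is a
  property of that data; the pipeline accepts k as configuration and can
  derive one for a given mask and smoothness.
* **Posterior-cerebellum rule**: among coronal slices containing the
  cerebellar label, the most anterior round(fraction·n) slices (round half
  up — exact for counts divisible by 4, deterministic otherwise) are
  cleared before use as a reference region, limiting spill-in from
  midbrain dopamine nuclei.

## Partial-volume correction

ROI-based GTM: ω_ij is the mean over region i's voxels of region j's
PSF-blurred indicator; observed means obey ω·true = observed, solved
directly. The unlabelled remainder is always included as an explicit
background region, making each row of ω a partition of unity — omitting it
biases corrections whenever background activity is nonzero. The PSF width
is configuration (default 4 mm FWHM, matching the reconstruction smoothing
used in this acquisition family; true scanner PSFs are rarely printed).
`gtm_correct` refuses matrices whose condition number exceeds a threshold
rather than amplifying noise silently.

## Statistics

* **Correlations**: Pearson or Spearman point estimates with t-transform
  p-values; CIs are percentile intervals over seeded paired bootstrap
  resamples (default 1000). Degenerate resamples are skipped. The
  percentile method is the default because nothing finer than "bootstrap
  CI" is conventionally reported; BCa could be added behind the same
  interface.
* **Partial correlation**: residual-on-covariates Pearson r with
  df = n − 2 − k. Used by the pipeline for the Ki × release comparison to
  correct for body weight under a fixed-mg dosing design.
* **Normality gating**: Shapiro–Wilk at α = 0.05 routes a comparison to
  Spearman when either margin rejects normality.
* **Paired t / dz**: d_z = mean(d)/sd(d) = t/√n.
* **Regression**: statsmodels OLS with intercept; per-coefficient t/p,
  model F, adjusted r². The pipeline's post-drug BP_ND model uses Ki,
  baseline BP_ND and region volume as predictors, dropping volume for the
  mask-derived whole-striatum region where it cannot vary.
* **Power**: Fisher-z approximation,
  power = Φ(|atanh ρ|·√(n−3) − z_crit) plus the negligible opposite tail.
  This differs from exact bivariate-normal routines (e.g. G\*Power) by a
  little under the percent level at n = 40; under this formula two-tailed
  power 0.80 at n = 40 corresponds to ρ ≈ 0.43, and detecting ρ = 0.32
  with power 0.80 needs n = 75.
* **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  measure — the standard choice for inter-rater reliability of continuous
  regional values; cross-checked against pingouin in the suite.
* **Missing data**: strict refusal at the operation level; the pipeline is
  expected to apply listwise deletion before calling.

## Problem sizes and seeds

Everything stochastic takes an explicit seed and reproduces bit for bit.
The recovery experiments in `scripts/acceptance.py` use 40-subject
single-region cohorts — 20 seeded cohorts for the release recovery and 50
for the correlation recovery, sizes at which the Monte-Carlo error of the
grand mean (≈ 0.15 percentage points and ≈ 0.02 r-units respectively) sits
comfortably inside the quantities' own sampling variability. Cohort-moment
tests use 10⁴ truth-only draws (TAC generation skipped) with 2-standard-
error tolerances; the type-I calibration uses 2000 replicates at n = 40.

## Known limitations

* SRTM assumptions (single apparent compartment, ideal reference) are
  built into both simulator and fitter; the package cannot by itself
  reveal biases that arise when real tissue violates them.
* The θ3 grid bounds clip extreme BP_ND (< k2/0.6 − 1 or very slow
  clearances); widen the grid for tracers outside the striatal D2/3 range.
* Percent-change estimates inherit doubled grid-quantisation error from
  the two BP_ND fits (≈ 0.1 percentage point at default settings).
* GTM correction assumes piecewise-constant regional activity and a known
  stationary isotropic PSF.
* No decay correction, motion, registration or spatial normalisation:
  volumes entering any operation must already share a grid.
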