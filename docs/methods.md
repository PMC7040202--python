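# Methods

This note documents the models, conventions and parameter choices behind
the package, what the synthetic cohorts do and do not emulate, and the
known limitations. Nothing here states an empirical result that the tests
or `scripts/acceptance.py` do not themselves compute.

## Volumes and grids

Voxel arrays are indexed `(z, y, x)` (slice, row, column) with spacing and
origin stored in the same order, in millimetres. Files are re-oriented to
LPS on load when the header carries direction cosines, so the 13 texture
direction labels mean the same thing for every input. An image/mask pair
must agree in shape, spacing and origin to within 1e-4 mm — the pipeline
assumes co-registered inputs and performs no registration. Before feature
extraction both volumes are resampled to 1 mm isotropic (trilinear for
intensities, nearest-neighbour + re-binarization for the mask); inputs
already on the target grid pass through untouched so no interpolation
error is introduced.

## Phantom simulator

Each phantom is an ellipsoidal tumor (default semi-axes 14 × 11 × 9 mm,
jittered ±20% per patient) centred in a 64³ voxel grid at 1 mm spacing —
a desk-scale stand-in for a 512×512, 1 mm-slice CT. Background voxels are
−50 + N(0, 15²) HU-like units; tumor voxels are 40 + s, where the texture
field s is built by:

1. white Gaussian noise, smoothed with an isotropic Gaussian kernel of
   physical width ℓ (the correlation length, default draw U(1, 4) mm);
2. standardization over the grid;
3. an optional monotone skewing map u → sinh(asinh(u) + γ) (identity at
   γ = 0; default draw U(−0.6, 0.6)), re-standardized;
4. scaling to variance σ² (default draw U(25, 400)).

The variance control is exact in expectation (tested against the law of
large numbers at ℓ → 0); γ is the handle that third-moment texture
features (GLCM cluster shade) respond to, verified as a monotonicity
property test.

Progression times are exponential: T ~ Exp(λ₀·exp(β·z)) with λ₀ = ln2/248
per day, so a null cohort has median PFS 248 days, and z the
cohort-standardized covariates named in β. Censoring is administrative,
C ~ U(30, 1095) days, giving ≈ 29% censoring at β = 0. The constant
baseline hazard makes medians and event fractions closed-form, which the
tests exploit. The default effect is β = 1.5 per SD of σ² and 1.2 per SD
of γ: this was calibrated so that the *extracted* signature's held-out
discrimination lands in the regime such signatures show on real cohorts
(validation C-index ≈ 0.7, median-split hazard ratios ≈ 2–5), absorbing
the attenuation between latent texture parameters and their feature-level
estimates. A `null_cohort` helper forces β = 0 for negative controls.

What the phantoms do **not** emulate: lung anatomy, lesion spiculation or
infiltration, partial-volume and reconstruction-kernel effects, scanner
noise spectra, inter-observer segmentation variability, and non-ellipsoid
shapes. Passing tests therefore demonstrate that the *pipeline machinery*
recovers known texture–survival structure; they say nothing about the
clinical validity of any particular signature.

## Feature registry (481)

13 shape features (computed once on the original-grid mask) plus 9
channels × 52 per-channel features:

- channels: original + 8 sub-bands (LLL…HHH) of a single-level
  **undecimated** coif1 wavelet decomposition, implemented as separable
  1-D correlations with the PyWavelets coif1 decomposition filters and
  reflection boundaries. Undecimated output keeps the input shape, so the
  original mask applies unchanged. Band letters follow array axis order
  (z, y, x).
- first-order (16): min, max, mean, median, range, variance, SD (all
  population-convention), Fisher skewness, non-excess kurtosis (normal
  = 3), energy, histogram entropy and uniformity (on the discretized
  levels), mean absolute deviation, RMS, 10th/90th percentiles.
- GLCM (24) and GLRLM (12): computed per direction over the 13 unique 3D
  offsets at distance 1 (GLCM symmetric), then feature values averaged
  over directions; directions with no valid pair/run are excluded from
  the average rather than zero-filled, which avoids biasing thin VOIs.
  The run-length family keeps gray-level variance and drops run-length
  variance to close the family at 12.

Discretization is equal-width into Ng = 32 levels over the VOI's
[min, max], recomputed per channel; a constant VOI maps to level 1 and is
flagged. Degenerate GLCM statistics (correlation, IMC1) are defined as 0
when a marginal is degenerate.

Shape conventions: the reported `volume` is voxel count × voxel volume;
`surface_area` comes from a marching-cubes mesh of the mask blurred with a
σ = 1 voxel Gaussian (anti-aliasing the staircase artefact, which
otherwise inflates a digital ball's area by ~8%), falling back to the raw
binary surface when the blurred peak drops below the 0.5 iso-level (tiny
structures). Sphericity and the compactness measures use the mesh-enclosed
volume together with the mesh area, which guarantees sphericity ≤ 1 for
masks of any size; axis lengths are 4·√eigenvalue of the physical
voxel-center covariance, with elongation/flatness defined as 0 for
degenerate (≤ 1 voxel) masks. The maximum 3D diameter uses voxel centers
(convex-hull accelerated above 1500 points).

These composition choices (channel set, Ng, direction aggregation, wavelet
family) are the package's own documented defaults; radiomics platforms
differ on all of them, and the registry is configurable.

## Feature discovery

Normalization is z-scoring with training-cohort mean and *sample* SD
(ddof = 1); zero-variance training columns are dropped with a logged
warning, and all other cohorts are transformed with the training state
(no leakage; covered by sentinel tests).

Pearson pruning removes features until no surviving pair has |r| > 0.8.
The removal rule is deterministic: iteratively drop the feature with the
most over-threshold partners, ties broken by larger mean |r| against the
current survivors, then by later registry order (earlier-registered
features survive ties).

The LASSO-Cox path uses scikit-survival's Coxnet (l1_ratio = 1) on a
100-point log-spaced grid down to 0.01·λ_max. The penalty is chosen to
minimize the mean Verweij–van Houwelingen cross-validated deviance
−2·[ll_all(β_k) − ll_train(β_k)] over 10 folds, stratified by event status
when the rarer class has at least `folds` members (plain shuffled folds
otherwise — stratification is impossible below that). The partial
likelihood uses the Breslow tie convention; simulated event times are
continuous, so ties are measure-zero. This λ choice was cross-checked
against R's `cv.glmnet` during development and agrees closely.

The events-per-variable rule (selected ≥ events/10 → warn) warns rather
than blocks: published practice routinely violates a strict reading, and
the pipeline's job is to surface the issue, not to halt.

Stability analysis repeats the full discovery chain (re-normalization
included) on the training halves of `n_splits` random 1:1
event-stratified cohort splits and reports per-feature selection
frequencies.

## Survival evaluation

The signature is the linear predictor of an unpenalized Cox fit
(lifelines) on the selected features; the dichotomization cutoff is the
training-median score, ties to the low group, higher score = higher
hazard. Evaluation per cohort:

- Kaplan–Meier curves with at-risk counts; the median is the earliest
  time with S ≤ 0.5, flagged undefined when never reached.
- G-rho weighted log-rank (own implementation): weights S̃(t−)^ρ with S̃
  the left-continuous pooled KM; ρ = 0 is the standard log-rank, ρ = 1
  the Peto–Peto weighting used throughout (default). Verified against
  R `survival::survdiff` at both ρ values on a frozen fixture and against
  lifelines at ρ = 0; type-I error calibration is an acceptance test.
- Harrell's C-index via scikit-survival, 95% CI by seeded percentile
  bootstrap over patients (2000 replicates by default).
- Time-dependent AUC: IPCW cumulative/dynamic estimator at a 183-day
  horizon (6 months); without censoring it reduces exactly to the
  rank-sum AUC (tested).
- Hazard-ratio table: univariate Cox per factor with likelihood-ratio
  p-values; non-convergent factors are flagged without aborting.
- Clinical model: covariates passing a univariate Cox screen at p < 0.05
  on the training half; combined model adds the signature. Degenerate
  (no covariate passes) is reported as an empty clinical model.
- Baseline comparability: Pearson chi-square without continuity
  correction on 2×k tables; age dichotomized at the pooled median.

## Pipeline and reproducibility

One YAML config drives all stages; flags override config. Every JSON
output embeds the resolved-config SHA-256 hash (first 16 hex digits) and
the seed; re-running a stage with the same config and seed rewrites
byte-identical artifacts (logs, which carry timestamps, are excluded).
Exit codes: 0 success, 2 validation error, 3 missing upstream artifact.

## Analysis scale

The demo analysis simulates 63 + 105 patients at the default 64³ grid.
The end-to-end recovery suite runs 20 replicates of n = 200 cohorts
(split 100/100) with phantoms on a 40³ grid and semi-axes 11 × 9 × 7.5 mm
(≈ 2 cm tumors — clinically realistic and ≈ 2.5× faster to extract than
the default geometry), plus 20 null cohorts of n = 60 scored by the
matching replicate's signature. Texture-oracle checks run on 200 random
≤ 6³ VOIs; log-rank calibration uses 2000 null simulations at n = 60.

## Known limitations

- Feature composition, Ng, wavelet family and direction aggregation are
  defensible defaults, not a certified standard (no IBSI certification).
- Gray-level size-zone/dependence matrices and LoG channels are out of
  scope.
- The exponential (constant-hazard) survival model and uniform
  administrative censoring are deliberately simple; real PFS data show
  non-constant hazards and informative censoring the pipeline's
  statistics would still handle, but the generator does not produce.
- The C-index bootstrap CI is percentile-based; no asymptotic variant is
  offered.
- Competing risks, overall survival and nomograms are out of scope.
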