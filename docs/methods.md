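# Methods

This note documents the models implemented in `deltarad`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Image preprocessing

Four variants are applied before texture/intensity extraction; shape is
always computed from the raw contour.

| variant | steps |
|---|---|
| `raw` | HU-window thresholding only |
| `smooth` | thresholding + 2D Butterworth low-pass |
| `resample8` | thresholding + 8-bit dynamic-range quantization |
| `smooth_resample8` | thresholding + Butterworth + 8-bit quantization |

**Thresholding** restricts the ROI *mask* to voxels in [−100, 200] HU
(inclusive); image values are never clipped, so smoothing sees true
neighborhood intensities. Thresholding always runs first and uses the
original HU values.

**Butterworth smoothing** multiplies each axial slice's 2D DFT by
H(f) = 1/√(1 + (f/f_c)^(2·order)) with order 2. The cutoff of 125 is
interpreted as an index on a 512-sample DFT axis (the reconstruction
matrix), i.e. f_c = 125/256 of Nyquist; the filter's units are not
standardized across implementations, so this convention is fixed here and
verified by a direct frequency-domain oracle in the tests. Filtering is 2D
per slice because the 2.5 mm slice spacing makes an isotropic 3D filter
ill-defined against the ~1 mm in-plane grid. DC gain is exactly 1 (slice
means are preserved).

**Bit-depth resampling** maps the 12-bit CT range [−1024, 3071] HU linearly
onto 2^bits levels: level = ⌊(HU + 1024)/bin_width⌋, bin width 4096/2^bits
(16 HU at the default 8 bits), clamped to [0, 255].

**Gray tones for texture.** Resampled variants use their native levels,
shifted so the level containing −100 HU is tone 1 (20 tones across the
window). Un-resampled variants are binned into 16-HU-wide bins over
[−100, 200] (19 tones) — the same bin width, so that tone transitions
reflect tissue-density differences rather than 1-HU noise.

## Feature registry

65 features: 16 shape, 11 intensity-histogram, 22 GLCM, 5 NGTDM, 11 RLM.
The registry follows the canonical Haralick (co-occurrence), Amadasun–King
(NGTDM) and Galloway/Chu (run-length) sets at exactly these counts; the
identities guaranteed by construction and exercised throughout are
compactness2, RLM gray-level non-uniformity and NGTDM texture strength.

* **Texture matrices** are built in 3D over the 13 unique distance-1
  directions, accumulated into a single matrix (not averaged per direction),
  with both voxels of a pair required to lie in the mask. GLCM counts are
  symmetric; RLM runs break at the mask boundary; the NGTDM neighborhood is
  the 26-connected in-mask neighborhood, and voxels without any in-mask
  neighbor are excluded from the normalization count.
* **NGTDM conventions**: ε = 10⁻⁶ guards all denominators — a flat region
  saturates coarseness at 1/ε and has strength 0 (zero numerator). Strength
  is implemented as [Σᵢⱼ pᵢpⱼ(i−j)²]/(ε + Σᵢ sᵢ); contrast/busyness/
  complexity follow Amadasun–King with single-tone regions defined as 0.
* **RLM run percentage** uses Σ l·r(g,l) (total voxel traversals) as the
  denominator so the value stays in (0, 1] under 13-direction accumulation.
* **Shape** is computed from the clinical contour without HU thresholding
  (the contour describes the gross tumor boundary; intensity exclusion
  would punch holes in it). Surface area comes from a marching-cubes
  isosurface with 50 iterations of Taubin (shape-preserving) mesh smoothing:
  the raw binary-mask mesh overestimates digitized-sphere area by ~9%,
  which would bias compactness2 = 36πV²/A³ down to ≈ 0.76 for a true ball;
  the smoothed mesh is accurate to <1% for balls of radius ≥10 voxels.
  Sharp axis-aligned boxes are outside this estimator's target geometry
  (edges are beveled; the digital cube reads ≈ 0.73 vs the π/6 ≈ 0.524
  closed form). Principal axes are 4√λ of the physical-coordinate
  covariance eigenvalues; elongation/flatness are √(λ₂/λ₁), √(λ₃/λ₁).

## Preprocessing selection

For every (feature, variant) pair on pretreatment data: a univariate Cox
model for overall survival on the z-scored feature (likelihood-ratio test
against the null model — the "better fit than null" reading; no multiplicity
correction, since these p-values steer selection rather than test
hypotheses), a two-sided Wilcoxon rank-sum test between the two scanner
groups on first-week values (exact for combined n ≤ 20, normal approximation
with tie correction otherwise), and Spearman correlation with tumor volume.
A variant survives if Cox p < 0.10 and scanner p > 0.05; among survivors the
smallest |ρ| wins (absolute value — a strongly negative volume correlation
is just as much a volume surrogate), ties broken by the fixed variant order
raw → smooth → resample8 → smooth_resample8. Features with no surviving
variant are dropped.

## Delta-radiomics stage

The dose-response screen fits, per feature,

    F_iw = β₀ + β₁·D_iw + b_i + ε_iw,   b_i ~ N(0, τ²), ε ~ N(0, σ²)

by maximum likelihood (statsmodels MixedLM; ML rather than REML because the
likelihood-ratio test compares fixed-effects structures) against the nested
model without the dose term; p from χ²₁. A boundary fit (τ² = 0) is a valid
ML solution and is used as-is. P-values are Benjamini–Hochberg corrected
across features.

Delta features per patient: relativeNetChange (week 1 = first *weekly*
scan, distinct from the pretreatment scan, whose values carry the `_Week0`
suffix), the OLS slope of the feature on cumulative dose in Gy (dose, not
week index, for consistency with the mixed-model covariate), and the
last-week value. Missing weeks are simply absent from the slope fit; a zero
week-1 value flags the net change missing, fewer than two weeks flags the
slope. One-sample two-tailed t-tests on the net changes and slopes
(BH-corrected within each family) complete the stage: a feature passes only
if the mixed-model LRT and both t-tests are BH-significant at 0.05.

## Survival modeling

Landmark analysis: time = outcome day − entry day − 90; patients with any
endpoint event on or before the landmark are excluded upstream (exclusion
order: ROI volume < 5 cm³ strictly, then protocol, then early event — the
order is fixed for reproducible tallies).

Cox models use the Breslow tie convention and are fitted by an in-package
vectorized Newton–Raphson solver (step halving; coefficients |β| > 15 on
standardized covariates are flagged as monotone-likelihood divergence and
the move skipped). The solver is cross-checked against lifelines to 10⁻⁶ on
tie-free data, where Breslow and Efron coincide; it exists because the
nested search below refits ~10⁴ models per cohort. AIC = −2 logL + 2k with
the partial likelihood and k = number of estimated coefficients.

The nested search: per left-out patient, level 1 runs bidirectional
stepwise AIC over the clinical factors starting from the full model;
level 2 adds the pretreatment features with level 1's selections forced
(never droppable); level 3 adds the delta features with level 2's model
forced. Equal-AIC ties prefer drops over adds, then candidate order —
the search is fully deterministic. Covariates selected in strictly more
than half of the LOOCV iterations are retained; final models are refit on
all patients, keeping nesting by construction, and compared by
likelihood-ratio tests (df = coefficient difference; identical covariate
sets are reported as non-comparable). A second LOOCV with frozen covariate
sets refits coefficients only and emits each left-out patient's linear
predictor; these unbiased risk scores feed Harrell's c-index (higher score
= earlier event; ties count ½) and a median split (strictly above the
median = high risk, ties low) evaluated by Kaplan–Meier curves and the
two-group log-rank test.

## Synthetic cohorts

The generator emulates the study conditions rather than any particular
patient: clinical factors from the published cohort's marginal frequencies
(n = 107 stage-III patients), 66/74 Gy prescriptions at 10 Gy per treatment
week, a pretreatment scan plus 7 weekly scans (5% of interior weekly scans
missing), two scanners with a +20 HU offset and extra noise on scanner B,
and per-patient latent variables: an ellipsoid geometry (lognormal volume,
median 30 cm³; uniform axis ratios) whose analytic compactness2 is the
planted *shape* covariate, and a Gamma(4, ¼) latent *response* score
(mean 1, strictly positive — a zero score yields zero evolution).

Outcomes follow a Weibull proportional-hazards model (shape 1.5; medians
638/900/2000 days for OS/DM/LR at zero log-hazard). The increasing hazard
keeps pre-landmark events near 3%, matching a cohort in which early deaths
are rare; a constant hazard would have put ~17% of events before the
landmark and distorted every downstream sample size. Log-hazards: OS gets
the shape coefficient (0.8 per SD of compactness2) plus the delta
coefficient (0.8 per SD of the response score) plus modest fixed clinical
effects; DM gets the shape and clinical terms only; LR the delta term only.
Censoring is an independent same-shape Weibull calibrated to the configured
rate (default 20%) with a 120-day minimum follow-up.

Image series: a 64³ grid at 2.5/1/1 mm spacing; the tumor is the patient's
ellipsoid filled with a spatially correlated Gaussian texture
(mean 40 HU, SD 35 HU, correlation length 1.5 voxels, clipped to
[−50, 150] HU) in a −800 HU lung background; per weekly scan the ellipsoid
scale shrinks as exp(−0.006·score·dose/3) per axis and the texture SD decays
as exp(−0.008·score·dose), both from the same frozen texture field, plus
fresh 4 HU acquisition noise. Masks are concentric, hence nested — voxel
counts are non-increasing by construction.

For replicate-level statistical studies a table-level emulator generates
the pretreatment and longitudinal feature tables directly from the same
latent variables (linear dose trends proportional to the response score,
patient random intercepts, weekly noise; one deliberately static feature as
a negative control), reproducing the modeling pipeline's inputs at a small
fraction of the voxel path's cost. What the generator does **not** emulate:
real anatomy and contouring variability, respiratory motion, scanner
reconstruction kernels, non-ellipsoidal growth patterns, informative
censoring, or correlations between clinical factors and imaging phenotype.
Passing recovery tests therefore demonstrates that the pipeline's
statistics behave as designed under its assumed data-generating model — not
that the same effect sizes would be found in patients.

## Problem sizes and numerics

Recovery studies use 25 replicate cohorts of 60 patients (≈54 after
exclusions) in table mode; the mixed-model calibration uses 500 null
replicates of 30 patients × 7 weeks; the voxel-level end-to-end run uses 16
patients × 6 scans. The Newton–Raphson Cox solver iterates to a 10⁻⁹
step/log-likelihood tolerance with warm starts along stepwise moves; the
mixed model relies on statsmodels' default ML optimizer. All randomness
flows from a single seed through `numpy.random.SeedSequence` substreams
(per stage and per patient), so cohorts, images and whole pipeline runs are
bit-reproducible.

## Known limitations

* The 22 GLCM and 16 shape feature identities are the canonical sets at the
  registry's fixed counts; other radiomics software may name or normalize
  individual features differently.
* The mesh surface-area estimator targets blob-like tumors; sharp
  axis-aligned geometry is beveled (see above).
* Stepwise AIC inside LOOCV shares almost all data across iterations, so a
  noise covariate that wins on the full cohort is typically selected in
  nearly every iteration. In null simulations any given noise covariate
  becomes "high-performing" in roughly 30% of cohorts — full-model-start
  bidirectional stepwise retains noise about twice as readily as the
  forward χ²₁ > 2 admission rate of ~16% — so the >50% retention rule
  distinguishes structure that recurs *across* cohorts, not within-cohort
  luck. This is a property of the procedure being implemented, visible in
  the package's null-cohort studies (`deltarad.study.null_study`).
* The scanner screen assumes exactly two scanner groups; more requires a
  different test.
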