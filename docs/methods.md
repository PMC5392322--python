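# Methods

## Image model and stain separation

A section image is an H×W×3 array of 8-bit RGB intensities with a
physical calibration in microns per pixel. The calibration is the unit
converter for all area arithmetic and must be explicit: a supplied
argument overrides TIFF resolution metadata, and an image with neither
is rejected rather than guessed at.

Under the Beer–Lambert law, per-channel optical density is linear in
stain concentration. We use OD_c = −log10((I_c + 1)/255); the +1 offset
keeps the transform finite at zero intensity at the cost of a negligible
bias (≤ 1.7×10⁻³ OD at full intensity, clipped to zero). Pixels are
unmixed with the Ruifrok–Johnstone H-DAB optical-density matrix
(hematoxylin, DAB, residual as the unit cross product), the de-facto
standard for DAB IHC; the matrix is user-overridable since real scanners
and stains drift from the published vectors.

Segmentation runs at a reduced analysis magnification: the RGB image is
block-mean downsampled by an integer `analysis_scale_factor` (default 4,
i.e. a 20× scan analyzed at 5×), which multiplies the pixel calibration
by the same factor. Averaging is done on intensities (what a lower-power
objective sees), then transformed to OD. The DAB concentration is
compared inclusively against `dab_od_threshold` (default 0.15 OD). The
original protocol set this threshold visually per batch in vendor
software; a fixed configurable OD threshold is a declared stand-in for
that semi-automated step — the vendor's "contrast difference" semantics
are not recoverable, and OD thresholding is the closest physically
grounded operation. Ragged edge blocks average their own pixels only;
the ROI mask is downsampled by block majority (> 0.5).

## Region-of-interest handling

ROIs are GeoJSON FeatureCollections of polygons in pixel coordinates
with a `role` of `include` (tumor) or `exclude` (necrosis, salivary
glands); a missing role defaults to include. Rasterization uses the
pixel-center rule: a pixel belongs to the mask when its center lies
strictly inside the include union and not inside the exclude union.
Centers exactly on a polygon boundary count as outside, which makes
rasterization deterministic; for ROI polygons drawn at sub-pixel
precision the boundary set has measure zero.

## Bud classification

Connected components of the stained mask use 8-connectivity, matching
the full-connectivity default of commercial labeling tools and keeping
diagonally touching cells in one region. Region area is pixel count ×
calibration². Two fixed thresholds define the score:

* **artifact floor** 150 µm² — regions strictly below it are removed
  (a region of exactly 150 µm² is retained);
* **bud ceiling** n_cells × 190 µm² — remaining regions strictly below
  it are buds. 190 µm² is the nominal cross-section of a single OSCC
  tumor cell; the default of 5 cells gives 950 µm².

Strict inequality at the ceiling is the adopted reading (a 950 µm²
region is not a bud); `BudParams.inclusive_ceiling` switches to ≤ for
sensitivity analyses, since the original software's convention at the
exact boundary is unknowable. No hole-filling or morphological cleanup
is applied beyond the two area filters. The bud-definition sweep
re-counts each patient's region table under cumulative ceilings
n = 1…20; counts are non-decreasing in n by construction.

## Phantom generator

Phantoms render islands (discs, ellipses, wobbled-radius blobs) of
target µm² area onto a white or faintly hematoxylin-tinted canvas by the
exact inverse of the segmentation optics: each stained pixel receives
OD = concentration × DAB vector and intensity 255·10^(−OD) − 1, so a
noiseless phantom of concentration c deconvolves back to c up to 8-bit
rounding. Footprint scale is tuned so the achieved pixel count is
closest to the target (within 5% for islands of ≥ 50 px); ground truth
records achieved, not target, areas and is therefore exact. Islands are
placed by rejection sampling with a 2-pixel dilated separation guard, so
8-connected labeling can never merge two islands and the constructed bud
count is the pipeline's correct answer at scale factor 1. Block
downsampling re-rasterizes areas, so truth-equality holds exactly only
at factor 1 with zero noise; at factor 4 counts agree approximately
(areas shift by anti-aliasing). Phantoms do not attempt photorealism:
no stromal texture, no stain gradients, no out-of-focus blur — passing
tests demonstrate correctness of the measurement chain, not robustness
to stain variation across real scanners.

## Cohort generator

The simulated cohort mimics a 222-patient early-stage OSCC series:
right-skewed bud counts (negative binomial, mean 600, dispersion 1.2 —
most patients between 0 and 1000 buds per section), lognormal invasive
depth with median 4 mm (about half the cohort deeper than 4 mm), age
N(64, 12²), 57% male, 34% node-positive at the default intercept, and
the categorical mixes (grade, subsite, invasive front, perineural
invasion, smoking) at the frequencies typical of such a series. Nodal
status is Bernoulli(logistic(linear predictor)); survival is exponential
with rate baseline × exp(linear hazard predictor) under uniform
administrative censoring over 8 years — the simplest generator exactly
compatible with the proportional-hazards and logistic models fitted
downstream, chosen so that recovery tests have a well-defined truth.
Default baseline rates (0.08/yr OS, 0.055/yr PFS) give event fractions
of roughly a third, similar to the target setting. Real survival data
violate these conveniences (non-exponential baselines, informative
censoring); the generator shows estimator correctness under the model,
not robustness to misspecification.

`cohort_with_target_auc` draws scores N(0,1) for negatives and N(δ,1)
for positives with δ = √2·Φ⁻¹(AUC), so the Bayes-optimal AUC equals the
target exactly (binormal identity); the implied logistic slope on the
score is δ.

## Risk model and evaluation

Logistic fits are maximum likelihood via IRLS with covariance from the
inverse observed information. Complete separation is detected (collapsed
fitted probabilities with runaway coefficients) and reported as an error
naming the most implicated variable. Forward selection adds, at each
step, the candidate with the smallest likelihood-ratio p-value when
below the entry threshold (default 0.05), with deterministic tie-break
in candidate order. The final variable set is configuration-driven —
candidates default to the standard clinicopathological panel — because a
fixed published set is not available to hard-code.

AUC is the Mann–Whitney statistic with ties counted ½; confidence
intervals use DeLong's structural-component variance with a normal
approximation truncated to [0, 1]. Cross-validation uses stratified
k-fold splits from a single integer seed; forward selection, when
requested, is re-run inside every training fold, and the AUC is computed
on pooled out-of-fold predictions rather than averaged per fold — more
stable at a few hundred patients with 10 folds.

The Hosmer–Lemeshow statistic bins by deciles of predicted risk
(quantile bins, ties kept together) and refers Σ(O−E)²/(E(1−E/n_b)) to
χ² with g−2 degrees of freedom. That reference distribution is the one
appropriate for probabilities fitted by maximum likelihood; applying the
test to externally supplied "true" probabilities inflates the statistic
toward χ²_g. If tie-merging collapses bins, the degrees of freedom
shrink accordingly (floored at 1, with a warning). Calibration tables
use quantile bins with exact Clopper–Pearson binomial intervals.

## Decision curves

Net benefit follows the standard decision-curve definition,
NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t), treating a patient when the
predicted probability is ≥ p_t (inclusive, the common convention).
Treat-all has NB = prevalence − (1−prevalence)·p_t/(1−p_t) and treat-none
zero; net reduction vs treat-all is (NB_model − NB_all)·(1−p_t)/p_t·100
per 100 patients. The default grid is 1–50% in 1% steps, the clinically
relevant range for the neck-dissection decision. Whether curves are fed
apparent or cross-validated probabilities is the caller's choice — both
are supported since either convention appears in practice.

## Survival analysis

Tertiles cut at the 33⅓ and 66⅔ linear-interpolation percentiles with
the lower boundary inclusive upward; ties always share a tertile.
Kaplan–Meier estimation, log-rank tests and Cox partial-likelihood
maximization (Newton–Raphson, Efron tie handling, Wald intervals) are
delegated to lifelines. Only Efron tie handling is offered: it is more
accurate than Breslow under ties, and the `ties` argument exists to make
the choice explicit rather than to multiply fitters.

"Conditional forward elimination" is realized as forward entry by
smallest LR p-value (< 0.05) followed, after each entry, by LR re-tests
of every included variable with removal at p > 0.10, iterated to a fixed
point — a documented, testable approximation of the SPSS stepwise mode
of that name; exact vendor internals are not reproduced. The null
partial log-likelihood for first-step LR tests is obtained from a fitted
model's likelihood-ratio test statistic.

The bud-size sweep fits, for each ceiling n, a Cox model with the
tertiled count as an ordinal covariate (hazard ratio per tertile
increment — the coding used for the multivariate models as well) and
summarizes log HR against n by least squares. Cumulative ceilings, not
disjoint size bins, are used: the sweep asks "what if a bud were defined
as up to n cells", which is the operational question. Ceilings whose
counts cannot form tertiles (e.g. more than a third of patients at zero)
are flagged and skipped with a warning.

## Numerical and testing choices

All simulations flow through `numpy.random.default_rng` seeded per spec;
identical inputs give bit-identical outputs, including rendered phantom
pixels. Test problem sizes are chosen as the smallest at which the
checked property is decisively measurable: 100-phantom oracle
equivalence at 320² px, coefficient recovery at n = 50 000 (logistic),
10 000 (Cox) and 5 000 (cross-validated AUC), and 1000-replicate null
calibration for the Hosmer–Lemeshow and log-rank tests. Dual-route
verification is kept throughout: the labeling/counting pipeline is
checked against a pure-Python flood-fill recount, the rank-based AUC
against brute-force pair counting and scikit-learn, and Efron Cox
estimates against a grid-maximized hand-written partial likelihood.

## Known limitations

* The OD threshold replaces a visual per-batch tuning step; absolute
  DTBC values depend on it and on scanner color response, so
  cross-scanner use requires recalibration.
* Areas are measured at analysis resolution; very thin strands can
  fragment or vanish under block downsampling.
* Whole-slide pyramid formats (NDPI/SVS/CZI) are out of scope; inputs
  are flat TIFF/PNG tiles with explicit calibration.
* The clinical-layer estimates are only as good as the cohort table;
  no imputation is provided, and categorical covariates must be
  dummy-coded by the caller.
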