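# Methods

This package implements a whole-brain tumor-burden detection analysis for
multimodal small-animal imaging: in vivo gadolinium-enhanced T1w MRI, T2w
MRI and amino acid PET segmentations are scored voxel-wise against an
ex vivo fluorescence ground truth (a tdTomato tumor-cell marker imaged in
optically cleared brain slices), subgroups are compared with exact
nonparametric tests, and PET uptake is regressed against biologic
correlates.  This note records the models, conventions and numerical
choices, what the synthetic test bed does and does not emulate, and the
known limitations.

## Geometry and resampling

All volumes live on axis-aligned lattices described by `GridGeometry`
(shape, spacing in mm, origin = world position of the *center* of voxel
(0,0,0)).  Distances are always computed in world millimetres so that
anisotropic grids — an MRI-class 0.2 × 0.2 × 0.5 mm grid versus the PET
0.5 × 0.5 × 1 mm grid — are handled without index-space shortcuts.
Oblique (rotated) NIfTI affines are rejected at the I/O boundary; rotation
must be resolved by the registration module first, which keeps every metric
contract exact on its lattice.

Two resampling primitives cover the analysis' needs:

* `upsample_nearest` — each target voxel takes the value of the source
  voxel with the nearest center (separable per axis).  Masks are only ever
  resampled this way: interpolation would create fractional labels and make
  sensitivity/specificity counts ill-defined.  Nearest-neighbor assignment
  at mask boundaries is a genuine convention choice; it perturbs counts by
  at most the boundary-shell fraction, which a dedicated test bounds.
* `downsample_block_mean` — block averaging onto an integer-multiple
  coarser grid (used to bring fluorescence to the PET voxel size).
  Trailing partial blocks average only the voxels present.

## Registration

Both registration problems are solved from landmark correspondences by
ordinary least squares: a 3-D affine (in vivo → ex vivo frame) and a
per-slice 2-D affine (cleared optical slices → ex vivo MRI slice planes;
full 6-dof affines because tissue slices deform anisotropically during
clearing).  With d+1 non-degenerate pairs the fit interpolates exactly;
degenerate configurations raise an error naming the deficient direction.
Resampling pulls each target voxel center back through the inverse
transform; out-of-field samples are zero, matching the convention that
everything outside the brain is removed.  The pipeline equally accepts
volumes that were already co-registered upstream.

## Segmentation and metrics

Tumors are segmented by a per-tumor intensity threshold (inclusive `>=`,
so a noiseless image whose tumor voxels sit exactly at the generative
cutoff reproduces the truth mask exactly) with an optional exclusion mask
for regions that are clearly not tumor.  Per-modality masks combine by
voxelwise union (T1+T2 → "MRI", MRI+PET), and an expanded MRI segmentation
dilates the MRI mask by a metric radius (default 2 mm) via an anisotropic
Euclidean distance transform — 2 mm means millimetres on any grid, not two
voxels.  On a discrete lattice, chained expansions satisfy
expand(r1)∘expand(r2) ⊆ expand(r1+r2) (triangle inequality on voxel
centers); the reverse containment holds only in continuous space, because
an intermediate voxel center need not exist.

Scores per tumor and modality, computed on the fine (tdTomato) grid after
nearest-neighbor upsampling of the in vivo masks (the scoring grid is a
parameter so grid sensitivity can be audited):

* sensitivity = |detection ∩ truth| / |truth|;
* specificity = (|brain| − |(detection ∪ truth) ∩ brain|) / (|brain| − |truth|),
  with detection voxels outside the brain region ignored.  Expanded
  segmentations are additionally clipped to the brain region for the volume
  report; the unclipped volume is kept alongside;
* Dice = 2|A∩B| / (|A|+|B|);
* maximum surface distance — surfaces are the true voxels with at least one
  false 6-neighbor (volume faces count as boundary); for every surface
  voxel of each mask, the minimum world-mm distance to the other surface;
  the reported value is the maximum over both directions (a symmetric,
  worst-case Hausdorff distance).  Undefined ("nd") when a mask is empty,
  i.e. the tumor was entirely undetected; such entries are excluded from
  distance medians.  Surface distances are 3-D, across the slice axis.

An empty detection yields sensitivity 0, Dice 0, specificity 1 and "nd"
distance by construction — the pattern non-enhancing tumors show on T1w.
Raw precision is kept internally; the reporting layer rounds half-up to
2 decimals (volumes to integer mm³, distances to 0.1 mm).

## Group statistics

Subgroups follow the study design: gadolinium-enhancing (Gd+),
non-enhancing (Gd−), and Gd− split by PET visibility.  Summaries are
median (min, max).  Comparisons use exact Wilcoxon tests, appropriate at
n = 13:

* paired modality contrasts on the same tumors: exact signed-rank test,
  zero differences discarded (the classical convention), midranks for tied
  absolute differences;
* unpaired Gd+ vs Gd− contrasts: exact rank-sum test with midranks.

Both exact null distributions are built by dynamic programming over doubled
(hence integer) midranks — all 2^m sign assignments, respectively all
C(n1+n2, n1) group assignments — and the two-sided p is
2·min(P(W ≤ w), P(W ≥ w)), capped at 1.  SciPy's exact modes decline data
with ties or zeros, which this cohort has, so the enumeration is
implemented here and cross-checked in the tests against brute-force
enumeration and closed forms (all-positive differences give p = 2·2^−m).
No multiple-testing correction is applied, matching the source analysis.
With every difference zero the test is degenerate: p = 1 with a warning.
p-values are reported to 1 significant figure at or below 0.01, else 2
decimals.

The packaged 13-tumor score table carries a known internal inconsistency:
five cells of its printed overall-median row (optical volume 95 vs 86 mm³,
MRI+PET sensitivity 0.87 vs 0.86, among others) disagree with the medians
of its own 13 rows.  The pipeline recomputes, flags each disagreement in a
log and a report file, and treats the recomputed value as canonical.
Near-degenerate contrasts are also sensitive to test convention: the
mixed-sign PET-vs-MRI sensitivity contrast gives two-sided p = 0.83 under
this exact convention, while approximations or different two-sided rules
give values near 0.85.

## PET correlates

Tumor-level records summarize PET by the maximum over the tumor mask and
each fluorescence channel (tdTomato cell marker, ASCT2 transporter stain,
lectin vascular stain) by the mean, every value divided by the mean over a
contralateral normal-brain mask — a dimensionless ratio invariant to global
scale.  Voxel-level records repeat this on the PET grid after block-mean
downsampling of fluorescence.  Continuous variables are natural-log
transformed and z-scored (n−1 denominator); the binary enhancement status
is z-scored but not logged (log 0 is undefined; the convention is recorded
here as an assumption).  By default the response is standardized as well; a
switch (`standardize_response=False`) keeps the response on the log scale,
since the upstream convention is not documented.

Fits are ordinary least squares (statsmodels), with coefficient p-values
from the t distribution on n−k−1 df.  Tumors without a lectin measurement
are handled by dual reporting: the full model on complete cases and a
lectin-free model on all cases (the full model is skipped, with a logged
note, when complete cases do not exceed the regressor count).  The
voxel-level model ignores within-tumor correlation (plain OLS).
Added-variable (partial-regression) plots regress the response and the
regressor of interest on all remaining regressors; the slope of the
y-residuals on the x-residuals equals the multivariate coefficient
(Frisch–Waugh–Lovell), verified to 1e-10 in the tests.

## The synthetic phantom

The generator produces co-registered multimodal cases with the statistical
structure the analysis assumes, on a 0.25 × 0.25 × 0.5 mm fine grid (so the
0.5 × 0.5 × 1 mm PET grid is an exact 2×2×2 block of fine voxels) inside an
ellipsoidal brain:

* ground truth: a solid spherical core plus an infiltrated margin — a
  smoothed random field thresholded to fill half the shell by default, with
  cell density ramping down from 1 to a floor of 0.3;
* tdTomato = background + amplitude·density (+ noise): thresholding the
  noiseless channel at its generative cutoff recovers the truth exactly;
* T1w shows an enhancing core only in Gd+ cases; T2w detects the densest
  `t2_detect_fraction` of the tumor (diffuse infiltration goes undetected);
* PET = background · (1 + contrast·density), contrast scaling with
  cellularity, boosted 1.3× by enhancement and zero for the PET-invisible
  stratum, blurred by a separable Gaussian PSF (FWHM 1.5 mm by default,
  σ = FWHM/2.355 per axis) and block-averaged onto the PET grid.
  Partial-volume overshoot of the tumor boundary arises naturally: a wider
  PSF strictly increases PET-segmented volume at fixed threshold and weakly
  decreases specificity;
* ASCT2 and lectin are linear functions of cell density with independent
  per-case amplitude jitter (lognormal, σ 0.35), so the biologic channels
  correlate with density without being collinear copies of one another —
  without the jitter the regression design is nearly rank-deficient and
  coefficient signs are unstable;
* the contralateral normal mask is the tumor's mirror across the
  mid-sagittal plane, minus a 2-mm expanded tumor neighborhood — the
  default tumor crosses the midline, and without the guard margin
  partial-volume PET signal leaks into the normalization denominator.

`generate_cohort` reproduces the study composition — 4 Gd+, 5 Gd−
PET-visible, 4 Gd− PET-invisible, with the invisible stratum more
infiltrative and less cellular, and 2 of 13 cases lacking lectin — from a
single master seed (per-case seeds derived via one generator; no global
random state).  `simulate_regression_table` draws tumor-level tables
directly from a standardized log-linear model with stated effect sizes
(tdTomato 1.2, ASCT2 0.3, lectin 0.15, volume 0.2, enhancement 0.4; noise
σ 0.3; the Gd+ count fixed at round(4n/13) so the design is never
degenerate), for the 200-replicate coefficient-recovery experiment.

What the phantom does **not** emulate: the true optical in-plane resolution
(tens of microns — the analysis contracts depend on grid ratios, not
absolute scale), MR relaxometry, PET count statistics and iterative
reconstruction, tumor-induced edema, and fluorescence loss in tumor cells.
Passing tests therefore demonstrate the correctness and the qualitative
behavior of the analysis machinery (ordering properties, exact statistics,
recovery under known transforms), not scanner-level realism.  The
infiltration-density profile is a free knob, not a calibrated claim.
Consequently, image-derived published values that depend on the original
scans — the regression fit R² = 0.77 and its per-regressor coefficients,
and the per-tumor metric rows — are out of reach by design; the pipeline
reproduces their qualitative structure (tdTomato as the dominant
standardized coefficient on a cell-density-driven cohort) and every summary
number that is derivable from the published per-tumor table.

## Numerical choices and degenerate inputs

* Threshold comparison inclusive; mask resampling nearest-only; expansion
  tolerance 1e-9 mm so voxels at exactly the radius are included.
* Surface extraction by 6-connectivity face adjacency; KD-tree distances
  between voxel centers in world mm, cross-checked against an O(n²)
  all-pairs oracle.
* Least-squares affine via `lstsq`; rank checked at 1e-9 relative
  tolerance; |det| > 1e-12 required for invertibility.
* Empty masks: volume 0; "nd" distance; sensitivity 0 where truth is
  non-empty; metrics raise typed errors (`UndefinedMetricError`) for
  genuinely undefined cases (empty truth, brain = truth, both masks empty),
  and per-modality errors are recorded per row without aborting a case.
* Problem sizes: default phantom grid 64 × 64 × 24 fine voxels, cohort of
  13 cases; 200 replicates for the recovery experiment; exact-test
  enumeration limited to 25 observations (beyond which the DP tables grow
  needlessly — the cohort has 13).  A full test run and the acceptance
  recomputation each finish in well under a minute on a laptop-class core.

## Reports

Every pipeline TSV starts with a provenance comment (`# tumorburden
v<version> config=<sha256 prefix of the scientific configuration> seed=<n>`);
identical configuration and seed give byte-identical outputs.  Per-tumor
tables mirror the published layout ("nd" literal included); summaries,
exact-test comparisons, correlate records, model coefficients and
partial-regression point sets are separate TSVs.
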