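# Methods

## Volumetry

All geometry is computed in mm internally and reported in cm/cm³.  A
`SegmentationMask` is a 3D boolean array with per-axis spacing
(in-plane-x, in-plane-y, slice); any nonzero stored voxel is foreground.
Masks with several connected components are accepted (slice-wise contours
can disconnect) and flagged; features are computed on the union.

**RTV** is the foreground count times the voxel volume — unbiased for
smooth shapes (a digitized r=18.8 mm sphere at 0.5 mm spacing is within
0.05% of 4/3 πr³).

**Contraction and the surface-area surrogate.**  The 1-mm "universal
contraction" of the contour is a threshold on the physical distance from
each voxel center to the tumor surface.  Conventions that measure
distance between binary voxels cannot localize the surface better than a
fraction of a voxel, and that bias is material at 1-mm depth: on the
reference sphere at 0.5 mm spacing, distance-to-background-centers
under-erodes the shell by ~12%, and distance to the background voxels'
boxes over-erodes it by ~16%.  We therefore reconstruct the surface at
subvoxel accuracy as the 0.5-isosurface (marching cubes) of the binary
indicator smoothed with an isotropic Gaussian of σ = 1 × min(spacing) mm,
and take per-voxel distances as the minimum over the surface sample
points (exact KDTree queries).  With this estimator the shell volume and
compactness of digitized spheres at 0.5 mm spacing are within 0.5% of
their closed forms across radii 15–26 mm, and the 20-mm box contracts to
exactly its 18-mm interior.  Structures too thin for the smoothed field
to reach 0.5 (single voxels, one-voxel slabs) fall back to the unsmoothed
indicator, whose isosurface is the midpoint surface between foreground
and background centers.  A foreground voxel whose center falls outside
the reconstructed surface (possible at sharp corners) is treated as
already on the boundary (distance 0).

When contraction empties the mask, the shell volume equals RTV (the
formula's natural limit) and the result is flagged; compactness then
reduces to RTV^(−0.5).  At 5-mm slice spacing a 1-mm contraction removes
no whole through-plane voxel layer; this under-erosion is inherent to
voxelized geometry and is documented rather than silently corrected —
`extract_features(..., isotropize=True)` optionally resamples to
isotropic 1 mm (nearest neighbor) first, default off, because the
resampled geometry is then what is measured.

**Axes and derived volumes.**  The long axis is the 3D Feret diameter
between foreground voxel centers (convex-hull extreme points, brute
force fallback); the diameter is the per-slice in-plane Feret maximum.
These are mask-derived approximations of manual caliper reads.  CATV
assumes a cylinder, π(d/2)²L; TCTV = RTV/compactness, which is
algebraically SA_RTV^1.5 and is asserted to 1e-9 in the tests.  The
compactness formula exponentiates the shell *volume* as-is (no √π or
thickness normalizer); the dimensional oddity is the feature's published
form and is preserved.

## Synthetic data

**Phantoms.**  Spheres, ellipsoids, and spiky shapes — a sphere of radius
r augmented by `spike_count` radial cones of amplitude A and fixed
half-angle (20° default), directions drawn uniformly from a seeded
generator.  Spiky shapes with A=0 digitize identically to spheres.
Closed-form sphere features serve as the independent oracle for the grid
code.  Phantoms exercise the compact-vs-spiculated contrast; they do not
emulate imaging physics, rectal anatomy, or contouring ambiguity, so
geometric accuracy on phantoms bounds only the discretization error of
the volumetry, not clinical segmentation error.

**Reader simulation** perturbs the signed distance of the boundary by a
smooth Gaussian random field (3-mm correlation length, pointwise SD =
the requested boundary noise in mm), emulating contouring variability
for ICC studies.

**Cohorts.**  The default covariate mix copies the reference CCRT
population: nodal stages 31/55/36 per 122, cT 7/103/12, 92%
fluorouracil-based chemotherapy, the five stated fractionation schedules
(whose EQD2 values reproduce the <45 / 45–50 / >50 Gy strata at
16.4/32.8/50.8%), age ≈ N(60.5, 12) clipped to the observed range, 68%
male.  No distributional form for the volumetric features is published,
so we declare: RTV lognormal with median 27.75 cm³ and log-SD 0.75
(spanning the reported 3.85–289 cm³ range), compactness gamma(k=5,
θ=0.3936) with median 1.84, independent of RTV (the two are reported as
orthogonal); CATV is log-linear in RTV (slope +1) and compactness (slope
−0.5) plus lognormal noise (SD 0.35), pinned to median 71.14 cm³ —
reproducing the reported correlation signs.  Outcomes are Bernoulli with
logit P(pCR) = β·x; the default slopes are the logs of the published
multivariate odds ratios (−0.0346/cm³ for volume, +1.412 for
compactness) and ln 0.45 for nodal involvement (from the 15.4% vs 29.0%
response rates), with the intercept −2.972 calibrated numerically (2M
draws) so the marginal prevalence is the observed 18.9%.  Feature-level
simulation is the default for speed; `phantom_level=True` draws shapes
and runs the real volumetry instead.  A single seed per spec drives all
draws.

`reference_cohort_from_counts` is distinct from the simulator: it
deterministically rebuilds the 122-patient endpoint-by-nodal-status
table from published marginal counts, so summary proportions (18.9%
prevalence, 25.4% cN0) and the 2×2 nodal odds ratio (2.25) are exact
arithmetic, not estimates.

## Dose–response scoring

EQD2 uses the linear-quadratic conversion with α/β configurable
(default 10 Gy, the conventional tumor value — the choice matters only
away from 2 Gy/fraction).  The TRP model is a logistic in EQD2, a volume
covariate and binarized nodal status; its four coefficients ship with
*no* defaults — they are published model constants the user must supply
(YAML schema in `examples/trp_coefficients.example.yaml`) and a missing
coefficient raises a configuration error rather than scoring silently.
Because the volume coefficient is per cm³ of the definition the model
was fitted on, alternative volume definitions are first rescaled to the
reference definition's median (`normalize_to_reference_median`; median =
midpoint of the central order statistics for even n).  TRP is a monotone
transform of its linear predictor, so single-score AUCs are unchanged by
the transform when only the volume covariate varies — asserted in the
tests.

## Statistics

Logistic fits are Newton-scored maximum likelihood (statsmodels;
tolerance 1e-8, ≤50 iterations) with Wald standard errors from the
inverse observed information; odds ratios and 95% CIs are exponentiated
coefficients.  Complete or quasi-complete separation yields a
`converged=False` fit with NaN fields and a diagnostic, never silent
huge coefficients; rank-deficient designs raise.  The clinical tables
this mirrors label the quantity "HR", but with a binary endpoint and no
time axis it is an odds ratio, and is reported as such.  Nodal status is
coded cN+ = 1; because the published univariate table appears to use the
opposite coding, the univariate report also prints the reciprocal
(cN0 vs cN1–2) odds ratio.

VIF is 1/(1−R²) from intercepted auxiliary regressions; values in
[2.5, 10) are flagged `high`, ≥10 (or exact collinearity) `extreme`.
The analysis pipeline applies the screening rule: when both volume
measures (RTV, CATV) are flagged, the configured one (default CATV) is
dropped before the multivariate fit, and the VIF table is re-reported on
the retained set.

ROC uses the Mann–Whitney ½-tie convention (trapezoidal curve);
orientation `auto` flips a score whose association with the positive
class is negative and records the flip.  The DeLong comparison estimates
the paired AUC covariance from per-case placement values; z is the AUC
difference over its standard error with a two-sided normal p.  A zero
variance with zero difference returns p=1; with a nonzero difference it
raises as degenerate.  Single-AUC confidence intervals in reports use
the same placement-variance estimator.

ICC defaults to the two-way random-effects, absolute-agreement,
single-measure form (readers are a sample; systematic offsets should
count as disagreement), with the consistency form selectable; agreement
bands are <0.40 poor, 0.40–0.59 fair, 0.60–0.74 good, ≥0.75 excellent.
No multiple-testing correction is applied anywhere (matching the
analysis this reproduces); all tests are two-sided.

## Pipeline

`run_analysis` executes, in order: volumetry summary (medians/ranges,
prevalence, nodal mix), Pearson+Spearman correlations among
CATV/RTV/compactness, univariate logistic per predictor, the VIF screen,
the multivariate fit on the retained predictors, paired ROC of
RTV/CATV/TCTV, optionally the TRP-model-assisted ROC (RTV and TCTV
median-normalized to CATV), and optional subgroup reruns.  Rows with
missing model covariates are excluded listwise with a reported count.
Reports serialize to JSON and per-section CSVs; every CLI `analyze` run
writes a manifest with the config hash, seed and package versions.
End-to-end runs are deterministic given a seed.

## Problem sizes and checks

The test suite and acceptance script use: the r=18.8 mm sphere at 0.5 mm
spacing (~220k foreground voxels) for closed-form geometry checks (5%
tolerance, actual error <0.5%); ≤30³ blob/box masks for exact
brute-force contraction agreement; 200 replicates of n=2000 cohorts for
coefficient recovery (|bias| < 5%, Wald coverage in [0.92, 0.98]);
10,000 stratified bootstrap draws at n=30 for the DeLong variance check
(±15%); 1000 null replicates at n=60 for DeLong p-value uniformity
(KS < 0.05); and 20 seeded n=300 cohorts for the AUC-ordering claim
(TCTV > RTV in the majority; observed 20/20).  These sizes make the full
suite run in well under a minute of statistics plus a few seconds of
geometry per fine phantom.

## Known limitations

- Clinical AUC levels from any real cohort are not reproducible from
  synthetic data; only orderings and calibrated rates are checked.
- The volumetric feature distributions (lognormal/gamma) are declared,
  not estimated from data.
- Sub-voxel surface reconstruction assumes the contour is smooth at the
  scale of one voxel; at 5-mm slice spacing through-plane contraction
  remains coarse (see Volumetry).
- No DICOM-RT parsing, no intensity/texture radiomics, no survival
  endpoints.
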