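# tumorvol

Volumetry-based prediction of pathological complete response (pCR) for
locally advanced rectal cancer after preoperative chemoradiotherapy
(CCRT), built around **tumor compactness** — a 3D shape feature that
separates sphere-like from spiculated ("sea-urchin") tumors.

The package is aimed at imaging/radiation-oncology researchers who have
3D tumor segmentation masks (NIfTI/NRRD) plus a per-patient clinical
table, and want to reproduce or extend a compactness-corrected volumetry
analysis, or to validate such an analysis end to end on synthetic data.

## The features and the model

From a binary mask with voxel spacing, all on the cm / cm³ reporting
scale:

- **RTV** — real tumor volume: foreground voxels × voxel volume.
- **SA_RTV** — surface-area surrogate: the volume of the outermost 1-mm
  layer, obtained by uniform 3D contraction of the contour by 1 mm and
  volume subtraction.
- **Compactness** — `RTV / SA_RTV^1.5`; high for compact tumors, low for
  spiky ones.
- **CATV** — cylindrical approximated tumor volume `π (d/2)² L` from the
  maximal in-plane diameter `d` and 3D long axis `L` (Feret diameters).
- **TCTV** — compactness-corrected volume `RTV / compactness`
  (algebraically `SA_RTV^1.5`).

Dose–response scoring uses the linear-quadratic equivalent dose in 2-Gy
fractions, `EQD2 = D (d + α/β) / (2 + α/β)`, inside a logistic
tumor-response-probability model
`TRP = logistic(b0 + b1·EQD2 + b_ts·Y_vol + b_N·Y_N)` whose coefficients
are user-supplied configuration.  Statistics: Pearson/Spearman
correlation, VIF-screened univariate/multivariate logistic regression
(odds ratios with Wald 95% CIs), ROC with paired AUC comparison by the
DeLong test, and ICC(2,1) for inter-observer agreement.

## Worked example

```python
import tumorvol as tv

cohort = tv.simulate_cohort(tv.CohortSimSpec(n=300, seed=11))
report = tv.run_analysis(cohort)
for row in report.sections["roc_volumes"]["auc"]:
    print(row["score"], round(row["auc"], 3))
for row in report.sections["roc_volumes"]["pairwise"]:
    print(row["pair"], round(row["p"], 4))
```

prints

```
rtv 0.608
catv 0.672
tctv 0.748
rtv vs catv 0.0015
rtv vs tctv 0.0
catv vs tctv 0.0002
```

The simulated cohort has a negative volume effect and a positive
compactness effect on the outcome (independent of each other), so TCTV —
which combines both signals in one number — discriminates responders
better than RTV or CATV alone; the DeLong p-values quantify the paired
AUC differences on the same 300 patients.  The `examples/` directory has
narrative scripts for each capability (phantom volumetry, dose–response
scoring, the full cohort analysis, reader-agreement ICC), and the
`tumorvol` CLI exposes `features`, `simulate-shapes`, `simulate-cohort`,
`analyze` and `roc-compare` subcommands for shell use.

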