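"""Full statistical analysis on a simulated cohort with known ground truth.

Simulates 300 patients whose pCR outcome follows a logistic model with a
negative volume effect and a positive compactness effect, then runs the
complete report: summary, correlations, VIF-screened logistic regression,
and the paired ROC comparison of the three volume definitions.
"""

import tumorvol as tv

cohort = tv.simulate_cohort(tv.CohortSimSpec(n=300, seed=11))
coefs = tv.TRPCoefficients(b0=-10.0, b1=0.18, b_tumor_size=-0.015, b_n_stage=-0.7)
report = tv.run_analysis(
    cohort, tv.AnalysisConfig(model_assisted=True, trp_coefficients=coefs)
)

s = report.sections["volumetry_summary"]
print(f"n={s['n']}  pCR prevalence {s['pcr_prevalence_pct']}%  cN0 {s['cn0_pct']}%")

print("\nmultivariate logistic (after VIF screen dropped CATV):")
for row in report.sections["multivariate"]:
    print(f"  {row['predictor']:<12} OR {row['odds_ratio']:.3f} "
          f"({row['ci_lower']:.3f}-{row['ci_upper']:.3f})  p={row['p']:.4f}")

print("\nROC comparison of volume definitions:")
for row in report.sections["roc_volumes"]["auc"]:
    print(f"  {row['score']:<6} AUC {row['auc']:.3f} "
          f"({row['ci_lower']:.3f}-{row['ci_upper']:.3f})")
for row in report.sections["roc_volumes"]["pairwise"]:
    print(f"  {row['pair']:<14} dAUC {row['auc_difference']:+.4f}  p={row['p']:.4f}")

print("\nmodel-assisted (TRP) ROC comparison:")
for row in report.sections["roc_model_assisted"]["auc"]:
    print(f"  {row['score']:<9} AUC {row['auc']:.3f}")

# TCTV (= RTV / compactness) combines the two independent signals, so its
# AUC exceeds RTV's both raw and inside the dose-response model — the
# qualitative ordering the method is designed to demonstrate.
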