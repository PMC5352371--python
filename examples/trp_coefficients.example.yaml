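# Logistic dose-response (TRP) coefficient configuration — EXAMPLE ONLY.
#
# The package ships NO default coefficients: these four numbers are
# placeholders demonstrating the schema and plausible signs.  For a real
# analysis, substitute the values of the published dose-response model you
# intend to apply (user-supplied; see Appelt et al. for one such model
# fitted on EQD2, cylindrical tumor volume and clinical nodal status).
trp_coefficients:
  b0: -10.0          # intercept (logit scale)
  b1: 0.18           # per Gy of EQD2
  b_tumor_size: -0.015  # per cm^3 of the reference volume definition
  b_n_stage: -0.7    # clinical N1-2 vs N0
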