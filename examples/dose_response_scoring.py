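"""EQD2 conversion and logistic tumor-response-probability scoring.

Converts the standard long-course schedules to their 2-Gy-fraction
equivalent dose, then scores two hypothetical patients with a logistic
dose-response model.  The coefficients below are placeholders with
plausible signs — real analyses must supply the published model's values
(see examples/trp_coefficients.example.yaml).
"""

import tumorvol as tv

for total, n_fx in [(44.0, 22), (45.0, 25), (50.4, 28), (54.0, 30)]:
    scheme = tv.DoseScheme(total, n_fx)  # alpha/beta defaults to 10 Gy
    print(f"{total:>5.1f} Gy in {n_fx} fx -> EQD2 = {tv.eqd2(scheme):.2f} Gy")

coefs = tv.TRPCoefficients(b0=-10.0, b1=0.18, b_tumor_size=-0.015, b_n_stage=-0.7)

# two patients at the same dose: small node-negative vs large node-positive
p_small = tv.trp(coefs, eqd2_gy=49.56, volume_cm3=20.0, n_positive=0)
p_large = tv.trp(coefs, eqd2_gy=49.56, volume_cm3=120.0, n_positive=1)
print(f"P(pCR) small cN0 tumor:  {p_small:.3f}")
print(f"P(pCR) large cN+ tumor:  {p_large:.3f}")

# Comparing volume definitions inside the model requires putting them on
# the reference volume's scale first (the volume coefficient is per cm^3
# of the volume the model was fitted on):
rtv = [12.0, 25.0, 48.0, 90.0]
catv = [30.0, 66.0, 110.0, 210.0]
print("median-normalized RTV:", tv.normalize_to_reference_median(rtv, catv))
# Output medians now match, so TRP scores computed from either volume
# definition are directly comparable.
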