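"""Inter-observer agreement of volumetry via the intraclass correlation.

Emulates three readers contouring the same 12 phantom tumors with ~1 mm
boundary variation, recomputes RTV and compactness per reader, and
reports ICC(2,1) with its agreement band.
"""

import numpy as np

import tumorvol as tv

rng = np.random.default_rng(0)
rtv = np.zeros((12, 3))
compactness = np.zeros((12, 3))

for i in range(12):
    truth = tv.make_phantom(
        tv.ShapeSpec("spiky", radius_mm=float(rng.uniform(12, 22)), spike_count=8,
                     spike_amplitude_mm=5.0, spacing=(1.5, 1.5, 1.5), seed=100 + i)
    )
    for reader in range(3):
        seen = tv.simulate_reader(truth, boundary_noise_mm=1.0, seed=1000 * reader + i)
        feats = tv.extract_features(seen)
        rtv[i, reader] = feats.rtv_cm3
        compactness[i, reader] = feats.compactness

for name, ratings in (("RTV", rtv), ("compactness", compactness)):
    value, band = tv.icc(ratings)
    print(f"ICC(2,1) for {name:<12}: {value:.3f}  ({band})")

# Volume is robust to contouring noise (high ICC); compactness, which
# depends on the 1-mm surface layer, is more sensitive — the same pattern
# reported for human readers.
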