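"""Volumetric shape features on phantoms with known geometry.

Builds a digitized sphere and a spiculated ("sea-urchin") phantom of
similar volume, extracts the full feature set, and compares the sphere
against its closed-form values.  The point of the compactness feature is
visible directly: equal tumor burden, very different surface shape.
"""

import tumorvol as tv

sphere = tv.make_phantom(tv.ShapeSpec("sphere", radius_mm=18.8, spacing=(0.5, 0.5, 0.5)))
spiky = tv.make_phantom(
    tv.ShapeSpec("spiky", radius_mm=16.5, spike_count=12, spike_amplitude_mm=11,
                 spacing=(0.5, 0.5, 0.5), seed=7)
)

f_sphere = tv.extract_features(sphere)
f_spiky = tv.extract_features(spiky)
analytic = tv.analytic_sphere_features(18.8)

print(f"{'feature':<16}{'sphere':>10}{'analytic':>10}{'spiky':>10}")
for name in ("rtv_cm3", "sa_rtv_cm3", "compactness", "long_axis_cm", "tctv_cm3"):
    print(
        f"{name:<16}{getattr(f_sphere, name):>10.3f}"
        f"{getattr(analytic, name):>10.3f}{getattr(f_spiky, name):>10.3f}"
    )

# The sphere's measured volume (RTV), 1-mm shell volume (the surface-area
# surrogate SA_RTV) and compactness RTV/SA_RTV^1.5 sit within a fraction of
# a percent of the closed forms.  The spiky phantom carries a similar RTV
# but a much larger 1-mm shell, hence a clearly lower compactness — the
# shape contrast that motivates correcting volume by compactness (TCTV).
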