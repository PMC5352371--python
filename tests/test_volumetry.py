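"""Volumetric features against closed-form and brute-force geometric oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import tumorvol as tv
from tumorvol.volumetry import distance_to_background_mm, surface_vertices_mm


def brute_force_contract(mask: tv.SegmentationMask, depth_mm: float) -> np.ndarray:
    """Naive reference: per-voxel min distance over all surface points."""
    verts = surface_vertices_mm(mask)
    from tumorvol.volumetry import _smoothed_indicator

    field = _smoothed_indicator(mask, 1.0)
    inside = field[2:-2, 2:-2, 2:-2] > 0.5
    centers = np.argwhere(mask.voxels) * np.asarray(mask.spacing)
    dmin = cdist(centers, verts).min(axis=1)
    out = np.zeros(mask.voxels.shape, dtype=bool)
    keep = dmin > depth_mm
    out[tuple(np.argwhere(mask.voxels).T)] = keep
    return out & inside


class TestRtv:
    def test_single_voxel(self):
        m = tv.SegmentationMask(np.ones((1, 1, 1), bool), (1, 1, 1))
        assert tv.compute_rtv(m) == pytest.approx(0.001)

    def test_box_coarse_spacing(self):
        m = tv.SegmentationMask(np.ones((10, 10, 10), bool), (2, 2, 2))
        assert tv.compute_rtv(m) == pytest.approx(8.0)

    def test_digitized_sphere_matches_closed_form(self, fine_sphere):
        analytic = 4.0 / 3.0 * math.pi * 1.88**3
        assert tv.compute_rtv(fine_sphere) == pytest.approx(analytic, rel=0.01)

    def test_empty_mask_raises(self):
        m = tv.SegmentationMask(np.zeros((3, 3, 3), bool), (1, 1, 1))
        with pytest.raises(tv.EmptyMaskError):
            tv.compute_rtv(m)


class TestContraction:
    def test_box_interior(self, box_mask):
        core = tv.contract_mask(box_mask, 1.0)
        assert core.n_foreground == 18**3
        assert tv.compute_sa_surrogate(box_mask) == pytest.approx(2.168)

    def test_single_voxel_contracts_to_empty(self):
        m = tv.SegmentationMask(np.ones((1, 1, 1), bool), (1, 1, 1))
        assert tv.contract_mask(m, 1.0).is_empty

    def test_sphere_contracts_to_smaller_sphere(self):
        m = tv.make_phantom(tv.ShapeSpec("sphere", radius_mm=15, spacing=(0.5, 0.5, 0.5)))
        vol = tv.compute_rtv(tv.contract_mask(m, 1.0))
        assert vol == pytest.approx(4.0 / 3.0 * math.pi * 1.4**3, rel=0.02)

    @pytest.mark.parametrize("depth", [0.7, 1.0, 2.5])
    def test_agrees_with_brute_force_on_small_masks(self, blob_mask, box_mask, depth):
        for mask in (blob_mask, box_mask):
            got = tv.contract_mask(mask, depth)
            want = brute_force_contract(mask, depth)
            assert np.array_equal(got.voxels, want)

    def test_nonpositive_depth_rejected(self, box_mask):
        with pytest.raises(tv.ParameterError):
            tv.contract_mask(box_mask, 0.0)

    def test_distance_field_zero_on_background(self, blob_mask):
        d = distance_to_background_mm(blob_mask)
        assert (d[~blob_mask.voxels] == 0).all()
        assert d[blob_mask.voxels].max() > 0


class TestShellAndCompactness:
    def test_sphere_shell_closed_form(self, fine_sphere_features):
        analytic = 4.0 / 3.0 * math.pi * (18.8**3 - 17.8**3) / 1000.0
        assert fine_sphere_features.sa_rtv_cm3 == pytest.approx(analytic, rel=0.05)

    def test_sphere_compactness_closed_form(self, fine_sphere_features):
        a = tv.analytic_sphere_features(18.8)
        assert fine_sphere_features.compactness == pytest.approx(a.compactness, rel=0.05)

    def test_shell_bounded_by_volume(self, blob_mask, box_mask):
        for mask in (blob_mask, box_mask):
            rtv = tv.compute_rtv(mask)
            shell = tv.compute_sa_surrogate(mask)
            assert 0 < shell <= rtv

    def test_thin_slab_compactness_is_rtv_to_minus_half(self):
        slab = tv.SegmentationMask(np.ones((12, 12, 1), bool), (1, 1, 1))
        rtv = tv.compute_rtv(slab)
        assert tv.compute_sa_surrogate(slab) == pytest.approx(rtv)
        assert tv.compute_compactness(slab) == pytest.approx(rtv**-0.5)

    def test_spiky_less_compact_than_sphere_of_similar_volume(self):
        spiky = tv.extract_features(
            tv.make_phantom(
                tv.ShapeSpec("spiky", radius_mm=13, spike_count=12,
                             spike_amplitude_mm=9, spacing=(1, 1, 1), seed=1)
            )
        )
        sphere = tv.extract_features(
            tv.make_phantom(tv.ShapeSpec("sphere", radius_mm=15, spacing=(1, 1, 1)))
        )
        assert abs(spiky.rtv_cm3 / sphere.rtv_cm3 - 1) < 0.25
        assert spiky.compactness < sphere.compactness


class TestAxes:
    def test_single_voxel_degenerate(self):
        m = tv.SegmentationMask(np.ones((1, 1, 1), bool), (1, 1, 1))
        assert tv.measure_axes(m) == (0.0, 0.0)

    def test_box_matches_brute_force_pairwise(self):
        vox = np.ones((10, 4, 4), bool)
        m = tv.SegmentationMask(vox, (5.0, 5.0, 5.0))
        long_axis, diameter = tv.measure_axes(m)
        pts = np.argwhere(vox) * 5.0
        brute = cdist(pts, pts).max() / 10.0
        assert long_axis == pytest.approx(brute)
        sl = np.argwhere(vox[:, :, 0]) * 5.0
        assert diameter == pytest.approx(cdist(sl, sl).max() / 10.0)

    def test_sphere_axes_equal_diameter(self):
        m = tv.make_phantom(tv.ShapeSpec("sphere", radius_mm=21, spacing=(1, 1, 1)))
        long_axis, diameter = tv.measure_axes(m)
        assert long_axis == pytest.approx(4.2, abs=0.2)
        assert diameter == pytest.approx(4.2, abs=0.2)


class TestDerivedVolumes:
    def test_catv_unit_cylinder(self):
        assert tv.compute_catv(2.0, 1.0) == pytest.approx(math.pi)

    def test_catv_closed_form_and_scaling(self):
        assert tv.compute_catv(4.2, 5.0) == pytest.approx(math.pi * 2.1**2 * 5.0)
        assert tv.compute_catv(4.0, 3.0) == pytest.approx(4 * tv.compute_catv(2.0, 3.0))

    def test_catv_rejects_nonpositive(self):
        with pytest.raises(tv.ParameterError):
            tv.compute_catv(0.0, 1.0)

    def test_tctv_identity_and_quotient(self):
        assert tv.compute_tctv(10.0, 1.0) == pytest.approx(10.0)
        assert tv.compute_tctv(27.75, 1.84) == pytest.approx(27.75 / 1.84)
        with pytest.raises(tv.ParameterError):
            tv.compute_tctv(10.0, 0.0)

    def test_tctv_equals_shell_to_three_halves(self, blob_mask, box_mask):
        for mask in (blob_mask, box_mask):
            f = tv.extract_features(mask)
            assert f.tctv_cm3 == pytest.approx(f.sa_rtv_cm3**1.5, rel=1e-9)


class TestExtractFeatures:
    def test_fields_match_individual_operations(self, box_mask):
        f = tv.extract_features(box_mask)
        assert f.rtv_cm3 == tv.compute_rtv(box_mask)
        assert f.sa_rtv_cm3 == pytest.approx(tv.compute_sa_surrogate(box_mask))
        assert f.compactness == pytest.approx(tv.compute_compactness(box_mask))
        la, d = tv.measure_axes(box_mask)
        assert (f.long_axis_cm, f.diameter_cm) == (la, d)
        assert f.catv_cm3 == pytest.approx(tv.compute_catv(d, la))

    def test_invariants_on_phantoms(self):
        for family, kwargs in [
            ("sphere", dict(radius_mm=12)),
            ("ellipsoid", dict(semiaxes_mm=(18, 9, 9))),
            ("spiky", dict(radius_mm=10, spike_count=8, spike_amplitude_mm=5, seed=3)),
        ]:
            f = tv.extract_features(tv.make_phantom(tv.ShapeSpec(family, **kwargs)))
            assert f.rtv_cm3 > 0
            assert 0 < f.sa_rtv_cm3 <= f.rtv_cm3
            assert f.compactness > 0
            assert f.catv_cm3 > 0
            assert f.tctv_cm3 == pytest.approx(f.rtv_cm3 / f.compactness, rel=1e-12)
            assert f.tctv_cm3 == pytest.approx(f.sa_rtv_cm3**1.5, rel=1e-9)

    def test_sphere_compactness_nearly_scale_invariant(self):
        f15 = tv.extract_features(
            tv.make_phantom(tv.ShapeSpec("sphere", radius_mm=15, spacing=(0.5, 0.5, 0.5)))
        )
        f25 = tv.extract_features(
            tv.make_phantom(tv.ShapeSpec("sphere", radius_mm=25, spacing=(0.5, 0.5, 0.5)))
        )
        assert abs(f15.compactness / f25.compactness - 1) < 0.10

    def test_multi_component_flagged(self):
        vox = np.zeros((20, 10, 10), bool)
        vox[2:6, 3:7, 3:7] = True
        vox[12:18, 3:7, 3:7] = True
        f = tv.extract_features(tv.SegmentationMask(vox, (1, 1, 1)))
        assert "multi_component" in f.flags

    def test_contraction_empty_flagged(self):
        slab = tv.SegmentationMask(np.ones((12, 12, 1), bool), (1, 1, 1))
        f = tv.extract_features(slab)
        assert "contraction_empty" in f.flags
        assert f.sa_rtv_cm3 == f.rtv_cm3

    def test_anisotropic_rtv_consistent(self):
        iso = tv.extract_features(
            tv.make_phantom(tv.ShapeSpec("sphere", radius_mm=18.8, spacing=(1, 1, 1)))
        )
        aniso = tv.extract_features(
            tv.make_phantom(tv.ShapeSpec("sphere", radius_mm=18.8, spacing=(0.78, 1.14, 5.0)))
        )
        assert aniso.rtv_cm3 == pytest.approx(iso.rtv_cm3, rel=0.05)
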