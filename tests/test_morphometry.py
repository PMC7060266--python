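import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depotmetry.io import BinaryMask
from depotmetry.morphometry import (
    EmptyMaskError,
    compute_sphericity,
    compute_surface_area,
    compute_volume,
    measure,
)

from conftest import digitize_ellipsoid_mask, digitize_sphere


def prolate_spheroid_area(a: float, c: float) -> float:
    """Closed-form surface area of a prolate spheroid (semi-axes a, a, c > a)."""
    e = np.sqrt(1.0 - (a / c) ** 2)
    return 2.0 * np.pi * a**2 * (1.0 + c / (a * e) * np.arcsin(e))


class TestVolume:
    def test_single_voxel_unit_conversion(self):
        mask = BinaryMask(np.ones((1, 1, 1), dtype=bool), (10.0, 10.0, 10.0))
        assert compute_volume(mask) == pytest.approx(1e-6, rel=1e-12)

    def test_solid_block_exact(self):
        mask = BinaryMask(np.ones((100, 100, 100), dtype=bool), (10.0, 10.0, 10.0))
        assert compute_volume(mask) == pytest.approx(1.0, rel=1e-12)

    def test_digitized_sphere_within_1pct_of_analytic(self):
        mask = digitize_sphere(40.0, spacing=(5.0, 5.0, 5.0))  # r = 200 µm
        analytic = 4.0 / 3.0 * np.pi * 0.2**3  # mm³ = µl
        assert analytic == pytest.approx(0.03351, abs=2e-5)
        assert compute_volume(mask) == pytest.approx(analytic, rel=0.01)

    def test_subset_mask_has_no_larger_volume(self):
        big = digitize_sphere(15.0)
        inner = big.data.copy()
        inner[big.shape[0] // 2] = False  # carve a slab out
        small = BinaryMask(inner, big.spacing)
        assert small.volume_ul() < big.volume_ul()


class TestSurfaceArea:
    def test_single_voxel_naive_faces_six_faces(self):
        # spacing of 1 mm so the six unit faces are 6 mm² exactly
        mask = BinaryMask(np.ones((1, 1, 1), dtype=bool), (1000.0, 1000.0, 1000.0))
        assert compute_surface_area(mask, "naive_faces") == pytest.approx(6.0, rel=1e-12)

    def test_cube_naive_faces_exact(self):
        L = 7
        mask = BinaryMask(np.ones((L, L, L), dtype=bool), (1000.0, 1000.0, 1000.0))
        assert compute_surface_area(mask, "naive_faces") == pytest.approx(6.0 * L**2, rel=1e-12)

    def test_naive_faces_anisotropy_aware(self):
        mask = BinaryMask(np.ones((1, 1, 1), dtype=bool), (2000.0, 1000.0, 500.0))
        # faces: 2*(dy*dx) + 2*(dz*dx) + 2*(dz*dy) in mm²
        assert compute_surface_area(mask, "naive_faces") == pytest.approx(
            2 * (1 * 0.5) + 2 * (2 * 0.5) + 2 * (2 * 1), rel=1e-12
        )

    def test_sphere_r40_calibrated_estimators_within_2pct(self, sphere_r40):
        true_area = 4.0 * np.pi * 40.0**2 / 1e6
        for est in ("weighted_config", "isosurface_mesh"):
            assert compute_surface_area(sphere_r40, est) == pytest.approx(true_area, rel=0.02)

    def test_sphere_r40_naive_faces_biased_by_half(self, sphere_r40):
        # exposed-face counting converges to 3/2 of the smooth area
        true_area = 4.0 * np.pi * 40.0**2 / 1e6
        ratio = compute_surface_area(sphere_r40, "naive_faces") / true_area
        assert ratio == pytest.approx(1.5, abs=0.05)
        assert not np.isclose(ratio, 1.0, atol=0.4)

    def test_estimators_agree_on_digitized_ellipsoids(self):
        # >= 20 voxels per semi-axis, isotropic and anisotropic spacing
        for spacing in ((1.0, 1.0, 1.0), (2.0, 1.0, 1.0)):
            mask = digitize_ellipsoid_mask((30.0, 45.0, 60.0), spacing)
            a_wc = compute_surface_area(mask, "weighted_config")
            a_mesh = compute_surface_area(mask, "isosurface_mesh")
            assert a_wc == pytest.approx(a_mesh, rel=0.03)

    def test_prolate_spheroid_matches_closed_form(self):
        mask = digitize_ellipsoid_mask((60.0, 30.0, 30.0), (1.0, 1.0, 1.0))
        analytic = prolate_spheroid_area(30.0, 60.0) / 1e6
        for est in ("weighted_config", "isosurface_mesh"):
            assert compute_surface_area(mask, est) == pytest.approx(analytic, rel=0.02)

    def test_empty_mask_rejected(self):
        empty = BinaryMask(np.zeros((3, 3, 3), dtype=bool), (1.0, 1.0, 1.0))
        with pytest.raises(EmptyMaskError):
            compute_surface_area(empty)

    def test_unknown_estimator_rejected(self, sphere_r40):
        with pytest.raises(ValueError, match="estimator"):
            compute_surface_area(sphere_r40, "marching_squares")


class TestSphericity:
    @pytest.mark.parametrize("r", [0.5, 1.0, 7.0])
    def test_analytic_sphere_is_exactly_one(self, r):
        v = 4.0 / 3.0 * np.pi * r**3
        a = 4.0 * np.pi * r**2
        assert compute_sphericity(v, a) == pytest.approx(1.0, abs=1e-14)

    def test_cube_closed_form(self):
        L = 3.0
        assert compute_sphericity(L**3, 6 * L**2) == pytest.approx((np.pi / 6) ** (1 / 3), abs=1e-12)
        assert (np.pi / 6) ** (1 / 3) == pytest.approx(0.8060, abs=5e-5)

    def test_prolate_spheroid_closed_form(self):
        a, c = 1.0, 2.0
        v = 4.0 / 3.0 * np.pi * a * a * c
        assert compute_sphericity(v, prolate_spheroid_area(a, c)) == pytest.approx(0.9287, abs=5e-5)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_sphericity(0.0, 1.0)
        with pytest.raises(ValueError):
            compute_sphericity(1.0, -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        v=st.floats(1e-6, 1e3), a=st.floats(1e-4, 1e4), k=st.floats(0.01, 100.0)
    )
    def test_scale_invariance_of_the_formula(self, v, a, k):
        # V ~ k³, A ~ k² leaves S unchanged
        s1 = compute_sphericity(v, a)
        s2 = compute_sphericity(v * k**3, a * k**2)
        assert s2 == pytest.approx(s1, rel=1e-9)


class TestMeasure:
    def test_digitized_sphere_sphericity_in_range(self):
        res = measure(digitize_sphere(30.0))
        assert 0.97 <= res.sphericity <= 1.0

    def test_flat_ellipsoid_less_spherical_than_sphere(self):
        flat = measure(digitize_ellipsoid_mask((300.0, 1500.0, 1500.0), (10.0, 10.0, 10.0)))
        assert flat.sphericity < 1.0
        nodular_like = measure(digitize_sphere(25.0))
        assert flat.sphericity < nodular_like.sphericity

    def test_scale_test_same_shape_finer_grid(self):
        coarse = measure(digitize_ellipsoid_mask((300.0, 500.0, 400.0), (20.0, 20.0, 20.0)))
        fine = measure(digitize_ellipsoid_mask((300.0, 500.0, 400.0), (10.0, 10.0, 10.0)))
        assert fine.sphericity == pytest.approx(coarse.sphericity, rel=0.02)

    def test_spacing_rescaling_scales_v_and_a_geometrically(self):
        mask = digitize_sphere(20.0)
        doubled = BinaryMask(mask.data, tuple(2 * s for s in mask.spacing))
        r1, r2 = measure(mask), measure(doubled)
        assert r2.volume_ul == pytest.approx(8 * r1.volume_ul, rel=1e-12)
        assert r2.surface_mm2 == pytest.approx(4 * r1.surface_mm2, rel=1e-9)
        assert r2.sphericity == pytest.approx(r1.sphericity, rel=1e-9)

    def test_centroid_and_bbox(self):
        data = np.zeros((6, 6, 6), dtype=bool)
        data[2:4, 1:5, 3] = True
        res = measure(BinaryMask(data, (10.0, 10.0, 10.0)))
        assert res.centroid_um == pytest.approx((30.0, 30.0, 35.0))
        assert res.bounding_box == ((2, 4), (1, 5), (3, 4))

    def test_empty_mask_gives_explicit_no_deposit_result(self):
        res = measure(BinaryMask(np.zeros((3, 3, 3), dtype=bool), (1.0, 1.0, 1.0)))
        assert res.is_empty
        assert res.volume_ul == 0.0
        assert np.isnan(res.surface_mm2) and np.isnan(res.sphericity)

    def test_calibrated_sphericity_never_exceeds_one(self):
        for r in (10.0, 25.0, 40.0):
            assert measure(digitize_sphere(r)).sphericity <= 1.0
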