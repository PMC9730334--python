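import math

import numpy as np
import pytest

from veinmorph.imagecore import ScaleBar
from veinmorph.morphometry import (
    canny_contour,
    cos_theta_profile,
    extract_contour_functions,
    length_from_pixels,
    measure_length,
    measure_vein,
    measure_width,
    orient_principal_axis,
    true_width_profile,
    width_from_pixels,
    WidthProfile,
)
from veinmorph.synth import degrade, generate_phantom, PhantomSpec

from conftest import random_mask, tilted_band_spec

SCALE = ScaleBar(0.2645)


class TestCannyContour:
    def test_solid_square_perimeter(self):
        m = np.zeros((9, 9), np.uint8)
        m[2:7, 2:7] = 1
        assert canny_contour(m).sum() == 16

    def test_empty_mask(self):
        assert canny_contour(np.zeros((5, 5), np.uint8)).sum() == 0

    def test_matches_neighbor_scan_oracle(self, rng):
        m = random_mask(rng, (20, 20), 0.5)
        out = canny_contour(m)
        for y in range(20):
            for x in range(20):
                if m[y, x] == 0:
                    assert out[y, x] == 0
                    continue
                nbrs = [
                    m[y + dy, x + dx] if 0 <= y + dy < 20 and 0 <= x + dx < 20 else 0
                    for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1))
                ]
                assert out[y, x] == (1 if min(nbrs) == 0 else 0)


class TestOrientation:
    def test_horizontal_band_barely_rotated(self, horizontal_band):
        _, mask, _ = horizontal_band
        skel = np.zeros_like(mask)
        skel[60, 60:460] = 1
        _, _, angle = orient_principal_axis(mask, skel)
        assert abs(angle) < 1.0

    @pytest.mark.parametrize("tilt", [15.0, 30.0])
    def test_detects_known_tilt(self, tilt):
        spec = tilted_band_spec(300, tilt, 15, seed=2)
        _, mask, _ = generate_phantom(spec)
        from veinmorph.f3ms import f3ms_pipeline

        skel = f3ms_pipeline(mask)
        m_r, s_r, angle = orient_principal_axis(mask, skel)
        assert abs(angle - tilt) < 1.0
        # post-rotation principal axis is horizontal
        _, _, residual = orient_principal_axis(m_r, s_r)
        assert abs(residual) < 1.0

    def test_vertical_band_rotated_to_horizontal(self, horizontal_band):
        _, mask, _ = horizontal_band
        v = np.rot90(mask).copy()
        skel = np.rot90(np.zeros_like(mask)).copy()
        skel[60:460, 60] = 1
        m_r, s_r, angle = orient_principal_axis(v, skel)
        assert abs(abs(angle) - 90) < 1.0
        ys, xs = np.nonzero(s_r)
        assert np.ptp(xs) > np.ptp(ys)

    def test_empty_skeleton_rejected(self):
        with pytest.raises(ValueError):
            orient_principal_axis(np.ones((5, 5), np.uint8), np.zeros((5, 5), np.uint8))


class TestContourFunctions:
    def test_rectangle_rows(self):
        m = np.zeros((30, 20), np.uint8)
        m[10:21, 2:18] = 1
        cf = extract_contour_functions(canny_contour(m))
        assert (cf.upper == 10).all()
        assert (cf.lower == 20).all()

    def test_single_pixel_columns_omitted(self):
        c = np.zeros((10, 5), np.uint8)
        c[4, 1] = 1  # lone contour pixel in column 1
        c[2, 3] = c[7, 3] = 1
        cf = extract_contour_functions(c)
        assert list(cf.columns) == [3]

    def test_wedge_separation_grows_with_slope(self):
        m = np.zeros((60, 50), np.uint8)
        for x in range(5, 45):
            half = 3 + (x - 5) // 4  # thickness grows 1 row per 4 columns
            m[30 - half : 30 + half + 1, x] = 1
        cf = extract_contour_functions(canny_contour(m))
        sep = cf.lower - cf.upper
        fit = np.polyfit(cf.columns, sep, 1)[0]
        assert fit == pytest.approx(0.5, rel=0.15)

    def test_no_valid_columns_rejected(self):
        with pytest.raises(ValueError):
            extract_contour_functions(np.zeros((5, 5), np.uint8))


class TestCosTheta:
    def test_horizontal_skeleton_gives_one(self):
        ct = cos_theta_profile(np.arange(10.0), np.full(10, 4.0))
        assert np.allclose(ct, 1.0)

    def test_45_degree_line(self):
        ct = cos_theta_profile(np.arange(10.0), np.arange(10.0))
        assert np.allclose(ct, math.sqrt(0.5), atol=1e-12)

    def test_bounds(self, rng):
        ct = cos_theta_profile(np.arange(30.0), rng.normal(0, 3, 30))
        assert (ct > 0).all() and (ct <= 1).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cos_theta_profile(np.arange(2.0), np.arange(2.0))


class TestTrueWidthProfile:
    def _band_pieces(self, tilt, T=20, L=300):
        spec = tilted_band_spec(L, tilt, T, seed=4)
        _, mask, _ = generate_phantom(spec)
        from veinmorph.f3ms import f3ms_pipeline

        skel = f3ms_pipeline(mask)
        cf = extract_contour_functions(canny_contour(mask))
        return cf, skel

    def test_horizontal_band_half_thickness_everywhere(self):
        cf, skel = self._band_pieces(0.0)
        profile = true_width_profile(cf, skel)
        inner = profile.true_width[20:-20]  # away from the rounded caps
        assert np.allclose(inner, 10.0, atol=0.51)

    def test_tilted_band_midline_mode_corrects_the_width(self):
        # no re-orientation: separation is T/cos(phi) but cos(theta)
        # recovers approximately cos(phi), so the product stays near T/2
        cf, skel = self._band_pieces(20.0)
        profile = true_width_profile(cf, skel, mode="midline")
        assert np.mean(profile.true_width[20:-20]) == pytest.approx(10.0, rel=0.03)

    def test_tilted_band_literal_mode_overestimates(self):
        # constant half-separation ordinate means cos(theta) = 1: the
        # tilted band is reported 1/cos(phi) too wide
        cf, skel = self._band_pieces(20.0)
        profile = true_width_profile(cf, skel, mode="half_separation")
        expected = 10.0 / math.cos(math.radians(20.0))
        assert np.mean(profile.true_width[20:-20]) == pytest.approx(expected, rel=0.03)

    def test_true_width_never_exceeds_half_separation(self):
        cf, skel = self._band_pieces(12.0)
        profile = true_width_profile(cf, skel)
        assert (profile.true_width <= profile.half_sep + 1e-12).all()
        assert (profile.cos_theta > 0).all() and (profile.cos_theta <= 1).all()

    def test_unknown_mode_rejected(self):
        cf, skel = self._band_pieces(0.0)
        with pytest.raises(ValueError):
            true_width_profile(cf, skel, mode="banana")


class TestUnitConversion:
    @pytest.mark.parametrize(
        "pixels,expected_mm",
        [
            (461.62500, 122.0998),
            (511.15625, 135.2008),
            (495.28125, 131.0019),
            (480.5625, 127.1088),
            (490.59375, 129.7620),
            (551.59375, 145.8965),
        ],
    )
    def test_length_conversion_group_means(self, pixels, expected_mm):
        assert length_from_pixels(pixels, SCALE) == pytest.approx(expected_mm, abs=5e-5)

    @pytest.mark.parametrize(
        "pixels,expected_mm",
        [
            (16.81806469, 4.448378111),
            (17.04709003, 4.508955313),
            (15.86600711, 4.196558881),
            (16.8325939, 4.452221086),
            (16.78426195, 4.439437285),
            (16.47386206, 4.357336515),
        ],
    )
    def test_width_conversion_group_means(self, pixels, expected_mm):
        assert width_from_pixels(pixels, SCALE) == pytest.approx(expected_mm, abs=5e-9)

    def test_measure_length_counts_pixels(self):
        m = np.zeros((5, 10), np.uint8)
        m[2, 1:9] = 1
        mm, count = measure_length(m, SCALE)
        assert count == 8
        assert mm == pytest.approx(8 * 0.2645)

    def test_empty_skeleton_measures_zero(self):
        mm, count = measure_length(np.zeros((4, 4), np.uint8), SCALE)
        assert (mm, count) == (0.0, 0)

    def test_length_is_linear_in_scale(self, horizontal_band):
        _, mask, _ = horizontal_band
        from veinmorph.f3ms import f3ms_pipeline

        skel = f3ms_pipeline(mask)
        mm1, n1 = measure_length(skel, ScaleBar(0.1))
        mm2, n2 = measure_length(skel, ScaleBar(0.3))
        assert n1 == n2
        assert mm2 == pytest.approx(3 * mm1)

    def test_measure_width_mean(self):
        profile = WidthProfile(
            columns=np.arange(4), skeleton_ordinate=np.zeros(4),
            half_sep=np.full(4, 9.0), cos_theta=np.ones(4), true_width=np.full(4, 9.0),
        )
        mm, px = measure_width(profile, SCALE)
        assert px == 9.0
        assert mm == pytest.approx(9.0 * 0.2645)


class TestMeasureVein:
    def test_clean_horizontal_phantom(self, horizontal_band):
        _, mask, truth = horizontal_band
        res = measure_vein(mask, ScaleBar(0.25))
        assert res.length_mm == pytest.approx(0.25 * truth.centerline_len_px, rel=0.05)
        assert res.width_mm == pytest.approx(0.25 * truth.half_width_px, rel=0.05)

    def test_gapped_phantom_measures_like_clean(self, horizontal_band):
        spec, mask, truth = horizontal_band
        from dataclasses import replace

        gapped_spec = replace(spec, n_gaps=2, gap_len_px=8)
        deg, _ = degrade(mask, gapped_spec, truth)
        res = measure_vein(deg, ScaleBar(0.25))
        assert res.length_mm == pytest.approx(0.25 * truth.centerline_len_px, rel=0.05)
        assert res.width_mm == pytest.approx(0.25 * truth.half_width_px, rel=0.05)

    def test_curved_phantom_arc_length(self):
        xs = np.linspace(60, 460, 41)
        ys = 100 + 25 * np.sin((xs - 60) / 400 * 2 * np.pi)
        cl = tuple((float(x), float(y)) for x, y in zip(xs, ys))
        arc = np.hypot(np.diff(xs), np.diff(ys)).sum()
        spec = PhantomSpec(canvas=(200, 520), centerline=cl, thickness=16,
                           n_gaps=0, n_holes=0, speckle_density=0.0, seed=4)
        _, mask, _ = generate_phantom(spec)
        res = measure_vein(mask, ScaleBar(1.0))
        assert res.length_mm == pytest.approx(arc, rel=0.07)

    @pytest.mark.parametrize("tilt", [0.0, 10.0, 20.0, 30.0])
    def test_width_recovery_across_tilts(self, tilt):
        spec = tilted_band_spec(400, tilt, 20, seed=5)
        _, mask, _ = generate_phantom(spec)
        res = measure_vein(mask, ScaleBar(1.0))
        assert res.mean_width_px == pytest.approx(10.0, rel=0.05)

    def test_quarter_turn_length_invariance(self, horizontal_band):
        _, mask, _ = horizontal_band
        a = measure_vein(mask, ScaleBar(1.0))
        b = measure_vein(np.rot90(mask).copy(), ScaleBar(1.0))
        assert b.length_mm == pytest.approx(a.length_mm, rel=0.02)

    def test_full_width_flag_doubles(self, horizontal_band):
        _, mask, _ = horizontal_band
        half = measure_vein(mask, ScaleBar(1.0))
        full = measure_vein(mask, ScaleBar(1.0), full_width=True)
        assert full.width_mm == pytest.approx(2 * half.width_mm)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            measure_vein(np.zeros((10, 10), np.uint8), ScaleBar(1.0))
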