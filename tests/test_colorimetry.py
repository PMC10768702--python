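"""Colorimetric transform tests against hand-computed and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chronolux import colorimetry as cm


def _img(values):
    return cm.EncodedImage(np.asarray(values, dtype=float))


# --------------------------------------------------------------------------
# Transfer function
# --------------------------------------------------------------------------


class TestDecode:
    def test_endpoints_fixed(self):
        img = _img([[[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]])
        out = cm.decode_srgb(img).pixels
        assert np.array_equal(out[0, 0], [0, 0, 0])
        assert np.array_equal(out[0, 1], [1, 1, 1])

    def test_midgrey_power(self):
        # 0.5 ** 2.2, high-precision scalar evaluation
        out = cm.decode_srgb(_img([[[0.5] * 3]])).pixels
        assert out[0, 0, 0] == pytest.approx(0.21763764082403103, abs=1e-12)

    def test_constancy_preserved(self):
        img = _img(np.full((4, 5, 3), 0.37))
        out = cm.decode_srgb(img).pixels
        assert np.ptp(out) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cm.EncodedImage(np.full((2, 2, 3), 1.5))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(0.0, 1.0), st.floats(0.2, 5.0))
    def test_monotone_and_invertible(self, v, gamma):
        img = _img([[[v] * 3]])
        lin = cm.decode_srgb(img, gamma)
        back = cm.encode_srgb(lin, gamma)
        assert back.pixels[0, 0, 0] == pytest.approx(v, abs=1e-9)


# --------------------------------------------------------------------------
# RGB <-> XYZ
# --------------------------------------------------------------------------


class TestRgbToXyz:
    def test_black_maps_to_zero(self):
        out = cm.rgb_to_xyz(np.zeros((1, 1, 3)))
        assert np.array_equal(out, np.zeros((1, 1, 3)))

    def test_white_maps_to_white_point(self):
        for name in ("D50", "D65", "D75", "D40"):
            wp = cm.get_white_point(name)
            out = cm.rgb_to_xyz(np.ones((1, 1, 3)), wp)[0, 0]
            assert out == pytest.approx(wp.XYZ_n, abs=1e-12)
            assert out[1] == pytest.approx(1.0, abs=1e-12)

    def test_linearity(self, rng):
        a = rng.uniform(0, 0.5, (3, 4, 3))
        b = rng.uniform(0, 0.5, (3, 4, 3))
        fa, fb = cm.rgb_to_xyz(a), cm.rgb_to_xyz(b)
        assert cm.rgb_to_xyz(a + b) == pytest.approx(fa + fb, abs=1e-12)
        assert cm.rgb_to_xyz(0.5 * a) == pytest.approx(0.5 * fa, abs=1e-12)

    def test_xyz_roundtrip(self, rng):
        rgb = rng.uniform(0, 1, (5, 5, 3))
        back = cm.xyz_to_rgb(cm.rgb_to_xyz(rgb))
        assert back == pytest.approx(rgb, abs=1e-12)


# --------------------------------------------------------------------------
# CIELAB
# --------------------------------------------------------------------------


class TestLab:
    def test_white_point_maps_to_L100(self):
        wp = cm.D65
        lab = cm.xyz_to_lab(wp.XYZ_n.reshape(1, 1, 3), wp)[0, 0]
        assert lab == pytest.approx([100.0, 0.0, 0.0], abs=1e-10)

    def test_black_is_L0(self):
        lab = cm.xyz_to_lab(np.zeros((1, 1, 3)))[0, 0]
        assert lab[0] == 0.0

    def test_mid_luminance_lightness(self):
        # L* = 116 * f(0.18) - 16 evaluated independently
        xyz = (cm.D65.XYZ_n * 0.18).reshape(1, 1, 3)
        lab = cm.xyz_to_lab(xyz)[0, 0]
        expected = 116.0 * 0.18 ** (1.0 / 3.0) - 16.0
        assert lab[0] == pytest.approx(expected, abs=1e-9)
        assert lab[0] == pytest.approx(49.49610761, abs=1e-6)

    def test_roundtrip_below_breakpoint_and_above(self, rng):
        xyz = rng.uniform(0.0, 1.0, (200, 3)) * cm.D65.XYZ_n
        xyz[:50] *= 1e-3  # exercise the linear segment
        back = cm.lab_to_xyz(cm.xyz_to_lab(xyz), cm.D65)
        assert np.max(np.abs(back - xyz) / np.maximum(np.abs(xyz), 1e-12)) < 1e-9

    def test_negative_tristimulus_clamped(self, caplog):
        with caplog.at_level("WARNING"):
            lab = cm.xyz_to_lab(np.full((1, 1, 3), -0.1))
        assert lab[0, 0, 0] == 0.0
        assert any("clamped" in r.message for r in caplog.records)


class TestPolar:
    def test_three_four_five(self):
        lab = np.array([[[50.0, 3.0, 4.0]]])
        chroma, hue, sat = cm.lab_to_polar(lab)
        assert chroma[0, 0] == pytest.approx(5.0, abs=1e-12)
        assert hue[0, 0] == pytest.approx(53.13010235415598, abs=1e-9)
        assert sat[0, 0] == pytest.approx(0.1, abs=1e-12)

    def test_achromatic_conventions(self):
        lab = np.array([[[0.0, 0.0, 0.0], [70.0, 0.0, 0.0]]])
        chroma, hue, sat = cm.lab_to_polar(lab)
        assert np.all(chroma == 0) and np.all(hue == 0) and np.all(sat == 0)

    def test_saturation_ratio(self):
        lab = np.array([[[100.0, 50.0, 0.0]]])
        _, _, sat = cm.lab_to_polar(lab)
        assert sat[0, 0] == pytest.approx(0.5, abs=1e-12)


# --------------------------------------------------------------------------
# CIE 1960 uv and CCT
# --------------------------------------------------------------------------


class TestUv:
    def test_equal_energy_white(self):
        uv = cm.xyz_to_uv1960(np.array([1.0, 1.0, 1.0]))
        assert uv == pytest.approx([4.0 / 19.0, 6.0 / 19.0], abs=1e-12)

    def test_projective_invariance(self, rng):
        xyz = rng.uniform(0.1, 1.0, (10, 3))
        assert cm.xyz_to_uv1960(3.7 * xyz) == pytest.approx(
            cm.xyz_to_uv1960(xyz), abs=1e-12
        )

    def test_zero_luminance(self):
        uv = cm.xyz_to_uv1960(np.array([0.5, 0.0, 0.5]))
        assert uv[1] == 0.0

    def test_zero_denominator_flagged(self):
        uv = cm.xyz_to_uv1960(np.zeros(3))
        assert np.all(np.isnan(uv))


def _oracle_planck_uv(T: float) -> np.ndarray:
    """Independent Planck-integration oracle: rectangle-rule integration of
    Planck's law against the color-matching functions."""
    wl = np.arange(360.0, 830.0 + 0.5, 1.0)
    c2 = 1.4388e7  # nm K
    spec = wl**-5.0 / (np.exp(c2 / (wl * T)) - 1.0)
    cmf = cm.cie1931_cmf(wl)
    X, Y, Z = (spec[:, None] * cmf).sum(axis=0)
    denom = X + 15.0 * Y + 3.0 * Z
    return np.array([4.0 * X / denom, 6.0 * Y / denom])


class TestCct:
    @pytest.mark.parametrize("T", [2000, 3000, 5000, 6500, 9000, 12000, 15000])
    def test_locus_recovery(self, T):
        cct, duv, oor = cm.compute_cct(_oracle_planck_uv(T))
        assert abs(cct - T) < 10.0
        assert abs(duv) < 1e-5
        assert not oor

    def test_positive_duv_for_green_shift(self):
        uv = _oracle_planck_uv(5000.0)
        cct0, duv0, _ = cm.compute_cct(uv)
        cct1, duv1, _ = cm.compute_cct(uv + np.array([0.0, 0.005]))
        assert duv1 > 0
        assert abs(duv0) < 1e-5
        # iso-temperature lines are tilted; the CCT moves only moderately
        assert abs(cct1 - cct0) < 400.0

    def test_d65_cct(self):
        # canonical value is 6504 K; the analytic CMF approximation shifts
        # the locus by a few kelvin
        uv = cm.xyz_to_uv1960(cm.D65.XYZ_n)
        cct, duv, _ = cm.compute_cct(uv)
        assert cct == pytest.approx(6504.0, abs=150.0)
        assert 0.0 < duv < 0.01

    def test_far_point_undefined(self):
        cct, duv, _ = cm.compute_cct(np.array([0.2, 0.45]))
        assert np.isnan(cct) and np.isnan(duv)

    def test_boundary_flagged(self):
        cct, _, oor = cm.compute_cct(cm.planck_uv(990.0))
        assert oor


# --------------------------------------------------------------------------
# CIEDE2000
# --------------------------------------------------------------------------


class TestDeltaE2000:
    def test_identity(self):
        assert cm.delta_e_2000([50, 2, -3], [50, 2, -3]) == 0.0

    def test_neutral_black_white(self):
        assert cm.delta_e_2000([0, 0, 0], [100, 0, 0]) == pytest.approx(100.0, abs=1e-12)

    def test_symmetry_random_pairs(self, rng):
        p = rng.uniform([0, -80, -80], [100, 80, 80], (50, 3))
        q = rng.uniform([0, -80, -80], [100, 80, 80], (50, 3))
        assert cm.delta_e_2000(p, q) == pytest.approx(cm.delta_e_2000(q, p), abs=1e-12)

    def test_against_independent_implementation(self, rng):
        from skimage.color import deltaE_ciede2000

        p = rng.uniform([0, -80, -80], [100, 80, 80], (100, 3))
        q = rng.uniform([0, -80, -80], [100, 80, 80], (100, 3))
        # include hue-discontinuity pairs around the 275-degree rotation zone
        hue_wrap = np.array(
            [
                [[50.0, 2.5, -30.0], [50.0, -2.5, -30.0]],
                [[60.0, 0.5, -44.0], [60.0, -0.5, -44.0]],
                [[35.0, 5.0, -40.0], [35.0, 4.0, 40.0]],
            ]
        )
        p = np.vstack([p, hue_wrap[:, 0]])
        q = np.vstack([q, hue_wrap[:, 1]])
        assert np.max(np.abs(cm.delta_e_2000(p, q) - deltaE_ciede2000(p, q))) < 1e-4


# --------------------------------------------------------------------------
# Luma, white points, orientation invariance
# --------------------------------------------------------------------------


class TestLuma:
    def test_white_and_greyscale(self):
        img = _img([[[1.0, 1.0, 1.0], [0.42, 0.42, 0.42]]])
        luma = cm.compute_luma(img)
        assert luma[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert luma[0, 1] == pytest.approx(0.42, abs=1e-12)

    def test_pure_green_weight(self):
        img = _img([[[0.0, 1.0, 0.0]]])
        assert cm.compute_luma(img)[0, 0] == pytest.approx(0.7152, abs=1e-12)


class TestWhitePoints:
    def test_named_and_daylight_series(self):
        d65 = cm.get_white_point("D65")
        assert d65.xy == (0.3127, 0.3290)
        d40 = cm.get_white_point("D40")
        # 4000 K daylight is warmer (larger x) than 6500 K
        assert d40.xy[0] > d65.xy[0]
        with pytest.raises(ValueError):
            cm.get_white_point("E27")

    def test_explicit_xy(self):
        wp = cm.get_white_point((0.33, 0.34))
        assert wp.XYZ_n[1] == 1.0


def test_maps_transpose_equivariance(rng):
    """Per-pixel maps carry no orientation dependence."""
    rgb = rng.uniform(0.05, 1.0, (6, 9, 3))
    lin = cm.LinearImage(rgb)
    lin_t = cm.LinearImage(rgb.transpose(1, 0, 2))
    m = cm.compute_color_maps(lin)
    mt = cm.compute_color_maps(lin_t)
    assert mt.lab == pytest.approx(m.lab.transpose(1, 0, 2), abs=1e-12)
    assert mt.saturation == pytest.approx(m.saturation.T, abs=1e-12)
    assert mt.cct == pytest.approx(m.cct.T, nan_ok=True, abs=1e-9)
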