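"""Vegetation indices, continuum removal, and band-position parameters."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wheatlnc.features import (FeatureConfig, POSITION_FEATURE_NAMES,
                               UndefinedFeatureError, VI_DEFINITIONS,
                               absorption_params, band_position_params,
                               compute_all_vis, compute_vi, continuum_remove,
                               first_derivative, position_feature_set,
                               reflection_params)
from wheatlnc.io import Spectrum, restrict
from wheatlnc.synthetic import CanopyParams, canopy_spectrum, params_from_lnc


def _spectrum_from_points(points: dict[float, float]) -> Spectrum:
    wl = np.array(sorted(points))
    return Spectrum(wl, np.array([points[w] for w in wl]))


def _flat_spectrum(value=0.3):
    wl = np.linspace(400.0, 1000.0, 200)
    return Spectrum(wl, np.full(200, value))


def _chord_hull_oracle(wl, r, kind):
    """Brute-force continuum: at each band, the extreme value over all chords
    between data-point pairs spanning it (the convex envelope of a finite
    point set is attained on such chords)."""
    n = len(wl)
    hull = r.copy().astype(float)
    for i in range(n):
        best = r[i]
        for j in range(i + 1):
            for k in range(i, n):
                if wl[k] == wl[j]:
                    continue
                t = (wl[i] - wl[j]) / (wl[k] - wl[j])
                chord = (1 - t) * r[j] + t * r[k]
                if kind == "absorption":
                    best = max(best, chord)
                else:
                    best = min(best, chord)
        hull[i] = best
    return hull


class TestVegetationIndices:
    def test_library_has_26_indices(self):
        assert len(VI_DEFINITIONS) == 26

    def test_ndvi_zero_when_bands_equal(self):
        s = _spectrum_from_points({600: 0.3, 670: 0.3, 700: 0.3, 800: 0.3})
        assert compute_vi(s, "NDVI I") == pytest.approx(0.0)

    def test_rvi_hand_value(self):
        s = _spectrum_from_points({600: 0.1, 670: 0.06, 800: 0.48, 900: 0.5})
        assert compute_vi(s, "RVI I") == pytest.approx(8.0)

    def test_savi_hand_value(self):
        s = _spectrum_from_points({600: 0.1, 670: 0.1, 800: 0.5, 900: 0.5})
        assert compute_vi(s, "SAVI I") == pytest.approx(1.5 * 0.4 / 1.1)

    def test_all_26_on_canopy_spectrum(self, canopy_spectrum_mid):
        s = restrict(canopy_spectrum_mid, 400, 1000)
        values = compute_all_vis(s)
        assert len(values) == 26
        assert all(np.isfinite(v) for v in values.values())

    def test_gndvi_identical_to_ndvi_ii(self, canopy_spectrum_mid):
        s = restrict(canopy_spectrum_mid, 400, 1000)
        values = compute_all_vis(s)
        assert values["GNDVI"] == values["NDVI II"]

    def test_flat_spectrum_nd_indices_zero(self):
        values = compute_all_vis(_flat_spectrum())
        for name in ("NDVI I", "NDVI II", "GNDVI", "NDRE", "NPCI",
                     "NDVIg-b#", "MSR", "PRI"):
            assert values[name] == pytest.approx(0.0), name

    def test_undefined_index_reported_not_dropped(self):
        # flat spectrum: DCNI divides by R700 - R670 = 0
        errors = {}
        values = compute_all_vis(_flat_spectrum(), errors=errors)
        assert len(values) == 26
        assert np.isnan(values["DCNI#"])
        assert "DCNI#" in errors

    def test_normalized_difference_bounded(self, canopy_spectrum_mid):
        s = restrict(canopy_spectrum_mid, 400, 1000)
        values = compute_all_vis(s)
        for name in ("NDVI I", "NDVI II", "GNDVI", "NDRE", "NPCI", "NDVIg-b#"):
            assert -1.0 <= values[name] <= 1.0

    def test_unknown_index_rejected(self, canopy_spectrum_mid):
        with pytest.raises(KeyError, match="unknown"):
            compute_vi(canopy_spectrum_mid, "NOPE")

    def test_missing_wavelength_is_an_error(self):
        s = _spectrum_from_points({600: 0.1, 670: 0.1, 700: 0.2})
        with pytest.raises(ValueError):
            compute_vi(s, "NDVI I")  # needs 800 nm


class TestContinuumRemoval:
    def test_linear_spectrum_removes_to_one(self):
        wl = np.linspace(500, 700, 21)
        s = Spectrum(wl, 0.1 + 0.001 * (wl - 500))
        cr = continuum_remove(s, (500, 700), "absorption")
        np.testing.assert_allclose(cr.removed, 1.0, atol=1e-12)

    def test_v_spectrum_hand_hull(self, v_spectrum):
        cr = continuum_remove(v_spectrum, (500, 700), "absorption")
        np.testing.assert_allclose(cr.hull, [0.4, 0.4, 0.4])
        np.testing.assert_allclose(cr.removed, [1.0, 0.5, 1.0])

    def test_endpoints_equal_spectrum(self, canopy_spectrum_mid):
        s = restrict(canopy_spectrum_mid, 400, 1000)
        cr = continuum_remove(s, (557, 754), "absorption")
        assert cr.hull[0] == pytest.approx(cr.reflectance[0])
        assert cr.hull[-1] == pytest.approx(cr.reflectance[-1])
        assert cr.removed[0] == pytest.approx(1.0)
        assert cr.removed[-1] == pytest.approx(1.0)

    @given(st.integers(0, 999))
    def test_hull_dominance_vs_chord_oracle(self, seed):
        # acceptance oracle at property scale: random short spectra
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        wl = np.sort(rng.uniform(500, 900, n))
        while np.any(np.diff(wl) <= 0):
            wl = np.sort(rng.uniform(500, 900, n))
        r = rng.uniform(0.05, 0.95, n)
        s = Spectrum(wl, r)
        for kind in ("absorption", "reflection"):
            cr = continuum_remove(s, (wl[0], wl[-1]), kind)
            oracle = _chord_hull_oracle(wl, r, kind)
            np.testing.assert_allclose(cr.hull, oracle, atol=1e-9)
            if kind == "absorption":
                assert np.all(cr.hull >= r - 1e-9)
            else:
                assert np.all(cr.hull <= r + 1e-9)

    def test_degenerate_region_removes_to_one(self):
        s = _flat_spectrum()
        cr = continuum_remove(s, (500, 700), "absorption")
        np.testing.assert_array_equal(cr.removed, 1.0)

    def test_too_few_bands_rejected(self):
        s = _spectrum_from_points({500: 0.1, 600: 0.2})
        with pytest.raises(ValueError, match="bands"):
            continuum_remove(s, (500, 600), "absorption")


class TestCharacteristicParams:
    def test_v_spectrum_absorption_depth_area_nd(self, v_spectrum):
        cr = continuum_remove(v_spectrum, (500, 700), "absorption")
        depth, area, nd = absorption_params(cr)
        assert depth == pytest.approx(0.5)
        assert area == pytest.approx(20.0)
        assert nd == pytest.approx(0.025)

    def test_inverted_v_reflection_params(self):
        s = _spectrum_from_points({500: 0.2, 600: 0.4, 700: 0.2})
        cr = continuum_remove(s, (500, 700), "reflection")
        np.testing.assert_allclose(cr.hull, 0.2)
        depth, area, nd = reflection_params(cr)
        assert depth == pytest.approx(0.5)
        assert area == pytest.approx(20.0)
        assert nd == pytest.approx(0.025)

    def test_flat_region_degenerate(self):
        cr = continuum_remove(_flat_spectrum(), (500, 700), "reflection")
        depth, area, nd = reflection_params(cr)
        assert depth == 0.0
        assert area == 0.0
        assert np.isnan(nd)

    def test_kind_mismatch_rejected(self, v_spectrum):
        cr = continuum_remove(v_spectrum, (500, 700), "absorption")
        with pytest.raises(ValueError, match="reflection"):
            reflection_params(cr)


class TestBandPosition:
    def test_rise_only_in_red_edge(self):
        wl = np.linspace(450, 800, 351)
        r = np.where(wl < 680, 0.1, 0.1 + 0.004 * (wl - 680))
        s = Spectrum(wl, np.clip(r, 0, 1))
        out = band_position_params(s, FeatureConfig(derivative="central"))
        assert out["Dr"] > 0.003
        assert abs(out["Db"]) < 1e-9
        assert abs(out["Dy"]) < 1e-9

    def test_green_peak_position(self):
        wl = np.linspace(450, 800, 351)
        r = 0.2 + 0.1 * np.exp(-0.5 * ((wl - 550) / 10) ** 2)
        s = Spectrum(wl, r)
        out = band_position_params(s)
        assert out["lambda_g"] == pytest.approx(550.0, abs=1.0)
        assert out["Rg"] == pytest.approx(0.3, abs=1e-3)

    def test_constant_slope_matches_finite_difference_oracle(self):
        wl = np.arange(450.0, 800.0, 1.281)
        r = 0.1 + 0.001 * (wl - 450.0)
        s = Spectrum(wl, r)
        out = band_position_params(s, FeatureConfig(derivative="central"))
        oracle = np.gradient(r, wl)
        win = (wl >= 680) & (wl <= 760)
        assert out["Dr"] == pytest.approx(oracle[win].max(), rel=1e-9)
        assert out["Dr"] == pytest.approx(0.001, rel=1e-6)
        assert out["SDr"] == pytest.approx(oracle[win].sum(), rel=1e-9)

    def test_savgol_matches_central_on_smooth_spectrum(self, canopy_spectrum_mid):
        s = restrict(canopy_spectrum_mid, 400, 1000)
        d_sg = first_derivative(s, FeatureConfig(derivative="savgol"))
        d_c = first_derivative(s, FeatureConfig(derivative="central"))
        # noise-free smooth curve: the two schemes agree to ~1% where the
        # curvature is largest and to machine precision elsewhere
        np.testing.assert_allclose(d_sg, d_c, atol=3e-4)

    def test_window_coverage_required(self):
        s = _spectrum_from_points({500: 0.1, 600: 0.2, 700: 0.3})
        with pytest.raises(ValueError, match="cover"):
            band_position_params(s)

    def test_positions_inside_their_windows(self, canopy_spectrum_mid):
        out = band_position_params(restrict(canopy_spectrum_mid, 400, 1000))
        assert 490 <= out["lambda_b"] <= 530
        assert 560 <= out["lambda_y"] <= 640
        assert 680 <= out["lambda_r"] <= 760
        assert 510 <= out["lambda_g"] <= 560
        assert 650 <= out["lambda_o"] <= 690


class TestPositionFeatureSet:
    def test_exactly_25_features(self, canopy_spectrum_mid):
        out = position_feature_set(restrict(canopy_spectrum_mid, 400, 1000))
        assert len(out) == 25
        assert tuple(out) == POSITION_FEATURE_NAMES

    def test_names_include_field_spellings(self, canopy_spectrum_mid):
        out = position_feature_set(restrict(canopy_spectrum_mid, 400, 1000))
        for name in ("R_Depth1", "R_Aear1", "R_ND1",
                     "A_Depth1", "A_Aear1", "A_ND1", "Rg"):
            assert name in out

    def test_flat_spectrum_degenerates_to_zero(self):
        errors = {}
        out = position_feature_set(_flat_spectrum(), errors=errors)
        for name in ("A_Depth1", "A_Aear1", "R_Depth1", "R_Aear1",
                     "Db", "Dy", "Dr", "SDb", "SDy", "SDr"):
            assert out[name] == pytest.approx(0.0), name

    def test_region_outside_window_reported_as_missing(self, canopy_spectrum_mid):
        s = restrict(canopy_spectrum_mid, 400, 1000)
        cfg = FeatureConfig(absorption_regions=((557.0, 754.0),
                                                (1500.0, 1600.0)))
        errors = {}
        out = position_feature_set(s, cfg, errors=errors)
        assert np.isnan(out["A_Depth2"])
        assert "A2" in errors


class TestScaleInvariance:
    @given(st.floats(0.2, 2.5))
    def test_scaling_leaves_removed_and_depth_unchanged(self, c):
        s = restrict(canopy_spectrum(params_from_lnc(2.5)), 400, 1000)
        scaled = Spectrum(s.wavelengths, np.clip(c * s.reflectance, 0, None))
        cr = continuum_remove(s, (557, 754), "absorption")
        cr_scaled = continuum_remove(scaled, (557, 754), "absorption")
        np.testing.assert_allclose(cr_scaled.removed, cr.removed, rtol=1e-9)
        d0, a0, _ = absorption_params(cr)
        d1, a1, _ = absorption_params(cr_scaled)
        assert d1 == pytest.approx(d0, rel=1e-9)
        assert a1 == pytest.approx(c * a0, rel=1e-9)

    def test_scaling_leaves_ratio_indices_unchanged(self):
        s = restrict(canopy_spectrum(params_from_lnc(2.5)), 400, 1000)
        scaled = Spectrum(s.wavelengths, 0.5 * s.reflectance)
        for name in ("NDVI I", "RVI I", "NDRE", "SIPI", "MSR", "VOG1"):
            assert compute_vi(scaled, name) == pytest.approx(
                compute_vi(s, name), rel=1e-9)


class TestGeneratorLinks:
    def test_a_depth_strictly_increasing_in_chl_depth(self):
        base = params_from_lnc(3.0).__dict__
        depths = []
        for chl in np.linspace(0.1, 0.9, 9):
            p = CanopyParams(**{**base, "chl_depth": float(chl)})
            s = restrict(canopy_spectrum(p), 400, 1000)
            d, _, _ = absorption_params(continuum_remove(s, (557, 754)))
            depths.append(d)
        assert np.all(np.diff(depths) > 0)

    def test_lambda_r_moves_with_red_edge_inflection(self):
        base = params_from_lnc(3.0).__dict__
        lrs = []
        for infl in np.linspace(695.0, 735.0, 9):
            p = CanopyParams(**{**base, "red_edge_infl": float(infl)})
            s = restrict(canopy_spectrum(p), 400, 1000)
            lrs.append(band_position_params(s)["lambda_r"])
        assert np.all(np.diff(lrs) >= 0)
        assert lrs[-1] - lrs[0] > 20.0
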