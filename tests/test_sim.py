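"""Simulator unit and property tests: emission model, shot noise,
concentration scaling, zone maps and dwell-time profiles."""

import numpy as np
import pytest

from lrics import (
    PSFModel,
    ScanGeometry,
    SimConfig,
    acf_x_profile,
    fit_rics_1d,
    global_acf,
    make_dwell_profile,
    make_zone_map,
    molecules_for_concentration,
    simulate_stack,
    subtract_global_mean,
)

from conftest import BRIGHT_LOW, DWELL, DX, W0


def small_geo(nx=32, ny=32, dwell=DWELL):
    return ScanGeometry(nx, ny, DX, dwell)


class TestEmissionModel:
    def test_zero_brightness_gives_all_zero_stack(self, psf):
        cfg = SimConfig(10, 0.0, 24.0, n_frames=3, seed=1, noise=False)
        st = simulate_stack(cfg, small_geo(), psf)
        assert np.all(st.data == 0)
        cfg = SimConfig(10, 0.0, 24.0, n_frames=3, seed=1, noise=True)
        assert np.all(simulate_stack(cfg, small_geo(), psf).data == 0)

    def test_stationary_center_molecule_emits_b_times_dwell(self, psf):
        # one nearly immobile molecule exactly on a pixel centre
        geo = small_geo(16, 16)
        pos = np.array([[5 * DX, 7 * DX, 0.0]])
        cfg = SimConfig(1, 1e5, 1e-9, n_frames=1, seed=0, noise=False,
                        initial_positions=pos)
        st = simulate_stack(cfg, geo, psf)
        expected = 1e5 * DWELL
        assert st.data[0, 7, 5] == pytest.approx(expected, rel=1e-6)
        # a pixel one step away is attenuated by the lateral PSF
        attn = np.exp(-2 * DX**2 / W0**2)
        assert st.data[0, 7, 6] == pytest.approx(expected * attn, rel=1e-5)

    def test_doubling_brightness_doubles_stack(self, psf):
        geo = small_geo()
        a = simulate_stack(SimConfig(50, 1e4, 20.0, n_frames=4, seed=3,
                                     noise=False), geo, psf)
        b = simulate_stack(SimConfig(50, 2e4, 20.0, n_frames=4, seed=3,
                                     noise=False), geo, psf)
        np.testing.assert_allclose(b.data, 2 * a.data, rtol=1e-12)

    def test_same_seed_is_deterministic(self, psf):
        cfg = SimConfig(40, 2e4, 15.0, n_frames=3, seed=9)
        a = simulate_stack(cfg, small_geo(), psf)
        b = simulate_stack(cfg, small_geo(), psf)
        np.testing.assert_array_equal(a.data, b.data)

    def test_shot_noise_is_poisson(self, psf):
        # pinned bright molecule -> constant expectation at its pixel;
        # counts must be Poisson: integer valued, variance ~= mean
        geo = small_geo(5, 5)
        pos = np.array([[2 * DX, 2 * DX, 0.0]])
        cfg = SimConfig(1, 2e5, 1e-9, n_frames=4000, seed=5, noise=True,
                        initial_positions=pos)
        st = simulate_stack(cfg, geo, psf)
        trace = st.data[:, 2, 2]
        assert np.all(trace == np.round(trace))
        ratio = trace.var() / trace.mean()
        assert 0.85 < ratio < 1.15

    def test_mean_intensity_matches_analytic_expectation(self, psf):
        # <I> = B tau n_mol V_psf / V_box with V_psf = (pi/2)^(3/2) w0^2 wz
        geo = small_geo(48, 48)
        n_mol = 900
        cfg = SimConfig(n_mol, 5e4, 20.0, n_frames=40, seed=6, noise=False)
        st = simulate_stack(cfg, geo, psf)
        lx = geo.nx * DX + 2 * cfg.box_margin
        ly = geo.ny * DX + 2 * cfg.box_margin
        v_box = lx * ly * 2 * (3 * psf.wz)
        v_psf = (np.pi / 2) ** 1.5 * psf.w0**2 * psf.wz
        expected = 5e4 * DWELL * n_mol * v_psf / v_box
        assert st.data.mean() == pytest.approx(expected, rel=0.1)


class TestFluctuationStatistics:
    def test_acf_amplitude_inverse_in_concentration(self, psf):
        # FCS property: G(0) ~ 1/<N>; halving the molecule count about
        # doubles the correlation amplitude
        geo = small_geo(48, 48)
        amps = []
        for n_mol, seed in ((300, 11), (600, 12)):
            cfg = SimConfig(n_mol, 1e5, 20.0, n_frames=60, seed=seed,
                            noise=False)
            st = subtract_global_mean(simulate_stack(cfg, geo, psf))
            prof = acf_x_profile(global_acf(st, 12))
            amps.append(prof.values[1])
        ratio = amps[0] / amps[1]
        assert 1.4 < ratio < 2.8

    def test_fitted_d_monotone_in_configured_d(self, psf):
        geo = small_geo(48, 48)
        n_mol = molecules_for_concentration(geo, psf)
        fitted = []
        for i, d in enumerate((4.0, 12.0, 24.0, 36.0)):
            cfg = SimConfig(n_mol, BRIGHT_LOW, d, n_frames=60, seed=20 + i)
            st = subtract_global_mean(simulate_stack(cfg, geo, psf))
            fit = fit_rics_1d(acf_x_profile(global_acf(st, 20)), geo, psf)
            assert fit.success
            fitted.append(fit.d)
        assert fitted == sorted(fitted)

    def test_global_fit_recovers_configured_d(self, psf):
        # uniform D = 24 um^2/s at GFP-like brightness: the fitted
        # whole-image ACF recovers the input within ~10%
        geo = ScanGeometry(64, 64, DX, DWELL)
        n_mol = molecules_for_concentration(geo, psf)
        cfg = SimConfig(n_mol, BRIGHT_LOW, 24.0, n_frames=100, seed=7)
        st = subtract_global_mean(simulate_stack(cfg, geo, psf))
        fit = fit_rics_1d(acf_x_profile(global_acf(st, 32)), geo, psf)
        assert fit.d == pytest.approx(24.0, rel=0.10)


class TestValidation:
    def test_rejects_nonpositive_diffusion(self):
        with pytest.raises(ValueError):
            SimConfig(10, 1e4, 0.0, n_frames=1)
        with pytest.raises(ValueError):
            SimConfig(10, 1e4, -3.0, n_frames=1)

    def test_rejects_mismatched_d_map(self, psf):
        cfg = SimConfig(10, 1e4, np.full((8, 8), 5.0), n_frames=1)
        with pytest.raises(ValueError, match="d_map"):
            simulate_stack(cfg, small_geo(16, 16), psf)

    def test_rejects_wrong_length_dwell_profile(self):
        with pytest.raises(ValueError, match="dwell"):
            ScanGeometry(32, 32, DX, np.full(16, DWELL))

    def test_rejects_nonpositive_dwell(self):
        with pytest.raises(ValueError):
            ScanGeometry(8, 8, DX, 0.0)


class TestZoneMap:
    def test_three_equal_zones_widths(self):
        zmap = make_zone_map(256, 256, [85, 85, 86], [12.0, 18.0, 24.0])
        assert zmap.shape == (256, 256)
        rows = zmap[:, 0]
        assert np.all(rows[:85] == 12.0)
        assert np.all(rows[85:170] == 18.0)
        assert np.all(rows[170:] == 24.0)

    def test_single_zone_is_constant(self):
        zmap = make_zone_map(16, 12, [12], [7.5])
        assert np.all(zmap == 7.5)

    def test_boundary_rows_match_index_arithmetic(self):
        widths, values = [3, 5, 4], [1.0, 2.0, 3.0]
        zmap = make_zone_map(6, 12, widths, values)
        expected = np.repeat(values, widths)   # explicit index enumeration
        np.testing.assert_array_equal(zmap[:, 2], expected)

    def test_zones_along_x(self):
        zmap = make_zone_map(10, 4, [4, 6], [1.0, 2.0], axis="x")
        np.testing.assert_array_equal(zmap[0], [1.0] * 4 + [2.0] * 6)

    def test_rejects_widths_not_summing_to_field(self):
        with pytest.raises(ValueError, match="sum"):
            make_zone_map(16, 16, [8, 9], [1.0, 2.0])


class TestDwellProfile:
    def test_constant_profile(self):
        prof = make_dwell_profile(64, "constant", {"tau": DWELL})
        assert prof.shape == (64,)
        assert np.all(prof == DWELL)

    def test_edge_slowdown_min_center_max_borders(self):
        prof = make_dwell_profile(
            256, "edge_slowdown", {"tau_min": 12e-6, "tau_max": 18e-6}
        )
        assert prof.min() == pytest.approx(12e-6, rel=1e-3)
        assert prof[0] == pytest.approx(18e-6)
        assert prof[-1] == pytest.approx(18e-6)
        assert np.argmin(prof) == pytest.approx(127.5, abs=1)

    def test_polynomial_profile(self):
        prof = make_dwell_profile(32, "polynomial", {"coeffs": [5e-6, 0, 10e-6]})
        assert prof[0] == pytest.approx(15e-6)
        assert prof.min() == pytest.approx(10e-6, rel=0.01)

    def test_rejects_nonpositive_profiles(self):
        with pytest.raises(ValueError, match="positive"):
            make_dwell_profile(32, "polynomial", {"coeffs": [1e-6, 0, -1e-7]})
        with pytest.raises(ValueError, match="kind"):
            make_dwell_profile(32, "unknown", {})


def test_zone_simulation_has_slower_decorrelation_in_slow_zone(psf, zone_stack):
    """Molecules in low-D zones decorrelate more slowly along the line:
    the x-ACF of the slow band must sit above the fast band's."""
    from lrics import RasterStack

    pre = subtract_global_mean(zone_stack)
    ny = pre.geometry.ny
    geo_band = ScanGeometry(pre.geometry.nx, 32, DX, DWELL)
    slow = RasterStack(pre.data[:, :32], geo_band, psf,
                       meta={"preprocessed": "global_mean"})
    fast = RasterStack(pre.data[:, ny - 32:], geo_band, psf,
                       meta={"preprocessed": "global_mean"})
    acf_slow = acf_x_profile(global_acf(slow, 16)).values
    acf_fast = acf_x_profile(global_acf(fast, 16)).values
    # compare normalized decay at a mid lag
    assert acf_slow[6] / acf_slow[1] > acf_fast[6] / acf_fast[1]
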