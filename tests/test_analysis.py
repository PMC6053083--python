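"""Acquisition-time arithmetic, line-scan diffusion profiles,
segmentation and Gaussian histogram fits."""

import numpy as np
import pytest

from lrics import (
    ScanGeometry,
    acquisition_time,
    fit_gaussian_mixture,
    line_rics,
    make_zone_map,
    mask_resolution,
    segment_by_channel,
)

from conftest import DWELL, DX, make_line_stack


class TestAcquisitionTime:
    def test_frame_time_of_reference_acquisition(self):
        geo = ScanGeometry(256, 256, DX, DWELL)
        assert acquisition_time(geo, 1) == pytest.approx(3.2768, abs=1e-12)

    def test_hundred_frames_in_minutes(self):
        geo = ScanGeometry(256, 256, DX, DWELL)
        assert acquisition_time(geo, 100) / 60 == pytest.approx(5.4613,
                                                                abs=1e-3)

    def test_thousand_lines(self):
        geo = ScanGeometry(256, 1, DX, DWELL)
        t = acquisition_time(geo, 1000, mode="lines")
        assert t == pytest.approx(12.8, abs=1e-12)
        assert t / 60 == pytest.approx(0.2133, abs=1e-3)

    def test_retrace_times_add(self):
        geo = ScanGeometry(64, 32, DX, DWELL, line_retrace=1e-3,
                           frame_retrace=0.1)
        expected = 32 * (64 * DWELL + 1e-3) + 0.1
        assert acquisition_time(geo, 1) == pytest.approx(expected)

    def test_mask_resolution_identities(self):
        assert mask_resolution(25, DX) == pytest.approx(0.5)
        assert mask_resolution(41, DX) == pytest.approx(0.82)


class TestLineRICS:
    def test_uniform_line_gives_flat_profile_at_configured_d(
            self, psf, line_calibration):
        st = make_line_stack(psf, 16.0, n_lines=3000, seed=310)
        lm = line_rics(st, 25, line_calibration)
        ok = np.isfinite(lm.d)
        assert ok.sum() > 30
        assert np.nanmean(lm.d) == pytest.approx(16.0, rel=0.15)
        # flat: no systematic left/right difference beyond the spread
        half = ok.sum() // 2
        vals = lm.d[ok]
        assert abs(vals[:half].mean() - vals[half:].mean()) < \
            3 * vals.std() / np.sqrt(half) + 0.1 * 16.0

    def test_two_segment_line_shows_step(self, psf, line_calibration):
        zmap = make_zone_map(64, 1, [32, 32], [10.0, 25.0], axis="x")
        st = make_line_stack(psf, zmap, n_lines=4000, seed=320)
        lm = line_rics(st, 25, line_calibration)
        left = np.nanmean(lm.d[12:22])
        right = np.nanmean(lm.d[42:52])
        assert left == pytest.approx(10.0, rel=0.3)
        assert right == pytest.approx(25.0, rel=0.3)
        assert right - left > 7.5

    def test_noise_decreases_with_line_count(self, psf, line_calibration):
        st = make_line_stack(psf, 16.0, n_lines=2000, seed=330)
        from lrics import RasterStack
        few = RasterStack(st.data[:500], st.geometry, st.psf)
        lm_few = line_rics(few, 25, line_calibration)
        lm_many = line_rics(st, 25, line_calibration)
        assert np.nanstd(lm_many.phi) < np.nanstd(lm_few.phi)

    def test_rejects_2d_stacks(self, psf):
        from lrics import RasterStack
        geo = ScanGeometry(32, 4, DX, DWELL)
        st = RasterStack(np.ones((5, 4, 32)), geo)
        with pytest.raises(ValueError, match="n_lines, 1, nx"):
            line_rics(st, 7)

    def test_csv_round_trip(self, psf, line_calibration, tmp_path):
        import pandas as pd
        st = make_line_stack(psf, 16.0, n_lines=200, seed=331)
        lm = line_rics(st, 25, line_calibration)
        path = tmp_path / "line.csv"
        lm.to_csv(path)
        back = pd.read_csv(path)
        assert list(back.columns[:3]) == ["x", "intensity", "phi"]
        assert len(back) == 64


class TestSegmentation:
    def test_zero_channel_puts_all_in_low_group(self):
        d = np.arange(12.0).reshape(3, 4)
        with pytest.warns(UserWarning, match="degenerate"):
            res = segment_by_channel(d, np.zeros((3, 4)))
        assert res.low_values.size == 12
        assert res.high_values.size == 0

    def test_known_labels_partition_exactly(self):
        channel = np.array([[0.0, 0.0, 5.0, 5.0]])
        d = np.array([[1.0, 2.0, 3.0, 4.0]])
        res = segment_by_channel(d, channel, threshold=0.5)
        np.testing.assert_array_equal(np.sort(res.low_values), [1.0, 2.0])
        np.testing.assert_array_equal(np.sort(res.high_values), [3.0, 4.0])

    def test_nan_pixels_excluded_and_norm_over_finite_region(self):
        channel = np.array([[0.0, 1.0, 0.5]])
        d = np.array([[np.nan, 2.0, 3.0]])
        res = segment_by_channel(d, channel)
        # the NaN pixel is dropped; min-max normalization runs over the
        # remaining region {1.0, 0.5} -> {1.0, 0.0}
        assert set(res.low_values) == {3.0}
        assert set(res.high_values) == {2.0}

    def test_two_population_groups_differ(self):
        rng = np.random.default_rng(0)
        d = np.concatenate([rng.normal(8, 1, 500), rng.normal(15, 3, 500)])
        channel = np.concatenate([np.zeros(500), np.ones(500)])
        res = segment_by_channel(d, channel)
        assert res.high_values.mean() - res.low_values.mean() > 5


class TestGaussianMixture:
    def test_single_gaussian_recovers_parameters(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(10.0, 2.0, 4000)
        fit = fit_gaussian_mixture(vals, 1)
        assert fit.means[0] == pytest.approx(10.0, abs=0.2)
        assert fit.sigmas[0] == pytest.approx(2.0, abs=0.3)

    def test_two_component_fit_separates_populations(self):
        # the two nucleolar-like populations: 8 +- 1 and 15 +- 3
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(8, 1, 2500),
                               rng.normal(15, 3, 2500)])
        fit = fit_gaussian_mixture(vals, 2)
        assert fit.means[0] == pytest.approx(8.0, abs=1.0)
        assert fit.means[1] == pytest.approx(15.0, abs=1.5)
        assert 0.2 < fit.weights[0] < 0.8

    def test_matches_em_mixture_oracle(self):
        # independent route: EM on the raw samples instead of a
        # least-squares histogram fit
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(8, 1, 3000),
                               rng.normal(15, 2.5, 3000)])
        fit = fit_gaussian_mixture(vals, 2)
        em = GaussianMixture(2, random_state=0).fit(vals[:, None])
        em_means = np.sort(em.means_.ravel())
        np.testing.assert_allclose(fit.means, em_means, atol=0.7)

    def test_two_components_on_single_population_degenerate(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(12.0, 2.0, 4000)
        fit = fit_gaussian_mixture(vals, 2)
        # either one component vanishes or both sit on the same mean
        assert (fit.weights.min() < 0.15
                or abs(fit.means[1] - fit.means[0]) < 1.5)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="50"):
            fit_gaussian_mixture(np.ones(10), 1)
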