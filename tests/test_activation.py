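"""HRF construction, GLM activation mapping, ROI handling, and dBV."""

import numpy as np
import pytest
import scipy.stats

from fusulm import (
    ActivationMap,
    HRFParams,
    ROI,
    StimulusParadigm,
    build_design,
    delta_bv,
    extract_roi,
    fit_hrf_params,
    glm_fit,
    hrf_kernel,
    mirror_roi,
    simulate_pd_series,
)
from fusulm.clutter import PowerDopplerSeries


@pytest.fixture
def paradigm():
    return StimulusParadigm((4.0, 14.0), (4.0, 4.0), 28.0, dt=0.1)


def _series_from_array(images, frame_interval=0.4):
    from fusulm import AcquisitionConfig

    cfg = AcquisitionConfig(framerate=500.0, block_size=200)
    return PowerDopplerSeries(images=images, frame_interval=frame_interval,
                              config=cfg, n_removed=0)


class TestHrfKernel:
    def test_pure_rise_fall_is_single_cosine_bump(self):
        k = hrf_kernel(HRFParams(d1=0, d2=2, d3=2, d4=0, c1=0, c2=0), dt=0.01)
        assert k[0] == 0.0
        assert k[200] == pytest.approx(1.0)  # peak at t = 2 s
        assert k[400] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(k[:200], k[400:200:-1], atol=1e-12)  # symmetric

    def test_peak_is_exactly_one(self):
        for params in (HRFParams(), HRFParams(d1=0.5, c1=0.3, c2=0.6)):
            assert hrf_kernel(params, 0.05).max() == 1.0

    def test_integral_matches_half_cosine_areas(self):
        d2, d3 = 1.5, 2.5
        k = hrf_kernel(HRFParams(d1=0, d2=d2, d3=d3, d4=0, c1=0, c2=0), dt=0.001)
        # closed form: each half-cosine ramp has mean 1/2 over its support
        assert np.trapezoid(k, dx=0.001) == pytest.approx(d2 / 2 + d3 / 2, rel=1e-3)

    def test_degenerate_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            hrf_kernel(HRFParams(d1=0, d2=0, d3=0, d4=0), 0.1)
        with pytest.raises(ValueError):
            HRFParams(d2=0, d3=0)


class TestBuildDesign:
    def test_delta_stimulus_reproduces_kernel(self):
        """A one-sample stimulus makes the regressor proportional to the
        HRF itself (convolution identity), up to the half-sample offset
        of frame-centre sampling."""
        p = StimulusParadigm((1.0,), (0.1,), 20.0, dt=0.1)
        hrf = HRFParams()
        X = build_design(p, hrf, n_frames=190, frame_interval=0.1)
        reg = X[:, 0]
        t_frames = (np.arange(190) + 0.5) * 0.1
        expected = hrf.evaluate(t_frames - 1.0)
        expected /= expected.max()
        assert np.corrcoef(reg, expected)[0, 1] > 0.999
        assert abs(t_frames[np.argmax(reg)] - (1.0 + hrf.d1 + hrf.d2)) <= 0.15
        assert np.all(reg[t_frames < 1.0] == 0)  # causal

    def test_zero_paradigm_gives_intercept_only(self):
        p = StimulusParadigm((), (), 20.0, dt=0.1)
        X = build_design(p, HRFParams(), 40, 0.4)
        assert np.all(X[:, 0] == 0) and np.all(X[:, 1] == 1)

    def test_corneal_preset_has_six_response_lobes(self):
        from fusulm import make_paradigm_preset

        p = make_paradigm_preset("corneal_mech", dt=0.1)
        X = build_design(p, HRFParams(), n_frames=550, frame_interval=0.4)
        above = X[:, 0] > 0.5
        n_lobes = int(np.sum(np.diff(above.astype(int)) == 1) + above[0])
        assert n_lobes == 6

    def test_short_paradigm_rejected(self, paradigm):
        with pytest.raises(ValueError, match="covers"):
            build_design(paradigm, HRFParams(), n_frames=100, frame_interval=0.4)


class TestGlmFit:
    def test_perfect_fit_reports_capped_z(self, paradigm):
        X = build_design(paradigm, HRFParams(), 60, 0.4)
        images = (10.0 + 2.0 * X[:, 0])[:, None, None] * np.ones((1, 3, 3))
        amap = glm_fit(_series_from_array(images), X)
        assert np.all(amap.z == 8.2)
        np.testing.assert_allclose(amap.beta, 2.0, rtol=1e-9)

    def test_noise_free_beta_equals_amplitude_times_baseline(self, paradigm):
        series, _ = simulate_pd_series(np.full((5, 5), 40.0), np.ones((5, 5), bool),
                                       0.25, paradigm, n_frames=60, frame_interval=0.4,
                                       noise_rel_std=0.0, seed=0)
        X = build_design(paradigm, HRFParams(), 60, 0.4)
        amap = glm_fit(series, X)
        np.testing.assert_allclose(amap.beta, 0.25 * 40.0, rtol=1e-6)

    def test_mask_consistent_with_bonferroni_rule(self, paradigm, rng):
        series, _ = simulate_pd_series(np.full((8, 8), 10.0), None, 0.0, paradigm,
                                       n_frames=60, frame_interval=0.4, seed=4)
        amap = glm_fit(series, X := build_design(paradigm, HRFParams(), 60, 0.4))
        np.testing.assert_array_equal(amap.mask, amap.p < amap.alpha / amap.n_tests)

    def test_rank_deficient_design_names_columns(self, paradigm):
        X = np.ones((60, 2))
        images = np.random.default_rng(0).random((60, 2, 2))
        with pytest.raises(ValueError, match="columns"):
            glm_fit(_series_from_array(images), X)

    def test_too_few_frames_rejected(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError, match="frames"):
            glm_fit(_series_from_array(np.ones((3, 2, 2))), X)


class TestRoi:
    def _map_from_mask(self, mask, z):
        return ActivationMap(z=z, p=np.where(mask, 1e-9, 0.5), mask=mask,
                             beta=z, alpha=0.05, n_tests=mask.size, df=10)

    def test_single_significant_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        roi = extract_roi(self._map_from_mask(mask, mask.astype(float)))
        assert roi.n_pixels == 1

    def test_component_containing_max_z_wins(self):
        """Two disjoint blobs: the ROI is exactly the blob holding the
        maximal Z, verified against exhaustive connected-component
        labelling."""
        mask = np.zeros((8, 8), bool)
        mask[1:3, 1:3] = True   # blob A
        mask[5:8, 5:8] = True   # blob B (contains max Z)
        z = np.zeros((8, 8))
        z[mask] = 1.0
        z[6, 6] = 5.0
        roi = extract_roi(self._map_from_mask(mask, z))
        expected = np.zeros((8, 8), bool)
        expected[5:8, 5:8] = True
        np.testing.assert_array_equal(roi.mask, expected)

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[1, 1] = True  # 8-connectivity joins diagonals
        z = mask.astype(float)
        roi = extract_roi(self._map_from_mask(mask, z))
        assert roi.n_pixels == 2

    def test_empty_map_raises_no_activation(self):
        with pytest.raises(ValueError, match="no activation"):
            extract_roi(self._map_from_mask(np.zeros((4, 4), bool), np.zeros((4, 4))))

    def test_mirror_is_involution_and_preserves_count(self):
        mask = np.zeros((6, 10), bool)
        mask[2:4, 1:4] = True
        roi = ROI(mask=mask)
        m1 = mirror_roi(roi, midline_x_mm=0.5, pixel_dx_mm=0.1)
        m2 = mirror_roi(m1, midline_x_mm=0.5, pixel_dx_mm=0.1)
        assert m1.n_pixels == roi.n_pixels
        np.testing.assert_array_equal(m2.mask, roi.mask)

    def test_mirror_out_of_grid_rejected(self):
        mask = np.zeros((4, 10), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError, match="outside"):
            mirror_roi(ROI(mask=mask), midline_x_mm=0.9, pixel_dx_mm=0.1)


class TestDeltaBV:
    def test_constant_signal_gives_zero_dbv(self, paradigm):
        images = np.full((60, 4, 4), 7.0)
        roi = ROI(mask=np.ones((4, 4), bool))
        tr = delta_bv(_series_from_array(images), roi, paradigm)
        np.testing.assert_allclose(tr.dbv, 0.0)
        assert tr.dbv_stim == 0.0

    def test_step_increase_arithmetic(self, paradigm):
        """Baseline 100, stimulation 107.3 -> dBV_STIM = 7.3%."""
        stim = paradigm.frame_stim_mask(60, 0.4)
        images = np.where(stim, 107.3, 100.0)[:, None, None] * np.ones((1, 2, 2))
        tr = delta_bv(_series_from_array(images), ROI(mask=np.ones((2, 2), bool)), paradigm)
        assert tr.dbv_stim == pytest.approx(7.3)
        assert tr.dbv_bl == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self, paradigm, rng):
        images = 5.0 + rng.random((60, 4, 4))
        roi = ROI(mask=np.ones((4, 4), bool))
        a = delta_bv(_series_from_array(images), roi, paradigm)
        b = delta_bv(_series_from_array(3.7 * images), roi, paradigm)
        np.testing.assert_allclose(a.dbv, b.dbv, atol=1e-9)

    def test_baseline_mean_exactly_zero(self, paradigm, rng):
        images = 5.0 + rng.random((60, 4, 4))
        tr = delta_bv(_series_from_array(images), ROI(mask=np.ones((4, 4), bool)), paradigm)
        assert abs(tr.dbv[~tr.stim_mask].mean()) < 1e-12

    def test_nonpositive_baseline_rejected(self, paradigm):
        images = np.zeros((60, 2, 2))
        with pytest.raises(ValueError, match="baseline"):
            delta_bv(_series_from_array(images), ROI(mask=np.ones((2, 2), bool)), paradigm)


class TestFitHrf:
    def _trace(self, paradigm, hrf, scale, noise=0.0, seed=0):
        X = build_design(paradigm, hrf, 70, 0.4)
        rng = np.random.default_rng(seed)
        y = scale * X[:, 0] + noise * rng.standard_normal(70)
        from fusulm.activation import DeltaBVTrace

        return DeltaBVTrace(t=(np.arange(70) + 0.5) * 0.4, dbv=y,
                            stim_mask=paradigm.frame_stim_mask(70, 0.4),
                            baseline_value=1.0, dbv_bl=0.0, dbv_stim=float(y.mean()))

    def test_noise_free_recovery_of_known_hrf(self, paradigm):
        true = HRFParams(d1=0, d2=1.2, d3=2.2, d4=1.8, c1=0, c2=0.25)
        trace = self._trace(paradigm, true, scale=8.0)
        fit = fit_hrf_params(trace, paradigm)
        assert fit.identifiable
        model = fit.scale * build_design(paradigm, fit.params, 70, 0.4)[:, 0]
        assert np.sqrt(np.mean((model - trace.dbv) ** 2)) < 0.05 * 8.0

    def test_flat_trace_flagged_non_identifiable(self, paradigm):
        trace = self._trace(paradigm, HRFParams(), scale=0.0)
        fit = fit_hrf_params(trace, paradigm)
        assert not fit.identifiable
        assert abs(fit.scale) < 1e-6

    def test_noisy_fit_residual_bounded_by_noise(self, paradigm):
        noise = 0.8  # SNR 10 against the scale-8 response
        trace = self._trace(paradigm, HRFParams(), scale=8.0, noise=noise, seed=3)
        fit = fit_hrf_params(trace, paradigm)
        model = fit.scale * build_design(paradigm, fit.params, 70, 0.4)[:, 0]
        resid = np.linalg.norm(model - trace.dbv)
        noise_norm = noise * np.sqrt(70)
        assert resid <= noise_norm * 1.1
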