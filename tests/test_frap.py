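"""FRAP traces, double normalization, recovery fitting, averaging, flow."""

import numpy as np
import pytest

import nequant as nq
from nequant.frap import FrapTrace, _model
from _oracles import interp_mean_loop


def _trace(t, I_b, I_tot, I_bg, n_pre):
    return FrapTrace(np.asarray(t, float), np.asarray(I_b, float),
                     np.asarray(I_tot, float), np.asarray(I_bg, float), n_pre)


class TestExtractTraces:
    def test_constant_image_gives_constant_trace(self):
        series = nq.ImageStack(np.full((5, 16, 16), 7.0), ("time", "y", "x"))
        roi = np.zeros((16, 16), bool)
        roi[4:8, 4:8] = True
        total = np.zeros((16, 16), bool)
        total[2:12, 2:12] = True
        bg = np.zeros((16, 16), bool)
        bg[14:, 14:] = True
        tr = nq.extract_traces(series, nq.FrapROISet(roi, total, bg), n_prebleach=2)
        assert np.all(tr.I_bleach == 7.0) and np.all(tr.I_total == 7.0)
        assert tr.t[0] == -2 and tr.t[2] == 0

    def test_generator_truth_recovered_within_noise(self, frap_geometry, background_roi):
        spec = nq.FrapSpec(mobile_fraction=0.6, rate=0.08, noise_sigma=2.0,
                           n_postbleach_frames=60, bleach_roi_halfwidth=3, seed=5)
        series, truth = nq.make_frap_series(spec, frap_geometry)
        rois = nq.FrapROISet(truth.masks["bleach"], truth.masks["structure"],
                             background_roi)
        tr = nq.extract_traces(series, rois, spec.n_prebleach_frames)
        expected = truth.frap["true_bleach_trace"] + spec.background_level
        sigma_of_mean = spec.noise_sigma / np.sqrt(truth.masks["bleach"].sum())
        assert np.all(np.abs(tr.I_bleach - expected) < 4 * sigma_of_mean)

    def test_roi_shape_mismatch_rejected(self):
        series = nq.ImageStack(np.ones((3, 8, 8)), ("time", "y", "x"))
        big = np.ones((10, 10), bool)
        with pytest.raises(ValueError):
            nq.extract_traces(series, nq.FrapROISet(big, big, ~big), 1)

    def test_empty_roi_rejected(self):
        empty = np.zeros((8, 8), bool)
        total = np.ones((8, 8), bool)
        with pytest.raises(ValueError, match="non-empty"):
            nq.FrapROISet(empty, total, ~total)


class TestDoubleNormalize:
    def test_reference_frame_normalizes_to_one(self):
        tr = _trace([-1, 0, 1], [100, 40, 60], [1000, 940, 950], [10, 10, 10], 1)
        nq.double_normalize(tr)
        assert tr.N[0] == pytest.approx(1.0, abs=1e-15)

    def test_printed_formula_worked_example(self):
        # reference frame 100/1000/10; at t: 55/910/10 -> (45/90)/(900/990) = 0.55
        tr = _trace([-1, 0], [100, 55], [1000, 910], [10, 10], 1)
        nq.double_normalize(tr, reference="last")
        assert tr.N[1] == pytest.approx(0.55, abs=1e-12)

    def test_proportional_traces_cancel_to_unity(self):
        t = np.arange(-2, 10, dtype=float)
        decay = np.exp(-0.03 * (t - t[0]))
        tr = _trace(t, 100 * decay + 10, 1000 * decay + 10, np.full_like(t, 10.0), 2)
        nq.double_normalize(tr)
        assert np.allclose(tr.N, 1.0, atol=1e-12)

    def test_affine_intensity_rescaling_invariance(self):
        t = np.arange(-2, 30, dtype=float)
        rng = np.random.default_rng(3)
        I_b = np.concatenate([[100, 100], 40 + 30 * (1 - np.exp(-0.1 * t[2:]))])
        I_tot = np.full_like(t, 900.0)
        I_bg = np.full_like(t, 12.0)
        tr1 = nq.double_normalize(_trace(t, I_b, I_tot, I_bg, 2))
        gain, offset = 3.7, 25.0
        tr2 = nq.double_normalize(_trace(t, gain * I_b + offset, gain * I_tot + offset,
                                         gain * I_bg + offset, 2))
        assert np.allclose(tr1.N, tr2.N, atol=1e-12)

    def test_reference_below_background_rejected(self):
        tr = _trace([-1, 0], [5, 4], [8, 7], [10, 10], 1)
        with pytest.raises(ValueError, match="reference"):
            nq.double_normalize(tr)

    def test_nonpositive_total_frames_excluded(self):
        tr = _trace([-1, 0, 1], [100, 40, 50], [1000, 5, 900], [10, 10, 10], 1)
        with pytest.warns(UserWarning, match="excluded"):
            nq.double_normalize(tr)
        assert tr.excluded_frames == [1]
        assert np.isnan(tr.N[1])

    def test_acquisition_bleaching_removed_for_immobile_pool(self, frap_geometry,
                                                             background_roi):
        spec = nq.FrapSpec(mobile_fraction=0.0, acquisition_bleach_rate=0.002,
                           noise_sigma=1.0, n_postbleach_frames=100,
                           bleach_roi_halfwidth=3, seed=8)
        series, truth = nq.make_frap_series(spec, frap_geometry)
        rois = nq.FrapROISet(truth.masks["bleach"], truth.masks["structure"],
                             background_roi)
        tr = nq.double_normalize(nq.extract_traces(series, rois, spec.n_prebleach_frames))
        post = tr.N_post
        assert np.ptp(post) < 0.05  # constant within noise: bleaching cancelled


class TestFitRecovery:
    def _normalized(self, t, N, n_pre=2):
        pre_t = np.arange(-n_pre, 0, dtype=float)
        tr = _trace(np.concatenate([pre_t, t]),
                    np.ones(n_pre + len(t)), np.ones(n_pre + len(t)),
                    np.zeros(n_pre + len(t)), n_pre)
        tr.N = np.concatenate([np.ones(n_pre), N])
        return tr

    def test_noise_free_closed_form(self):
        t = np.arange(0, 200, dtype=float)
        D, plateau, k = 0.4, 0.9, 0.05
        N = plateau + (D - plateau) * np.exp(-k * t)
        fit = nq.fit_recovery(self._normalized(t, N))
        assert fit.mobile_fraction == pytest.approx((0.9 - 0.4) / 0.6, abs=1e-6)
        assert fit.t_half == pytest.approx(np.log(2) / 0.05, rel=1e-6)
        assert fit.residual_norm < 1e-6

    def test_flat_trace_means_immobile(self):
        t = np.arange(0, 50, dtype=float)
        with pytest.warns(UserWarning, match="no recovery"):
            fit = nq.fit_recovery(self._normalized(t, np.full_like(t, 0.4)))
        assert fit.mobile_fraction == 0.0
        assert np.isnan(fit.rate)

    def test_full_recovery_reaches_mobile_fraction_one(self):
        t = np.arange(0, 300, dtype=float)
        N = 1.0 + (0.3 - 1.0) * np.exp(-0.04 * t)
        fit = nq.fit_recovery(self._normalized(t, N))
        assert fit.mobile_fraction == pytest.approx(1.0, abs=1e-5)

    def test_cofit_depth_matches_fixed_depth_on_clean_data(self):
        t = np.arange(0, 200, dtype=float)
        N = 0.75 + (0.35 - 0.75) * np.exp(-0.07 * t)
        fixed = nq.fit_recovery(self._normalized(t, N), fix_depth=True)
        cofit = nq.fit_recovery(self._normalized(t, N), fix_depth=False)
        assert cofit.mobile_fraction == pytest.approx(fixed.mobile_fraction, abs=1e-5)
        assert cofit.rate == pytest.approx(fixed.rate, rel=1e-4)

    def test_too_few_frames_rejected(self):
        t = np.arange(0, 5, dtype=float)
        with pytest.raises(ValueError, match="10 post-bleach"):
            nq.fit_recovery(self._normalized(t, np.full_like(t, 0.4)))


class TestAverageCurves:
    def _norm_trace(self, t, N):
        tr = _trace(t, np.ones_like(t), np.ones_like(t), np.zeros_like(t), 1)
        tr.N = np.asarray(N, float)
        return tr

    def test_identical_curves_have_zero_sem(self):
        t = np.arange(-1, 10, dtype=float)
        trs = [self._norm_trace(t, np.linspace(1, 0.5, len(t))) for _ in range(5)]
        out = nq.average_curves(trs)
        assert np.allclose(out["sem"], 0.0)
        assert (out["n_curves"] == 5).all()

    def test_sem_of_two_values(self):
        t = np.array([-1.0, 0.0])
        out = nq.average_curves([self._norm_trace(t, [1.0, 0.4]),
                                 self._norm_trace(t, [1.0, 0.6])])
        assert out["mean"].iloc[1] == pytest.approx(0.5)
        assert out["sem"].iloc[1] == pytest.approx(0.1, abs=1e-12)

    def test_single_trace_sem_missing(self):
        t = np.array([-1.0, 0.0, 1.0])
        out = nq.average_curves([self._norm_trace(t, [1, 0.5, 0.6])])
        assert np.isnan(out["sem"]).all()

    def test_shifted_grids_match_interpolation_oracle(self):
        t1 = np.array([-1.0, 0.0, 1.0, 2.0, 3.0])
        t2 = np.array([-1.5, -0.5, 0.5, 1.5, 2.5, 3.5])
        n1 = np.array([1.0, 0.4, 0.55, 0.63, 0.68])
        n2 = np.array([1.0, 1.0, 0.5, 0.6, 0.66, 0.7])
        out = nq.average_curves([self._norm_trace(t1, n1), self._norm_trace(t2, n2)])
        oracle = interp_mean_loop(out["t"], [(t1, n1), (t2, n2)])
        assert np.allclose(out["mean"], oracle, atol=1e-12)


class TestFlowMetric:
    def _pipeline(self, spec, geometry, background_roi):
        series, truth = nq.make_frap_series(spec, geometry)
        rois = nq.FrapROISet(truth.masks["bleach"], truth.masks["structure"],
                             background_roi)
        tr = nq.extract_traces(series, rois, spec.n_prebleach_frames)
        return tr, truth

    def test_gain_equals_loss_without_acquisition_bleaching(self, frap_geometry,
                                                            background_roi):
        spec = nq.FrapSpec(mobile_fraction=0.5, noise_sigma=0.0,
                           n_postbleach_frames=80, seed=2)
        tr, truth = self._pipeline(spec, frap_geometry, background_roi)
        fm = nq.flow_metric(tr, int(truth.masks["bleach"].sum()),
                            int(truth.masks["structure"].sum()))
        assert np.abs(fm["residual"]).max() < 1e-9

    def test_immobile_pool_transfers_nothing(self, frap_geometry, background_roi):
        spec = nq.FrapSpec(mobile_fraction=0.0, noise_sigma=0.0,
                           n_postbleach_frames=40, seed=2)
        tr, truth = self._pipeline(spec, frap_geometry, background_roi)
        fm = nq.flow_metric(tr, int(truth.masks["bleach"].sum()),
                            int(truth.masks["structure"].sum()))
        assert np.abs(fm["transfer"]).max() < 1e-9

    def test_asymptotic_transfer_matches_recovery_law(self, frap_geometry,
                                                      background_roi):
        spec = nq.FrapSpec(mobile_fraction=0.5, rate=0.05, noise_sigma=0.0,
                           n_postbleach_frames=300, seed=2)
        tr, truth = self._pipeline(spec, frap_geometry, background_roi)
        n_b = int(truth.masks["bleach"].sum())
        fm = nq.flow_metric(tr, n_b, int(truth.masks["structure"].sum()))
        P, D = spec.prebleach_level, spec.postbleach_depth * spec.prebleach_level
        expected = spec.mobile_fraction * (P - D) * n_b
        assert fm["gain"].iloc[-1] == pytest.approx(expected, rel=0.05)

    def test_rois_must_partition_structure(self):
        t = np.arange(-1, 20, dtype=float)
        tr = _trace(t, np.ones_like(t), np.ones_like(t), np.zeros_like(t), 1)
        with pytest.raises(ValueError, match="partition"):
            nq.flow_metric(tr, 10, 10)


def test_model_matches_plateau_identity():
    # plateau = D + M (1 - D) is the fit family's defining identity
    t = np.linspace(0, 500, 50)
    D, M, k = 0.25, 0.6, 0.02
    assert _model(t, D, M, k)[-1] == pytest.approx(D + M * (1 - D), abs=1e-4)
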