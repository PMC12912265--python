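import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yolkflow.io import CalibratedStack, Roi
from yolkflow.kinetics import (
    LN2,
    FitError,
    accumulation_slope,
    fit_recovery,
    intensity_series,
    measure_gap_width,
    normalize_frap,
    recoil_velocity,
)
from yolkflow.synth import make_ablation_stack, make_frap_trace


class TestNormalizeFrap:
    def test_arithmetic_example(self):
        raw = np.array([100.0, 100.0, 40.0, 80.0])
        curve = normalize_frap(raw, bleach_index=2, frame_interval=1.0)
        assert curve.values[1] == pytest.approx((80 - 40) / (100 - 40))

    def test_prebleach_value_maps_to_one(self):
        raw = np.array([100.0, 100.0, 40.0, 100.0])
        curve = normalize_frap(raw, 2, 1.0)
        assert curve.values[-1] == pytest.approx(1.0)

    def test_generator_closed_form_pointwise(self):
        trace, gt = make_frap_trace(tau=10.0, f_pre=1.0, f_bleach=0.3, f_inf=0.9,
                                    n_pre=10, n_post=60, dt=0.5, noise_sigma=0.0)
        curve = normalize_frap(trace, 10, 0.5)
        m = (0.9 - 0.3) / (1.0 - 0.3)
        expected = m * (1 - np.exp(-curve.times / 10.0))
        np.testing.assert_allclose(curve.values, expected, atol=1e-12)

    def test_no_bleach_is_explicit_error(self):
        raw = np.array([50.0, 50.0, 60.0, 70.0])
        with pytest.raises(ValueError, match="prebleach mean 50"):
            normalize_frap(raw, 2, 1.0)

    def test_too_few_prebleach_frames(self):
        with pytest.raises(ValueError):
            normalize_frap(np.array([1.0, 0.2, 0.5]), 1, 1.0)

    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-10.0, 10.0))
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, scale, offset):
        """a·F + b (a > 0) leaves the normalized curve unchanged."""
        trace, _ = make_frap_trace(tau=8.0, n_pre=5, n_post=40, noise_sigma=0.01, seed=2)
        c0 = normalize_frap(trace, 5, 0.5)
        c1 = normalize_frap(scale * trace + offset, 5, 0.5)
        np.testing.assert_allclose(c1.values, c0.values, atol=1e-9)


class TestFitRecovery:
    def test_noiseless_recovers_tau_and_half_time(self):
        trace, _ = make_frap_trace(tau=10.0, n_pre=10, n_post=120, dt=0.5, noise_sigma=0.0)
        fit = fit_recovery(normalize_frap(trace, 10, 0.5))
        assert fit.tau == pytest.approx(10.0, rel=1e-6)
        assert fit.half_time == pytest.approx(10.0 * LN2, rel=1e-6)
        assert fit.half_time / fit.tau == LN2

    def test_noisy_tau_recovered(self):
        # bleach-depth normalization pins the scale to one noisy frame, so
        # single-trace tau error at sigma=0.02 can reach ~10%; the ensemble
        # test below bounds the median error
        trace, _ = make_frap_trace(tau=10.0, n_pre=10, n_post=120, dt=0.5,
                                   noise_sigma=0.02, seed=11)
        fit = fit_recovery(normalize_frap(trace, 10, 0.5))
        assert fit.tau == pytest.approx(10.0, rel=0.15)

    def test_mobile_fraction_matches_plateau(self):
        trace, _ = make_frap_trace(tau=5.0, f_pre=1.0, f_bleach=0.2, f_inf=0.8,
                                   n_pre=10, n_post=200, dt=0.5, noise_sigma=0.0)
        fit = fit_recovery(normalize_frap(trace, 10, 0.5))
        assert fit.mobile_fraction == pytest.approx((0.8 - 0.2) / (1.0 - 0.2), rel=1e-4)

    def test_flat_curve_is_fit_error(self):
        from yolkflow.kinetics import RecoveryCurve

        curve = RecoveryCurve(times=np.arange(20.0), values=np.zeros(20),
                              n_pre=2, bleach_index=2, prebleach_mean=1.0,
                              first_postbleach=0.0)
        with pytest.raises(FitError):
            fit_recovery(curve)

    def test_too_few_points_rejected(self):
        from yolkflow.kinetics import RecoveryCurve

        curve = RecoveryCurve(times=np.arange(5.0), values=np.linspace(0, 1, 5),
                              n_pre=2, bleach_index=2, prebleach_mean=1.0,
                              first_postbleach=0.0)
        with pytest.raises(ValueError):
            fit_recovery(curve)

    def test_parameter_recovery_ensemble(self):
        """Median relative tau error < 15% at sigma=0.05, no sign bias."""
        errs = []
        for seed in range(100):
            trace, _ = make_frap_trace(tau=10.0, n_pre=10, n_post=120, dt=0.5,
                                       noise_sigma=0.05, seed=seed)
            fit = fit_recovery(normalize_frap(trace, 10, 0.5))
            errs.append((fit.tau - 10.0) / 10.0)
        errs = np.asarray(errs)
        assert np.median(np.abs(errs)) < 0.15
        from scipy.stats import binomtest

        n_pos = int(np.sum(errs > 0))
        assert binomtest(n_pos, errs.size, 0.5).pvalue > 0.01


class TestGapWidth:
    def _strip_stack(self, gap_px):
        frames = np.ones((2, 40, 8))
        if gap_px:
            start = 20 - gap_px // 2
            frames[1, start : start + gap_px, :] = 0.0
        return CalibratedStack(frames, pixel_size=0.2, frame_interval=1.0)

    def test_binary_gap_counting(self):
        stack = self._strip_stack(10)
        roi = Roi(kind="rectangle", bounds=(0, 0, 40, 8))
        series = measure_gap_width(stack, roi, 0.5, cut_index=1)
        assert series.widths_um[0] == pytest.approx(2.0, abs=0.2)

    def test_pre_cut_frame_zero_width(self):
        stack = self._strip_stack(0)
        roi = Roi(kind="rectangle", bounds=(0, 0, 40, 8))
        series = measure_gap_width(stack, roi, 0.5, cut_index=1)
        assert series.widths_um[0] == 0.0

    def test_no_pre_cut_frame_is_error(self):
        stack = self._strip_stack(10)
        roi = Roi(kind="rectangle", bounds=(0, 0, 40, 8))
        with pytest.raises(ValueError):
            measure_gap_width(stack, roi, 0.5, cut_index=0)

    def test_generator_widths_within_one_pixel(self):
        stack, gt = make_ablation_stack(3.0, 2.0, n_frames=15, dt=0.1,
                                        pixel_size=0.05, shape=(256, 32))
        roi = Roi(kind="rectangle", bounds=(0, 0, 256, 32))
        series = measure_gap_width(stack, roi, 0.5, cut_index=gt.data["n_pre"])
        true = np.asarray(gt.data["widths_um"])[gt.data["n_pre"]:]
        assert np.max(np.abs(series.widths_um - true)) <= 0.05  # 1 px = 0.05 µm


class TestRecoilVelocity:
    def test_exact_line(self):
        from yolkflow.kinetics import RecoilSeries

        series = RecoilSeries(times=np.array([0.0, 1.0, 2.0]),
                              widths_um=np.array([2.0, 3.0, 4.0]))
        out = recoil_velocity(series, fit_frames=3)
        assert out.velocity_um_s == pytest.approx(1.0)
        assert out.velocity_se == pytest.approx(0.0, abs=1e-12)

    def test_constant_width_zero_velocity(self):
        from yolkflow.kinetics import RecoilSeries

        series = RecoilSeries(times=np.arange(5.0), widths_um=np.full(5, 2.0))
        assert recoil_velocity(series, 5).velocity_um_s == pytest.approx(0.0)

    def test_saturating_family_underestimates_monotonically(self):
        """Longer fit windows on w(t)=w_inf(1-exp(-t/tau)) bias the slope
        further below the true initial velocity."""
        t = np.arange(30) * 0.1
        w = 3.0 * (1 - np.exp(-t / 2.0))
        from yolkflow.kinetics import RecoilSeries

        series = RecoilSeries(times=t, widths_um=w)
        slopes = [recoil_velocity(series, k).velocity_um_s for k in (2, 5, 10, 20, 30)]
        assert all(s1 > s2 for s1, s2 in zip(slopes, slopes[1:]))
        assert all(s < 1.5 for s in slopes)

    def test_generator_velocity_within_10pc(self):
        stack, gt = make_ablation_stack(3.0, 2.0, n_frames=20, dt=0.05,
                                        pixel_size=0.02, shape=(256, 32))
        roi = Roi(kind="rectangle", bounds=(0, 0, 256, 32))
        series = measure_gap_width(stack, roi, 0.5, cut_index=gt.data["n_pre"])
        out = recoil_velocity(series, fit_frames=5)
        assert out.velocity_um_s == pytest.approx(1.5, rel=0.10)

    def test_too_few_points(self):
        from yolkflow.kinetics import RecoilSeries

        series = RecoilSeries(times=np.arange(3.0), widths_um=np.arange(3.0))
        with pytest.raises(ValueError):
            recoil_velocity(series, fit_frames=1)


class TestIntensitySeries:
    def _stack(self, frames):
        return CalibratedStack(np.asarray(frames, dtype=float), 0.25, 30.0)

    def test_constant_stack_first_frame_mode(self):
        stack = self._stack(np.full((5, 8, 8), 7.0))
        roi = Roi(kind="rectangle", bounds=(0, 0, 8, 8))
        series = intensity_series(stack, roi, "first-frame")
        np.testing.assert_allclose(series.values, 1.0)

    def test_blastoderm_ratio(self):
        frames = np.zeros((1, 8, 16))
        frames[0, :, :8] = 200.0
        frames[0, :, 8:] = 100.0
        stack = self._stack(frames)
        roi = Roi(kind="rectangle", bounds=(0, 0, 8, 8))
        ref = Roi(kind="rectangle", bounds=(0, 8, 8, 8))
        series = intensity_series(stack, roi, "blastoderm-roi", reference_roi=ref)
        assert series.values[0] == pytest.approx(2.0)

    def test_linear_ramp_oracle(self):
        t_min = np.arange(6) * 0.5  # 30 s frames
        frames = np.ones((6, 4, 4)) * (1 + 0.1 * t_min)[:, None, None]
        stack = self._stack(frames)
        roi = Roi(kind="rectangle", bounds=(0, 0, 4, 4))
        series = intensity_series(stack, roi, "first-frame")
        np.testing.assert_allclose(series.values, 1 + 0.1 * t_min, rtol=1e-12)

    def test_blastoderm_mode_cancels_global_scaling(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 2, size=(6, 8, 16))
        gains = rng.uniform(0.5, 1.5, size=6)[:, None, None]
        roi = Roi(kind="rectangle", bounds=(0, 0, 8, 8))
        ref = Roi(kind="rectangle", bounds=(0, 8, 8, 8))
        s0 = intensity_series(self._stack(base), roi, "blastoderm-roi", reference_roi=ref)
        s1 = intensity_series(self._stack(base * gains), roi, "blastoderm-roi", reference_roi=ref)
        np.testing.assert_allclose(s1.values, s0.values, rtol=1e-12)

    def test_reference_roi_requirement(self):
        stack = self._stack(np.ones((3, 8, 8)))
        roi = Roi(kind="rectangle", bounds=(0, 0, 4, 4))
        with pytest.raises(ValueError, match="reference_roi"):
            intensity_series(stack, roi, "blastoderm-roi")
        with pytest.raises(ValueError, match="reference_roi"):
            intensity_series(stack, roi, "first-frame", reference_roi=roi)


class TestAccumulationSlope:
    def _series(self, values, dt_s=60.0):
        from yolkflow.kinetics import IntensitySeries

        values = np.asarray(values, dtype=float)
        return IntensitySeries(times_s=np.arange(values.size) * dt_s,
                               values=values, normalization="first-frame")

    def test_exact_line(self):
        out = accumulation_slope(self._series([1.0, 1.1, 1.2]))
        assert out.slope_per_min == pytest.approx(0.1)

    def test_constant_series_zero_slope(self):
        out = accumulation_slope(self._series([1.0] * 5))
        assert out.slope_per_min == pytest.approx(0.0)

    def test_noisy_ramp_within_3se(self):
        rng = np.random.default_rng(5)
        t_min = np.arange(30)
        vals = 1 + 0.02 * t_min + rng.normal(0, 0.01, 30)
        out = accumulation_slope(self._series(vals))
        assert abs(out.slope_per_min - 0.02) < 3 * out.slope_se

    def test_unnormalized_rejected(self):
        from yolkflow.kinetics import IntensitySeries

        series = IntensitySeries(times_s=np.arange(5.0), values=np.ones(5),
                                 normalization="none")
        with pytest.raises(ValueError, match="first-frame"):
            accumulation_slope(series)
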