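"""Resampling, filtering, integration, alignment, synchronization and the
sliding-window statistics, checked against closed forms and direct-summation
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    DT_EXACT,
    F_EXACT,
    FS,
    brute_sliding_correlation,
    brute_sliding_variance,
)
from xcski.imu_io import GRAVITY, SensorRecording
from xcski.preprocess import (
    align_ski_sensor,
    bandpass,
    edge_mask,
    integrate_debias,
    resample,
    sliding_correlation,
    sliding_mean,
    sliding_variance,
    sync_lag,
    window_halfwidth,
)
from xcski.ski_orientation import gravity_forward


def _recording(t, gyro_col=None, accel=None, rate=None, placement="left_ski"):
    n = len(t)
    gyro = np.zeros((n, 3))
    if gyro_col is not None:
        gyro[:, 1] = gyro_col
    if accel is None:
        accel = np.tile([0.0, 0.0, -GRAVITY], (n, 1))
    return SensorRecording(placement=placement, rate=rate, t=t,
                           gyro=gyro, accel=accel)


class TestResample:
    def test_sinusoid_amplitude_preserved_256_to_20(self):
        rate, f = 256.0, 1.0
        t = np.arange(int(20 * rate)) / rate
        rec = _recording(t, np.sin(2 * np.pi * f * t), rate=rate)
        out = resample(rec, 20.0)
        assert out.rate == 20.0
        # compare to the analytic sinusoid on the new clock, away from edges
        ref = np.sin(2 * np.pi * f * out.t)
        sl = slice(20, -20)
        amp = np.max(np.abs(out.gyro[sl, 1]))
        assert abs(amp - 1.0) < 0.01
        assert np.max(np.abs(out.gyro[sl, 1] - ref[sl])) < 0.02

    def test_equal_rates_identity(self):
        t = np.arange(100) / 20.0
        rec = _recording(t, np.sin(t), rate=20.0)
        out = resample(rec, 20.0)
        np.testing.assert_array_equal(out.gyro, rec.gyro)

    def test_constant_stays_constant(self):
        t = np.arange(2560) / 256.0
        rec = _recording(t, np.full(len(t), 3.7), rate=256.0)
        out = resample(rec, 20.0)
        np.testing.assert_allclose(out.gyro[20:-20, 1], 3.7, atol=0.02)

    def test_upsampling_refused(self):
        t = np.arange(100) / 20.0
        rec = _recording(t, np.zeros(100), rate=20.0)
        with pytest.raises(ValueError, match="upsampling"):
            resample(rec, 40.0)


class TestBandpass:
    def test_dc_removed(self):
        x = np.full(2000, 5.0)
        y = bandpass(x, 0.3, 3.0, FS)
        assert np.max(np.abs(y)) < 1e-3 * 5.0

    def test_in_band_sinusoid_preserved(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        y = bandpass(x, 0.3, 3.0, FS)
        amp = np.max(np.abs(y[200:-200]))
        assert abs(amp - 1.0) < 0.05

    def test_out_of_band_sinusoid_attenuated(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 8.0 * t)
        y = bandpass(x, 0.3, 3.0, FS)
        assert np.max(np.abs(y[200:-200])) < 0.1

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        lhs = bandpass(2.0 * x - 3.0 * y, 0.3, 3.0, FS)
        rhs = 2.0 * bandpass(x, 0.3, 3.0, FS) - 3.0 * bandpass(y, 0.3, 3.0, FS)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            bandpass(np.zeros(100), 3.0, 0.3, FS)


class TestIntegrateDebias:
    def test_constant_rate_gives_centered_ramp(self):
        c, n = 4.0, 200
        out = integrate_debias(np.full(n, c), FS)
        ramp = c * np.arange(n) / FS
        np.testing.assert_allclose(out.theta, ramp - ramp.mean(), atol=1e-9)

    def test_cosine_rate_integrates_to_sine(self):
        A, f = 3.0, 1.0
        t = np.arange(int(10 * FS)) / FS  # integer number of periods
        rate = A * 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        out = integrate_debias(rate, FS)
        ref = A * np.sin(2 * np.pi * f * t)
        assert np.max(np.abs(out.theta - ref)) < 0.01 * A

    def test_zero_rate_zero_angle(self):
        out = integrate_debias(np.zeros(50), FS)
        np.testing.assert_array_equal(out.theta, np.zeros(50))

    def test_output_mean_is_zero(self):
        rng = np.random.default_rng(2)
        out = integrate_debias(rng.standard_normal(5000), FS)
        assert abs(out.theta.mean()) < 1e-9


class TestAlignSkiSensor:
    def test_already_aligned_is_identity(self):
        t = np.arange(100) / FS
        rec = _recording(t, rate=FS)
        out = align_ski_sensor(rec)
        np.testing.assert_allclose(out.accel, rec.accel, atol=1e-9)

    def test_tilted_static_sensor_restored(self):
        t = np.arange(200) / FS
        tilt = np.deg2rad(10.0)
        accel = np.tile(gravity_forward(tilt, 0.0), (200, 1))
        rec = _recording(t, accel=accel, rate=FS)
        out = align_ski_sensor(rec)
        mean = out.accel.mean(axis=0)
        np.testing.assert_allclose(mean, [0.0, 0.0, -GRAVITY], atol=1e-6)

    def test_idempotent(self):
        t = np.arange(200) / FS
        accel = np.tile(gravity_forward(0.2, -0.1), (200, 1))
        rec = _recording(t, accel=accel, rate=FS)
        once = align_ski_sensor(rec)
        twice = align_ski_sensor(once)
        np.testing.assert_allclose(twice.accel, once.accel, atol=1e-9)
        np.testing.assert_allclose(twice.gyro, once.gyro, atol=1e-9)

    def test_zero_accel_rejected(self):
        t = np.arange(100) / FS
        rec = _recording(t, accel=np.zeros((100, 3)), rate=FS)
        with pytest.raises(ValueError, match="mean specific force"):
            align_ski_sensor(rec)


class TestSyncLag:
    def test_constructed_delay_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(4000)
        shift = int(0.5 * FS)
        b = np.concatenate([np.zeros(shift), a[:-shift]])
        res = sync_lag(a, b, FS, highpass_cut=0.1)
        assert res.lag == pytest.approx(0.5, abs=1.0 / FS)
        assert not res.low_confidence

    def test_identical_series_zero_lag(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(2000)
        res = sync_lag(a, a, FS)
        assert res.lag == 0.0
        assert res.peak_correlation == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_flagged_low_confidence(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(10_000)
        b = rng.standard_normal(10_000)
        res = sync_lag(a, b, FS)
        assert abs(res.peak_correlation) < 0.2
        assert res.low_confidence

    def test_flat_input_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            sync_lag(np.zeros(2000), np.ones(2000), FS)


class TestSlidingStatistics:
    def test_constant_series_zero_variance(self):
        v = sliding_variance(np.full(200, 2.5), 1.3, FS)
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_sinusoid_interior_variance_half(self):
        # window of 51 samples spans exactly 3 periods of F_EXACT
        t = np.arange(400) / FS
        x = np.sin(2 * np.pi * F_EXACT * t)
        v = sliding_variance(x, DT_EXACT, FS)
        h = window_halfwidth(DT_EXACT, FS)
        np.testing.assert_allclose(v[h:-h], 0.5, atol=1e-9)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(3000) * 50 + 20
        v = sliding_variance(x, 1.3, FS)
        ref = brute_sliding_variance(x, 1.3, FS)
        np.testing.assert_allclose(v, ref, rtol=1e-9, atol=1e-12)

    def test_correlation_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(3000)
        y = 0.5 * x + rng.standard_normal(3000)
        r = sliding_correlation(x, y, 1.3, FS)
        ref = brute_sliding_correlation(x, y, 1.3, FS)
        np.testing.assert_allclose(r, ref, rtol=1e-9, atol=1e-9)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sliding_variance(np.zeros(10), 1.3, FS)

    def test_single_sample_moving_average_is_identity(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(sliding_mean(x, 0.01, FS), x)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=100.0),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_variance_nonnegative_and_scales_quadratically(self, c, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        v1 = sliding_variance(x, 1.3, FS)
        v2 = sliding_variance(c * x, 1.3, FS)
        assert np.all(v1 >= 0)
        np.testing.assert_allclose(v2, c * c * v1, rtol=1e-7, atol=1e-12)

    def test_edge_mask_marks_truncated_windows(self):
        m = edge_mask(100, 1.3, FS)
        h = window_halfwidth(1.3, FS)
        assert m[:h].all() and m[-h:].all()
        assert not m[h:-h].any()
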