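"""Preprocessing chain: filters, standardization, epoching, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scrlti import TimeSeries, EventSchedule
from scrlti.exceptions import (
    DegenerateInputError,
    InvalidParameterError,
)
from scrlti.signal_prep import (
    average_epochs,
    butter_filter,
    detect_clipping,
    downsample,
    extract_epochs,
    fir_bandpass_nerve,
    minimum_correct,
    piecewise_detrend,
    reconstruct_scr_from_derivative,
    rectified_leaky_integrate,
    zscore,
)


def _sine(freq, rate=100.0, duration=120.0, amp=1.0):
    t = np.arange(int(duration * rate)) / rate
    return TimeSeries(amp * np.sin(2 * np.pi * freq * t), rate=rate)


def _steady_amplitude(values, rate, skip_s=40.0):
    tail = values[int(skip_s * rate):]
    return (tail.max() - tail.min()) / 2.0


class TestButterFilter:
    def test_highpass_rejects_dc(self):
        # constant in, exponential decay out (10 s time constant)
        ts = TimeSeries(np.ones(12000), rate=100.0)
        out = butter_filter(ts, low_cut=0.0159, order=1)
        assert abs(out.values[-1]) < 1e-3
        tail = np.abs(out.values[100:])
        assert np.all(np.diff(tail) <= 1e-12)

    def test_lowpass_half_power_at_cutoff(self):
        # analog 1st-order magnitude at f = fc is 1/sqrt(2)
        ts = _sine(5.0, rate=1000.0, duration=20.0)
        out = butter_filter(ts, high_cut=5.0, order=1)
        ratio = _steady_amplitude(out.values, 1000.0, 10.0)
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_bandpass_passes_mid_band(self):
        # closed-form cascade magnitude at 0.5 Hz in the 0.0159-5 Hz band
        ts = _sine(0.5, rate=100.0, duration=200.0)
        out = butter_filter(ts, low_cut=0.0159, high_cut=5.0, order=1)
        amp = _steady_amplitude(out.values, 100.0, 100.0)
        expected = (1 / np.sqrt(1 + (0.0159 / 0.5) ** 2)) * (
            1 / np.sqrt(1 + (0.5 / 5.0) ** 2)
        )
        assert amp == pytest.approx(expected, rel=0.05)

    def test_cutoff_validation(self):
        ts = _sine(1.0, rate=10.0, duration=5.0)
        with pytest.raises(InvalidParameterError):
            butter_filter(ts, low_cut=6.0)
        with pytest.raises(InvalidParameterError):
            butter_filter(ts)

    def test_zero_maps_to_zero_and_length_preserved(self):
        ts = TimeSeries(np.zeros(500), rate=100.0)
        out = butter_filter(ts, low_cut=0.0159, high_cut=5.0)
        assert len(out) == 500
        np.testing.assert_allclose(out.values, 0.0)


class TestFirBandpassNerve:
    def test_zero_input(self):
        ts = TimeSeries(np.zeros(2000), rate=10000.0)
        out = fir_bandpass_nerve(ts)
        assert len(out) == 2000
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_passband_and_stopband(self):
        rate = 10000.0
        t = np.arange(int(rate)) / rate
        pass_ts = TimeSeries(np.sin(2 * np.pi * 1000 * t), rate=rate)
        stop_ts = TimeSeries(np.sin(2 * np.pi * 50 * t), rate=rate)
        amp_pass = _steady_amplitude(fir_bandpass_nerve(pass_ts).values, rate, 0.1)
        amp_stop = _steady_amplitude(fir_bandpass_nerve(stop_ts).values, rate, 0.1)
        assert 20 * np.log10(amp_pass) == pytest.approx(0.0, abs=1.0)
        assert 20 * np.log10(amp_stop / amp_pass) < -20.0

    def test_rate_too_low(self):
        with pytest.raises(InvalidParameterError):
            fir_bandpass_nerve(TimeSeries(np.zeros(100), rate=1000.0))

    def test_delay_compensation_keeps_burst_latency(self):
        rate = 10000.0
        rng = np.random.default_rng(0)
        t = np.arange(int(rate)) / rate
        env = np.exp(-((t - 0.5) ** 2) / (2 * 0.05**2))
        x = rng.normal(0, 1, t.size) * env
        out = fir_bandpass_nerve(TimeSeries(x, rate=rate))
        smooth = rectified_leaky_integrate(out, tau=0.05)
        assert abs(t[np.argmax(smooth.values)] - 0.5) < 0.1


class TestZscore:
    def test_moments(self):
        rng = np.random.default_rng(1)
        ts = TimeSeries(rng.normal(3.0, 2.0, 1000), rate=10.0)
        z = zscore(ts)
        assert abs(z.values.mean()) < 1e-10
        assert abs(z.values.std() - 1) < 1e-10

    def test_degenerate(self):
        with pytest.raises(DegenerateInputError):
            zscore(TimeSeries(np.ones(10), rate=10.0))

    @given(
        data=st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=60),
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_affine_invariant(self, data, a, b):
        x = np.asarray(data)
        if np.std(x) < 1e-6:
            return
        ts = TimeSeries(x, rate=10.0)
        z1 = zscore(ts).values
        np.testing.assert_allclose(zscore(zscore(ts)).values, z1, atol=1e-10)
        z2 = zscore(TimeSeries(a * x + b, rate=10.0)).values
        np.testing.assert_allclose(z2, z1, atol=1e-8)


class TestRectifiedLeakyIntegrate:
    def test_impulse_decay_ratio(self):
        ts = TimeSeries(np.r_[1.0, np.zeros(99)], rate=100.0)
        y = rectified_leaky_integrate(ts, tau=0.1).values
        alpha = np.exp(-0.01 / 0.1)
        ratios = y[2:20] / y[1:19]
        np.testing.assert_allclose(ratios, alpha, rtol=1e-10)

    def test_constant_converges_to_input(self):
        ts = TimeSeries(np.full(5000, 0.7), rate=100.0)
        y = rectified_leaky_integrate(ts, tau=0.1).values
        assert y[-1] == pytest.approx(0.7, rel=1e-6)

    def test_zero_and_nonnegative(self):
        rng = np.random.default_rng(2)
        ts = TimeSeries(rng.normal(0, 1, 500), rate=100.0)
        assert np.all(rectified_leaky_integrate(ts).values >= 0)
        zeros = TimeSeries(np.zeros(50), rate=100.0)
        np.testing.assert_allclose(rectified_leaky_integrate(zeros).values, 0.0)


class TestDownsample:
    def test_ramp_keeps_exact_samples(self):
        t = np.arange(1000) / 100.0
        out = downsample(TimeSeries(t, rate=100.0), 10.0)
        np.testing.assert_allclose(out.values, np.arange(100) / 10.0)
        assert out.rate == 10.0

    def test_identity_factor(self):
        ts = TimeSeries(np.arange(10.0), rate=10.0)
        np.testing.assert_array_equal(downsample(ts, 10.0).values, ts.values)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(InvalidParameterError):
            downsample(TimeSeries(np.arange(10.0), rate=25.0), 10.0)


class TestPiecewiseDetrend:
    def test_annihilates_global_line(self):
        t = np.arange(500) / 10.0
        out = piecewise_detrend(TimeSeries(3.0 * t - 7.0, rate=10.0), window=5.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_matches_per_window_ols_oracle(self):
        rng = np.random.default_rng(3)
        x = 0.5 * np.arange(240) / 10.0 + np.sin(2 * np.pi * 1.3 * np.arange(240) / 10.0)
        x += rng.normal(0, 0.1, 240)
        out = piecewise_detrend(TimeSeries(x, rate=10.0), window=5.0).values
        # brute-force oracle
        expect = x.copy()
        for i0 in range(0, 240, 50):
            seg = expect[i0:i0 + 50]
            tt = np.arange(seg.size, dtype=float)
            A = np.c_[tt, np.ones_like(tt)]
            beta, *_ = np.linalg.lstsq(A, seg, rcond=None)
            expect[i0:i0 + 50] = seg - A @ beta
        np.testing.assert_allclose(out, expect, atol=1e-9)

    def test_fast_sinusoid_survives(self):
        t = np.arange(600) / 10.0
        sine = np.sin(2 * np.pi * 1.0 * t)   # period 1 s << 5 s window
        out = piecewise_detrend(TimeSeries(2.0 * t + sine, rate=10.0), window=5.0)
        # amplitude of the 1 Hz component via quadrature projection
        s, c = np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)
        amp = np.hypot(2 * out.values @ s / len(t), 2 * out.values @ c / len(t))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_per_window_residual_properties(self):
        rng = np.random.default_rng(4)
        out = piecewise_detrend(
            TimeSeries(rng.normal(0, 1, 200), rate=10.0), window=5.0
        ).values
        for i0 in range(0, 200, 50):
            seg = out[i0:i0 + 50]
            assert abs(seg.mean()) < 1e-9
            assert abs(np.polyfit(np.arange(50.0), seg, 1)[0]) < 1e-9


class TestReconstruct:
    def test_alternating_series(self):
        ts = TimeSeries(np.tile([1.0, -1.0], 10), rate=10.0)
        out = reconstruct_scr_from_derivative(ts).values
        np.testing.assert_allclose(out, np.tile([1.0, 0.0], 10))

    def test_constant_maps_to_zero(self):
        out = reconstruct_scr_from_derivative(TimeSeries(np.full(30, 2.5), rate=10.0))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_roundtrip_with_first_difference(self, theta_low_rate):
        from scrlti import InputTrain, build_input_train, convolve_predict, \
            scrf_impulse_response

        train = build_input_train(InputTrain((10.0, 35.0)), rate=10.0, duration=120.0)
        ir = scrf_impulse_response(theta_low_rate, dt=0.1, duration=90.0)
        scr = convolve_predict(ir, train, gain=-1.0).values
        deriv = np.diff(scr, prepend=scr[0])
        rec = reconstruct_scr_from_derivative(TimeSeries(deriv, rate=10.0)).values
        assert np.corrcoef(rec, scr)[0, 1] > 0.99


class TestEpoching:
    def _series(self, n=400, rate=10.0):
        return TimeSeries(np.arange(n, dtype=float), rate=rate)

    def test_index_arithmetic(self):
        events = EventSchedule([10.0], ["a"])
        (ep,) = extract_epochs(self._series(), events)
        assert len(ep) == 300
        assert ep.values[0] == 50.0   # sample at t = 5 s

    def test_out_of_bounds_skipped_with_warning(self):
        events = EventSchedule([10.0, 39.0], ["a", "a"])
        with pytest.warns(UserWarning, match="skipped"):
            eps = extract_epochs(self._series(), events)
        assert len(eps) == 1

    def test_time_invariance_of_epoching(self):
        ts = TimeSeries(np.sin(np.arange(600) / 11.0), rate=10.0)
        ev = EventSchedule([10.0, 25.0], ["a", "a"])
        shifted = ev.shifted(1.0)   # 10 samples
        eps = extract_epochs(ts, ev)
        eps_shift = extract_epochs(ts, shifted)
        for e0, e1 in zip(eps, eps_shift):
            np.testing.assert_allclose(
                e1.values[:-10], e0.values[10:], atol=1e-12
            )

    def test_minimum_correct(self):
        events = EventSchedule([10.0], ["a"])
        (ep,) = extract_epochs(self._series(), events)
        out = minimum_correct(ep)
        assert out.values.min() == 0.0
        np.testing.assert_allclose(
            minimum_correct(out).values, out.values
        )
        # shape preserved
        np.testing.assert_allclose(np.diff(out.values), np.diff(ep.values))


class TestAverageEpochs:
    def _epoch(self, values, subject="s01", etype="a"):
        from scrlti.timeseries import Epoch

        return Epoch(values=values, subject=subject, event_type=etype)

    def test_identical_and_symmetry(self):
        x = np.sin(np.arange(300) / 10.0)
        avg = average_epochs([self._epoch(x), self._epoch(x.copy())])
        np.testing.assert_allclose(avg[("a",)].values, x)
        avg2 = average_epochs([self._epoch(x), self._epoch(-x)])
        np.testing.assert_allclose(avg2[("a",)].values, 0.0, atol=1e-12)

    def test_noise_suppression_clt(self):
        rng = np.random.default_rng(5)
        template = np.sin(np.arange(300) / 15.0)
        eps = [self._epoch(template + rng.normal(0, 1, 300)) for _ in range(10)]
        avg = average_epochs(eps)[("a",)].values
        assert np.all(np.abs(avg - template) < 3.0 / np.sqrt(10) * 3)

    def test_grouping_by_subject(self):
        a = self._epoch(np.zeros(300), subject="s01")
        b = self._epoch(np.ones(300), subject="s02")
        avg = average_epochs([a, b], by="subject_event_type")
        assert set(avg) == {("s01", "a"), ("s02", "a")}


class TestDetectClipping:
    def test_below_level_no_flags(self):
        ts = TimeSeries(np.sin(np.arange(100) / 5.0), rate=10.0)
        assert detect_clipping(ts, level=2.0) == []

    def test_single_run(self):
        x = np.zeros(50)
        x[10:15] = 3.0
        assert detect_clipping(TimeSeries(x, rate=10.0), level=3.0) == [(10, 15)]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 500)
        x[50:60] = 5.0
        x[200:204] = -5.0
        x[300:302] = 5.0   # too short to flag
        got = detect_clipping(TimeSeries(x, rate=10.0), level=4.0)
        # brute-force oracle
        flags = np.abs(x) >= 4.0
        runs = []
        i = 0
        while i < len(x):
            if flags[i]:
                j = i
                while j < len(x) and flags[j]:
                    j += 1
                if j - i >= 3:
                    runs.append((i, j))
                i = j
            else:
                i += 1
        assert got == runs == [(50, 60), (200, 204)]
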