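"""Inverse problems: burst fitting, response-function fitting, gains,
explained variance, partitioning, reference comparison, gain trend."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scrlti import (
    GaussianBurstParams,
    InputTrain,
    TimeSeries,
    build_input_train,
    compare_scrf_to_reference,
    classify_epochs_by_rate,
    estimate_gain,
    explained_variance,
    fit_gaussian_burst,
    fit_scrf,
    gain_trend,
    gaussian_burst,
    scrf_impulse_response,
    scrf_simulate,
    variance_partition,
)
from scrlti.exceptions import DegenerateInputError, InvalidInputError
from scrlti.models import GaussianBurstModel
from scrlti.timeseries import Epoch

from conftest import BURST_ODDBALL, THETA_LOW_RATE, THETA_MEDIUM_RATE


def _epoch_from(values):
    return Epoch(values=np.asarray(values, float))


def _ir_shape_r2(theta_est, theta_true, dt=0.1):
    a = scrf_impulse_response(theta_est, dt=dt).values
    b = scrf_impulse_response(theta_true, dt=dt).values
    X = np.c_[np.ones_like(a), a]
    beta, *_ = np.linalg.lstsq(X, b, rcond=None)
    resid = b - X @ beta
    return 1 - resid @ resid / np.sum((b - b.mean()) ** 2)


class TestFitGaussianBurst:
    def test_noiseless_published_oddball_recovery(self):
        t = np.arange(300) / 10.0 - 5.0
        ep = _epoch_from(gaussian_burst(t, BURST_ODDBALL).values)
        res = fit_gaussian_burst(ep)
        assert res.r2 > 0.9999
        assert res.params.A == pytest.approx(BURST_ODDBALL.A, rel=1e-3)
        assert res.params.mu == pytest.approx(BURST_ODDBALL.mu, rel=1e-3)
        assert res.params.sigma == pytest.approx(BURST_ODDBALL.sigma, rel=1e-3)
        assert abs(res.params.c) < 1e-3

    def test_constant_epoch_degenerates_to_baseline(self):
        res = fit_gaussian_burst(_epoch_from(np.full(300, 0.37)))
        assert abs(res.params.A) < 1e-2
        assert res.params.c == pytest.approx(0.37, abs=1e-2)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(7)
        t = np.arange(300) / 10.0 - 5.0
        clean = gaussian_burst(t, BURST_ODDBALL).values
        noisy = clean + rng.normal(0, 0.1 * clean.max(), clean.size)
        res = fit_gaussian_burst(_epoch_from(noisy))
        assert abs(res.params.mu - BURST_ODDBALL.mu) < 0.1
        assert abs(res.params.sigma - BURST_ODDBALL.sigma) < 0.2 * BURST_ODDBALL.sigma

    def test_summary_mentions_parameters(self):
        t = np.arange(300) / 10.0 - 5.0
        res = GaussianBurstModel(t, gaussian_burst(t, BURST_ODDBALL).values).fit()
        text = res.summary()
        assert "mu" in text and "R^2" in text


class TestFitScrf:
    def _make_data(self, theta, gain=1.0, noise_frac=0.0, seed=0):
        onsets = tuple(10.0 + 10.0 * k for k in range(10))
        train = build_input_train(InputTrain(onsets), rate=10.0, duration=140.0)
        clean = scrf_simulate(theta, train, gain=gain).values
        rng = np.random.default_rng(seed)
        y = clean + rng.normal(0, noise_frac * clean.std(), clean.size)
        return train, TimeSeries(y, rate=10.0)

    def test_noiseless_low_rate_recovery(self):
        train, obs = self._make_data(THETA_LOW_RATE, gain=1.0)
        res = fit_scrf(train, obs)
        assert res.r2 > 0.999
        assert _ir_shape_r2(res.params, THETA_LOW_RATE) > 0.99
        # theta-space is shallowly identified; the gain-scaled response area
        # g/theta3 is the identified quantity
        area_est = res.gain / res.params.theta3
        assert area_est == pytest.approx(1.0 / THETA_LOW_RATE.theta3, rel=0.02)

    def test_zero_observation_is_degenerate_not_fatal(self):
        train, _ = self._make_data(THETA_LOW_RATE)
        obs = TimeSeries(np.zeros(len(train)), rate=10.0)
        res = fit_scrf(train, obs)
        assert res.degenerate
        assert res.r2 == 1.0
        assert res.gain == 0.0

    def test_noisy_recovery_meets_analytic_floor(self):
        # 20% additive noise: R^2 ceiling 1/(1+0.04) ~ 0.96
        train, obs = self._make_data(THETA_LOW_RATE, noise_frac=0.2, seed=1)
        res = fit_scrf(train, obs)
        assert res.r2 >= 0.9

    def test_priors_pull_estimates(self):
        train, obs = self._make_data(THETA_LOW_RATE, noise_frac=0.2, seed=2)
        tight = {
            "theta1": (THETA_LOW_RATE.theta1, 1e-4),
            "theta2": (THETA_LOW_RATE.theta2, 1e-4),
            "theta3": (THETA_LOW_RATE.theta3, 1e-5),
        }
        res = fit_scrf(train, obs, priors=tight, start=THETA_LOW_RATE)
        assert res.params.theta1 == pytest.approx(THETA_LOW_RATE.theta1, rel=1e-2)
        assert res.params.theta3 == pytest.approx(THETA_LOW_RATE.theta3, rel=1e-2)


class TestEstimateGain:
    def test_exact_scaling(self):
        rng = np.random.default_rng(8)
        p = rng.normal(0, 1, 200)
        assert estimate_gain([p], [3.0 * p])[0] == pytest.approx(3.0, rel=1e-12)

    def test_orthogonal_gives_zero(self):
        p = np.r_[np.ones(50), np.zeros(50)]
        o = np.r_[np.zeros(50), np.ones(50)]
        assert estimate_gain([p], [o])[0] == 0.0

    def test_matches_closed_form(self):
        rng = np.random.default_rng(9)
        p, o = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
        g = estimate_gain([p], [o])[0]
        assert g == pytest.approx(float(p @ o) / float(p @ p), rel=1e-12)

    def test_fixed_mode_concatenates(self):
        rng = np.random.default_rng(10)
        ps = [rng.normal(0, 1, 50) for _ in range(3)]
        os_ = [2.0 * p + rng.normal(0, 0.1, 50) for p in ps]
        g = estimate_gain(ps, os_, mode="fixed")
        cp, co = np.concatenate(ps), np.concatenate(os_)
        assert g == pytest.approx(float(cp @ co) / float(cp @ cp), rel=1e-12)

    @given(a=st.floats(-10, 10).filter(lambda v: abs(v) > 1e-3))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, a):
        rng = np.random.default_rng(11)
        p, o = rng.normal(0, 1, 64), rng.normal(0, 1, 64)
        g1 = estimate_gain([p], [o])[0]
        g2 = estimate_gain([p], [a * o])[0]
        assert g2 == pytest.approx(a * g1, rel=1e-9, abs=1e-12)

    def test_zero_energy_predictor_flagged(self):
        g = estimate_gain([np.zeros(10)], [np.ones(10)])
        assert np.isnan(g[0])


class TestExplainedVariance:
    def test_perfect_and_mean_predictor(self):
        rng = np.random.default_rng(12)
        o = rng.normal(0, 1, 100)
        assert explained_variance([o], [o]) == 1.0
        assert explained_variance([np.full(100, o.mean())], [o]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(13)
        o = rng.normal(0, 1, 80)
        p = 0.5 * o + rng.normal(0, 0.5, 80)
        expect = 1 - np.sum((o - p) ** 2) / np.sum((o - o.mean()) ** 2)
        assert explained_variance([p], [o]) == pytest.approx(expect, rel=1e-12)

    def test_degenerate_observed(self):
        with pytest.raises(DegenerateInputError):
            explained_variance([np.ones(10)], [np.ones(10)])


class TestVariancePartition:
    def _dataset(self, per_subject_shift=0.0, noise=0.05, seed=0):
        """Epochs from two subjects; optionally subject-specific response
        shapes; returns observed and canonical/subject predictions."""
        rng = np.random.default_rng(seed)
        t = np.arange(300) / 10.0
        base = np.exp(-((t - 8) ** 2) / 8.0)
        obs, pc, ps, subjects = [], [], [], []
        for s, shift in (("s01", 0.0), ("s02", per_subject_shift)):
            shape = np.exp(-((t - 8 - shift) ** 2) / 8.0)
            for _ in range(5):
                g = rng.uniform(0.8, 1.2)
                o = g * shape + rng.normal(0, noise, t.size)
                obs.append(o)
                pc.append(base * float(base @ o) / float(base @ base))
                ps.append(shape * float(shape @ o) / float(shape @ shape))
                subjects.append(s)
        return obs, pc, ps, subjects

    def test_shared_shape_gives_no_subject_extra(self):
        obs, pc, ps, subjects = self._dataset(0.0)
        part = variance_partition(obs, pc, ps, subjects=subjects)
        assert part.subject_extra < 0.01
        assert part.canonical > 0.9

    def test_distinct_shapes_give_subject_extra(self):
        obs, pc, ps, subjects = self._dataset(3.0)
        part = variance_partition(obs, pc, ps, subjects=subjects)
        assert part.subject_extra > 0.05

    def test_fractions_sum_to_one_and_nonnegative(self):
        obs, pc, ps, subjects = self._dataset(1.0, noise=0.3, seed=3)
        part = variance_partition(obs, pc, ps, subjects=subjects)
        total = part.canonical + part.subject_extra + part.residual
        assert total == pytest.approx(1.0, abs=1e-9)
        assert part.subject_extra >= 0.0

    def test_conservative_fallback_enforces_monotonicity(self):
        # subject predictions deliberately worse than canonical
        rng = np.random.default_rng(4)
        obs = [rng.normal(0, 1, 50) + 3 * np.sin(np.arange(50) / 5) for _ in range(4)]
        pc = [3 * np.sin(np.arange(50) / 5)] * 4
        ps = [np.zeros(50)] * 4
        part = variance_partition(obs, pc, ps, subjects=["a", "a", "b", "b"])
        assert part.subject_extra == 0.0


class TestCompareScrfToReference:
    def test_self_comparison(self, theta_low_rate):
        ir = scrf_impulse_response(theta_low_rate)
        cmp_ = compare_scrf_to_reference(ir, ir)
        assert cmp_.r2 == pytest.approx(1.0, abs=1e-12)
        assert cmp_.shift_s == 0.0

    def test_affine_invariance(self, theta_low_rate):
        ir = scrf_impulse_response(theta_low_rate)
        scaled = ir.copy_with(values=2.5 * ir.values - 0.3)
        assert compare_scrf_to_reference(scaled, ir).r2 == pytest.approx(1.0, abs=1e-9)

    def test_shift_is_recovered(self, theta_low_rate):
        ir = scrf_impulse_response(theta_low_rate, dt=0.1, duration=30.0)
        shifted = ir.copy_with(values=np.r_[np.zeros(13), ir.values[:-13]])
        cmp_ = compare_scrf_to_reference(shifted, ir)
        assert cmp_.r2 > 0.999
        assert cmp_.shift_s == pytest.approx(1.3, abs=0.11)

    def test_white_noise_scores_near_zero(self, theta_low_rate):
        rng = np.random.default_rng(5)
        ir = scrf_impulse_response(theta_low_rate, dt=0.1, duration=30.0)
        noise = ir.copy_with(values=rng.normal(0, 1, len(ir)))
        assert compare_scrf_to_reference(noise, ir, allow_shift=False).r2 < 0.05


class TestGainTrend:
    def _frame(self, slope, noise=0.0, n_per=20, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s, icpt in (("s01", 1.0), ("s02", 1.5)):
            for rep in range(1, n_per + 1):
                rows.append(
                    {
                        "subject": s,
                        "repetition": rep,
                        "gain": icpt + slope * rep + rng.normal(0, noise),
                    }
                )
        return pd.DataFrame(rows)

    def test_exact_linear_trend(self):
        res = gain_trend(self._frame(0.1))
        assert res.slope == pytest.approx(0.1, abs=1e-9)

    def test_constant_gains(self):
        res = gain_trend(self._frame(0.0))
        assert res.slope == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_within_two_se(self):
        res = gain_trend(self._frame(-0.05, noise=0.1, n_per=100, seed=6))
        assert abs(res.slope - (-0.05)) < 2 * res.se

    def test_single_repetition_rejected(self):
        df = pd.DataFrame(
            {"subject": ["a", "b"], "repetition": [1, 1], "gain": [1.0, 2.0]}
        )
        with pytest.raises(InvalidInputError):
            gain_trend(df)


class TestClassifyEpochsByRate:
    def test_rate_classes(self):
        onsets = [
            np.arange(0, 100, 10.0),   # 0.1 Hz -> low
            np.arange(0, 40, 2.0),     # 0.5 Hz -> medium
            np.arange(0, 20, 1.0),     # 1 Hz -> high
            np.arange(0, 5, 0.1),      # 10 Hz -> excluded
            np.array([3.0]),           # rate undefined
        ]
        assert classify_epochs_by_rate(onsets) == [
            "low", "medium", "high", "excluded", "undefined",
        ]

    def test_generated_rates_classification(self):
        # trains at 0.1/0.2/0.5/1/1.5 Hz map to low/medium/medium/high/high
        rates = [0.1, 0.2, 0.5, 1.0, 1.5]
        onsets = [np.arange(0, 60, 1.0 / r) for r in rates]
        assert classify_epochs_by_rate(onsets) == [
            "low", "medium", "medium", "high", "high",
        ]
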