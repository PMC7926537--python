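"""HAND counter: filtering, calibration rules, counting state machine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from manucount import (
    ConfigurationError,
    HandCounter,
    HandCountParams,
    InsufficientDataError,
    calibrate,
    derive_run_requirements,
    hand_count,
    intensity,
    lowpass,
    parameter_sweep,
)
from manucount.hand_algorithm import CalibrationResult, round_half_away_from_zero
from manucount.sensor_model import DifferentialLog

from .reference import reference_hand_count, reference_run_lengths

FS = 52.6


def _diff(values, fs=FS):
    values = np.asarray(values, float)
    return DifferentialLog(t=np.arange(len(values)) / fs, d=values)


# ---------------------------------------------------------------------------
# Filter


class TestLowpass:
    def test_unit_dc_gain_on_constant(self):
        x = np.full((200, 3), 37.0)
        y = lowpass(x, 8.0, FS)
        assert np.allclose(y, 37.0, atol=1e-9)

    def test_none_cutoff_is_passthrough(self, rng):
        x = rng.normal(size=(100, 3))
        assert np.array_equal(lowpass(x, None, FS), x)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            lowpass(np.zeros((10, 3)), FS / 2, FS)

    def test_white_noise_variance_matches_spectral_oracle(self, rng):
        """Output variance equals the integral of |H(f)|^2 over the band."""
        x = rng.normal(size=(400_000, 1))
        y = lowpass(x, 8.0, FS)[5000:]
        b, a = sps.butter(2, 8.0, fs=FS)
        w, h = sps.freqz(b, a, worN=1 << 16)
        expected = np.trapezoid(np.abs(h) ** 2, w) / np.pi
        assert np.var(y) == pytest.approx(expected, rel=0.05)


# ---------------------------------------------------------------------------
# Calibration rules


class TestRunRequirements:
    def test_worked_example_sigma_1p5(self, default_params):
        """sigma 1.5 scaled by 4 -> at least 6 same-direction samples."""
        params = HandCountParams(sds_two_axes=4)
        assert derive_run_requirements(1.5, params).n_two_axes == 6

    def test_rounding_and_one_axis_addition(self):
        """sigma 1.2, scale 4, 3 extra samples -> runs of 5 and 8."""
        params = HandCountParams(sds_two_axes=4, extra_samples_one_axis=3)
        calib = derive_run_requirements(1.2, params)
        assert (calib.n_two_axes, calib.n_one_axis) == (5, 8)

    @pytest.mark.parametrize("x, expected", [(4.5, 5), (4.4, 4), (-4.5, -5), (6.5, 7)])
    def test_round_half_away_from_zero(self, x, expected):
        assert round_half_away_from_zero(x) == expected

    def test_two_axis_requirement_floor_is_one(self):
        params = HandCountParams(sds_two_axes=1)
        assert derive_run_requirements(0.01, params).n_two_axes == 1

    def test_alternative_extra_sds_mode(self):
        params = HandCountParams(sds_two_axes=4, extra_samples_one_axis=3,
                                 one_axis_mode="extra_sds")
        calib = derive_run_requirements(1.2, params)
        assert calib.n_one_axis == round_half_away_from_zero(7 * 1.2)


class TestCalibrate:
    def test_sigma_matches_monte_carlo_geometric_oracle(self, rng):
        """iid sign-symmetric supra-threshold changes give geometric runs
        (p = 1/2); the measured run-length SD matches a Monte-Carlo
        estimate from 1e6 simulated runs within 2%."""
        params = HandCountParams(lp_cutoff=None, threshold=5.0)
        steps = rng.choice([-10.0, 10.0], size=(400_000, 3))
        log = _diff(np.cumsum(steps, axis=0))
        sigma = calibrate(log, params).sigma
        mc = np.std(rng.geometric(0.5, size=1_000_000), ddof=1)
        assert sigma == pytest.approx(mc, rel=0.02)

    def test_run_survival_follows_two_to_minus_n(self, rng):
        """P(run length >= n) = 2^-(n-1) for iid sign-symmetric noise."""
        params = HandCountParams(lp_cutoff=None, threshold=5.0)
        steps = rng.choice([-10.0, 10.0], size=(300_000, 1))
        runs = np.asarray(reference_run_lengths(steps[:, 0], 5.0))
        for n in (2, 4, 6):
            p = np.mean(runs >= n)
            expected = 2.0 ** -(n - 1)
            se = np.sqrt(expected * (1 - expected) / runs.size)
            assert abs(p - expected) < 3 * se

    def test_pooled_run_lengths_match_reference(self, rng):
        params = HandCountParams(lp_cutoff=None, threshold=3.0)
        d = rng.normal(0, 6, size=(5000, 3)).cumsum(axis=0)
        calib = calibrate(_diff(d), params)
        pooled = []
        for axis in range(3):
            pooled.extend(reference_run_lengths(np.diff(d[:, axis]), 3.0))
        assert calib.n_runs == len(pooled)
        assert calib.sigma == pytest.approx(np.std(pooled, ddof=1))

    def test_insufficient_runs_raises(self):
        params = HandCountParams()
        quiet = _diff(np.zeros((200, 3)))
        with pytest.raises(InsufficientDataError):
            calibrate(quiet, params)


# ---------------------------------------------------------------------------
# Counting


class TestHandCount:
    def test_constant_input_counts_nothing(self, default_params, fixed_calibration):
        count, events = hand_count(_diff(np.full((300, 3), 50.0)),
                                   default_params, fixed_calibration)
        assert count == 0 and events == []

    def test_two_axis_ramp_counts_once(self, fixed_calibration):
        """A monotone supra-threshold ramp on two axes fires one count."""
        params = HandCountParams(lp_cutoff=None)
        d = np.zeros((40, 3))
        ramp = np.arange(40) * 20.0  # +20 LSB per sample > threshold 8
        d[:, 0] = ramp
        d[:, 2] = ramp
        count, events = hand_count(_diff(d), params,
                                   CalibrationResult(1.2, 6, 8, threshold=8.0))
        assert count == 1
        assert events[0].trigger == "two_axes"
        assert set(events[0].axes) == {"x", "z"}
        assert events[0].t == pytest.approx(6 / FS)  # 6th supra-threshold change

    def test_single_axis_needs_longer_run(self):
        params = HandCountParams(lp_cutoff=None)
        calib = CalibrationResult(1.2, 6, 8, threshold=8.0)
        d = np.zeros((40, 3))
        d[:, 1] = np.arange(40) * 20.0
        count, events = hand_count(_diff(d), params, calib)
        assert count == 1
        assert events[0].trigger == "one_axis"
        assert events[0].t == pytest.approx(8 / FS)

    def test_sub_threshold_samples_preserve_runs(self):
        """Changes within the threshold neither extend nor break a run."""
        params = HandCountParams(lp_cutoff=None)
        calib = CalibrationResult(1.0, 3, 5, threshold=8.0)
        # supra, sub, supra, sub, supra -> run of 3 on both axes
        steps = [20.0, 1.0, 20.0, -1.0, 20.0]
        d = np.zeros((len(steps) + 1, 3))
        d[1:, 0] = np.cumsum(steps)
        d[1:, 2] = np.cumsum(steps)
        count, events = hand_count(_diff(d), params, calib)
        assert count == 1
        assert events[0].t == pytest.approx(5 / FS)

    def test_reversal_restarts_run(self):
        params = HandCountParams(lp_cutoff=None)
        calib = CalibrationResult(1.0, 4, 6, threshold=8.0)
        steps = [20.0, 20.0, 20.0, -20.0, 20.0, 20.0, 20.0]  # reversal at step 4
        d = np.zeros((len(steps) + 1, 3))
        d[1:, 0] = np.cumsum(steps)
        d[1:, 1] = np.cumsum(steps)
        count, events = hand_count(_diff(d), params, calib)
        assert count == 0  # no run ever reaches 4

    def test_suppression_lifts_on_reversal_then_timeout(self):
        params = HandCountParams(lp_cutoff=None)
        calib = CalibrationResult(1.0, 3, 5, threshold=8.0)
        up = [20.0] * 3
        down = [-20.0] * 3
        quiet = [0.0] * 10
        steps = up + quiet + down + quiet
        d = np.zeros((len(steps) + 1, 3))
        d[1:, 0] = np.cumsum(steps)
        d[1:, 1] = np.cumsum(steps)
        count, events = hand_count(_diff(d), params, calib)
        # second (reversed) ramp both lifts suppression and builds a new run
        assert count == 2
        assert events[1].t > events[0].t

    def test_sign_flip_invariance(self, rng, default_params, fixed_calibration):
        d = rng.normal(0, 30, size=(2000, 3)).cumsum(axis=0)
        c1, e1 = hand_count(_diff(d), default_params, fixed_calibration)
        c2, e2 = hand_count(_diff(-d), default_params, fixed_calibration)
        assert c1 == c2
        assert [e.t for e in e1] == [e.t for e in e2]

    def test_determinism(self, rng, default_params, fixed_calibration):
        d = rng.normal(0, 30, size=(1500, 3)).cumsum(axis=0)
        r1 = hand_count(_diff(d), default_params, fixed_calibration)
        r2 = hand_count(_diff(d), default_params, fixed_calibration)
        assert r1 == r2

    def test_threshold_mismatch_rejected(self, default_params):
        calib = CalibrationResult(1.2, 6, 8, threshold=16.0, lp_cutoff=8.0)
        with pytest.raises(ConfigurationError):
            hand_count(_diff(np.zeros((10, 3))), default_params, calib)

    def test_events_within_two_seconds_require_reversal(self, rng, default_params,
                                                        fixed_calibration):
        """Monotone event separation: close-together events imply an
        intervening supra-threshold reversal on a triggering axis."""
        d = rng.normal(0, 40, size=(4000, 3)).cumsum(axis=0)
        _, events = hand_count(_diff(d), default_params, fixed_calibration)
        y = lowpass(d, default_params.lp_cutoff, FS)
        delta = np.diff(y, axis=0)
        t = np.arange(len(d)) / FS
        checked = 0
        for prev, nxt in zip(events, events[1:]):
            if nxt.t - prev.t >= default_params.reset_timeout:
                continue
            k0 = int(round(prev.t * FS))
            k1 = int(round(nxt.t * FS))
            axes_idx = ["xyz".index(a) for a in prev.axes]
            reversed_ = False
            for a in axes_idx:
                seg = delta[k0 : k1 + 1, a]
                direction = np.sign(delta[k0 - 1, a])
                if np.any((np.abs(seg) > default_params.threshold)
                          & (np.sign(seg) == -direction)):
                    reversed_ = True
            assert reversed_
            checked += 1
        assert checked > 0  # the random walk must actually exercise this path


class TestOracleEquivalence:
    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_matches_literal_transliteration(self, fixed_calibration, data):
        """Streaming implementation equals an offline replay of the rules."""
        n = data.draw(st.integers(min_value=5, max_value=400))
        seed = data.draw(st.integers(min_value=0, max_value=2**31 - 1))
        rng = np.random.default_rng(seed)
        d = rng.integers(-100, 100, size=(n, 3)).astype(float)
        params = HandCountParams(
            lp_cutoff=data.draw(st.sampled_from([None, 8.0])),
            threshold=data.draw(st.sampled_from([0.0, 8.0, 16.0])),
        )
        calib = CalibrationResult(
            sigma=1.2,
            n_two_axes=data.draw(st.integers(2, 8)),
            n_one_axis=data.draw(st.integers(8, 12)),
            threshold=params.threshold,
            lp_cutoff=params.lp_cutoff,
        )
        t = np.arange(n) / FS
        count, events = hand_count(DifferentialLog(t, d), params, calib)
        ref = reference_hand_count(
            t, d, params.threshold, calib.n_two_axes, calib.n_one_axis,
            params.lp_cutoff, FS,
        )
        assert count == len(ref)
        assert [e.t for e in events] == [r["t"] for r in ref]
        assert [e.trigger for e in events] == [r["trigger"] for r in ref]

    def test_streaming_equals_batch_on_many_random_sequences(self, default_params,
                                                             fixed_calibration):
        """Sample-by-sample processing reproduces the batch events exactly."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(5, 120))
            d = DifferentialLog(
                np.arange(n) / FS,
                rng.integers(-100, 100, size=(n, 3)).astype(float),
            )
            _, batch = hand_count(d, default_params, fixed_calibration)
            counter = HandCounter(default_params, fixed_calibration)
            stream = [
                e
                for e in (counter.process(float(t), row) for t, row in zip(d.t, d.d))
                if e is not None
            ]
            assert [(e.t, e.trigger, e.axes) for e in batch] == [
                (e.t, e.trigger, e.axes) for e in stream
            ]


class TestFalsePositiveRate:
    def test_event_rate_matches_monte_carlo_oracle(self):
        """On iid sign-symmetric supra-threshold noise the event count
        agrees with an independent replay on fresh noise within 3 SE."""
        params = HandCountParams(lp_cutoff=None, threshold=5.0)
        calib = CalibrationResult(1.4, 6, 8, threshold=5.0, lp_cutoff=None)
        n = 60_000
        rng = np.random.default_rng(21)
        d = np.cumsum(rng.choice([-10.0, 10.0], size=(n, 3)), axis=0)
        t = np.arange(n) / FS
        count, _ = hand_count(DifferentialLog(t, d), params, calib)
        rng2 = np.random.default_rng(22)
        d2 = np.cumsum(rng2.choice([-10.0, 10.0], size=(n, 3)), axis=0)
        ref = len(reference_hand_count(t, d2, 5.0, 6, 8, None, FS))
        assert count > 50  # the regime actually produces events
        assert abs(count - ref) <= 3 * np.sqrt(count + ref)


# ---------------------------------------------------------------------------
# Sweep and intensity


class TestSweepAndIntensity:
    def test_errors_computed_per_definition(self, rng):
        params = HandCountParams(lp_cutoff=None, threshold=5.0)
        # arm logs: iid noise (false positives only); hand log: noise + ramps
        arm = np.cumsum(rng.choice([-10.0, 10.0], size=(20_000, 3)), axis=0)
        hand = arm.copy()
        table = parameter_sweep(
            hand_logs=[(_diff(hand), 50)],
            arm_logs=[(_diff(arm), 200)],
            grid=[params],
        )
        calib = calibrate(_diff(arm), params)
        expected, _ = hand_count(_diff(arm), params, calib)
        row = table.iloc[0]
        assert row.arm_error_pct == pytest.approx(expected / 200 * 100)
        assert row.hand_error_pct == pytest.approx(abs(expected - 50) / 50 * 100)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            parameter_sweep([], [], [])

    @pytest.mark.parametrize(
        "n, hours, per_hour, per_minute",
        [(0, 5.0, 0.0, 0.0), (1000, 1.0, 1000.0, 1000 / 60), (50, 1 / 60, 3000.0, 50.0)],
    )
    def test_intensity(self, n, hours, per_hour, per_minute):
        ph, pm = intensity(n, hours)
        assert ph == pytest.approx(per_hour)
        assert pm == pytest.approx(per_minute)

    def test_zero_duration_rejected(self):
        with pytest.raises(ConfigurationError):
            intensity(5, 0.0)
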