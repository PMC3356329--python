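"""Beat detection and per-beat metrics."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cardioafm.beats import (
    GAUSSIAN_FWHM_FACTOR,
    compare_conditions,
    detect_beats,
    estimate_baseline,
    fraction_above_rate,
    smoothed_histogram,
    summarize_beats,
    BeatEvent,
)
from cardioafm.exceptions import DegenerateInputError
from cardioafm.synthetic import BeatTrainConfig, simulate_beat_trajectory
from cardioafm.trajectory import ForceTrajectory


def make_train(**kw):
    defaults = dict(duration=30.0, beat_rate_mean=1.0, beat_rate_cv=0.0,
                    amplitude_mean=1e-9, amplitude_cv=0.0, fwhm_mean=0.2,
                    fwhm_cv=0.0, peak_shape="gaussian", noise_sd=0.0, seed=0)
    defaults.update(kw)
    return simulate_beat_trajectory(BeatTrainConfig(**defaults))


class TestBaseline:
    def test_constant_input_gives_constant_baseline(self):
        traj = ForceTrajectory(np.arange(4000) / 2000.0, np.full(4000, 0.5e-9), 2000.0)
        bl = estimate_baseline(traj)
        np.testing.assert_allclose(bl, 0.5e-9, rtol=1e-12)

    def test_noiseless_train_baseline_near_zero(self):
        traj = make_train(duration=20.0)
        bl = estimate_baseline(traj)
        assert np.max(np.abs(bl)) < 0.01 * 1e-9  # within 1% of peak amplitude

    def test_linear_ramp_tracked_within_percentile_offset(self):
        # oracle: direct sliding-window percentile of the same ramp
        fs, n = 2000.0, 20000
        t = np.arange(n) / fs
        ramp = 1e-9 * t / 10.0
        bl = estimate_baseline(ramp, window=2.0, percentile=10.0, sampling_rate=fs)
        w = int(2.0 * fs)
        interior = slice(w, n - w)
        oracle = np.array([np.percentile(ramp[i - w // 2:i + w // 2], 10.0)
                           for i in range(w, n - w, 500)])
        got = bl[w:n - w:500]
        np.testing.assert_allclose(got, oracle, atol=2e-13)

    def test_window_longer_than_recording_warns(self):
        traj = ForceTrajectory(np.arange(1000) / 2000.0,
                               np.random.default_rng(0).normal(0, 1e-12, 1000), 2000.0)
        with pytest.warns(UserWarning, match="window longer"):
            estimate_baseline(traj, window=10.0)


class TestDetection:
    def test_noiseless_train_counts_forces_rates(self):
        traj = make_train()
        events = detect_beats(traj)
        truth = traj.metadata["truth"]
        assert len(events) == len(truth["beat_times"])
        for e in events:
            assert e.force == pytest.approx(1e-9, rel=5e-3)
        rates = [e.rate_to_next for e in events if e.rate_to_next is not None]
        assert np.allclose(rates, 1.0, rtol=1e-3)

    def test_gaussian_fwhm_closed_form(self):
        sigma = 0.1
        traj = make_train(fwhm_mean=GAUSSIAN_FWHM_FACTOR * sigma)
        events = detect_beats(traj)
        dt = 1.0 / traj.sampling_rate
        for e in events:
            assert abs(e.fwhm - GAUSSIAN_FWHM_FACTOR * sigma) <= dt

    def test_pure_noise_yields_zero_events(self):
        traj = make_train(beat_rate_mean=0.0, noise_sd=20e-12, duration=120.0, seed=9)
        assert detect_beats(traj) == []

    def test_translation_invariance(self):
        traj = make_train(noise_sd=20e-12, seed=4)
        shifted = ForceTrajectory(traj.time, traj.force + 0.7e-9, traj.sampling_rate)
        e1, e2 = detect_beats(traj), detect_beats(shifted)
        assert len(e1) == len(e2)
        for a, b in zip(e1, e2):
            assert a.force == pytest.approx(b.force, abs=1e-13)
            assert a.t_peak == pytest.approx(b.t_peak, abs=1e-4)

    @given(offset=st.floats(-2e-9, 2e-9))
    def test_shift_never_changes_beat_count(self, offset):
        traj = make_train(duration=10.0, noise_sd=20e-12, seed=6)
        shifted = ForceTrajectory(traj.time, traj.force + offset, traj.sampling_rate)
        assert len(detect_beats(shifted)) == len(detect_beats(traj))

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            traj = ForceTrajectory(np.array([0.0, 1.0]), np.zeros(2), 1.0)
            traj.time = np.empty(0)
            traj.force = np.empty(0)
            detect_beats(traj)

    def test_noisy_recovery_within_tolerances(self):
        # the workhorse property: 20 pN noise, physiological beat
        cfg = BeatTrainConfig(duration=120.0, amplitude_mean=0.5e-9,
                              amplitude_cv=0.1, beat_rate_mean=1.0,
                              beat_rate_cv=0.1, fwhm_mean=0.25, fwhm_cv=0.05,
                              seed=21)
        traj = simulate_beat_trajectory(cfg)
        events = detect_beats(traj)
        truth = traj.metadata["truth"]
        assert len(events) == len(truth["beat_times"])
        mf = np.mean([e.force for e in events])
        assert mf == pytest.approx(truth["amplitudes"].mean(), abs=40e-12)
        rates = [e.rate_to_next for e in events if e.rate_to_next is not None]
        assert np.mean(rates) == pytest.approx(truth["rates"].mean(), rel=0.01)
        fw = [e.fwhm for e in events if math.isfinite(e.fwhm)]
        assert abs(np.mean(fw) - truth["fwhms"].mean()) < 2.0 / traj.sampling_rate


class TestSummaries:
    def test_mean_sd_cv(self):
        events = [BeatEvent(i, f, 0.2, 1.0) for i, f in
                  enumerate([1e-9, 2e-9, 3e-9])]
        s = summarize_beats(events)
        assert s.force.mean == pytest.approx(2e-9)
        assert s.force.sd == pytest.approx(1e-9)
        assert s.force.cv == pytest.approx(0.5)

    def test_single_beat_flags_undefined_spread(self):
        s = summarize_beats([BeatEvent(0.0, 1e-9, 0.2, None)])
        assert s.n_beats == 1
        assert math.isnan(s.force.sd) and math.isnan(s.force.cv)

    def test_empty_input_flags_everything(self):
        s = summarize_beats([])
        assert s.n_beats == 0 and math.isnan(s.force.mean)

    def test_amplitude_cv_recovered_from_simulated_train(self):
        cfg = BeatTrainConfig(duration=110.0, beat_rate_mean=1.0,
                              amplitude_mean=1e-9, amplitude_cv=0.05,
                              fwhm_mean=0.2, seed=13)
        events = detect_beats(simulate_beat_trajectory(cfg))
        s = summarize_beats(events)
        assert s.force.n >= 90
        assert 0.03 < s.force.cv < 0.07

    @pytest.mark.parametrize("rates, cutoff, expected", [
        ([1.0, 1.8, 2.0, 1.5], 1.7, 0.5),
        ([1.0, 1.2], 0.5, 1.0),
        ([1.0, 1.2], 3.0, 0.0),
    ])
    def test_fraction_above_rate(self, rates, cutoff, expected):
        events = [BeatEvent(float(i), 1e-9, 0.2, r) for i, r in enumerate(rates)]
        assert fraction_above_rate(events, cutoff) == expected

    def test_fraction_without_rates_rejected(self):
        with pytest.raises(ValueError):
            fraction_above_rate([BeatEvent(0.0, 1e-9, 0.2, None)], 1.0)


class TestSmoothedHistogram:
    def test_standard_normal_density_at_zero(self, rng):
        values = rng.standard_normal(10000)
        curve = smoothed_histogram(values)
        d0 = np.interp(0.0, curve.x, curve.density)
        assert d0 == pytest.approx(1.0 / math.sqrt(2 * math.pi), rel=0.05)

    def test_unit_integral(self, rng):
        curve = smoothed_histogram(rng.normal(2.0, 0.5, 500))
        assert curve.integral() == pytest.approx(1.0, abs=1e-6)

    def test_shift_equivariance(self, rng):
        v = rng.standard_normal(400)
        c1 = smoothed_histogram(v)
        c2 = smoothed_histogram(v + 5.0)
        np.testing.assert_allclose(c2.x, c1.x + 5.0, atol=1e-9)
        np.testing.assert_allclose(c2.density, c1.density, rtol=1e-9)

    def test_degenerate_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            smoothed_histogram(np.full(10, 1.0))


class TestConditionComparison:
    def _events(self, forces):
        return [BeatEvent(float(i), f, 0.2, 1.0) for i, f in enumerate(forces)]

    def test_fold_change(self, rng):
        pre = self._events(rng.normal(0.1e-9, 0.005e-9, 30))
        post = self._events(rng.normal(0.26e-9, 0.005e-9, 30))
        cmp_ = compare_conditions(pre, post)
        assert cmp_.fold_change_force == pytest.approx(2.6, rel=0.05)
        assert cmp_.p_force < 1e-6

    def test_identical_samples(self):
        ev = self._events([1e-9, 1.1e-9, 0.9e-9])
        cmp_ = compare_conditions(ev, list(ev))
        assert cmp_.fold_change_force == pytest.approx(1.0)
        assert cmp_.p_force > 0.99

    def test_welch_close_to_exact_permutation_small_n(self, rng):
        pre = self._events(rng.normal(1.0e-9, 0.2e-9, 5))
        post = self._events(rng.normal(1.5e-9, 0.2e-9, 5))
        cmp_ = compare_conditions(pre, post, permutation=True, seed=0)
        # C(10,5) = 252 labelings are fully enumerated internally
        assert cmp_.p_force_permutation == pytest.approx(cmp_.p_force, abs=0.06)

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions(self._events([1e-9]), self._events([1e-9, 2e-9]))
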