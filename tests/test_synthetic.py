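"""Generators: determinism, noiseless construction, physical identities."""
import math

import numpy as np
import pytest

from cardioafm.exceptions import ConfigError
from cardioafm.hertz import hertz_force
from cardioafm.synthetic import (
    BeatTrainConfig,
    DoseResponseConfig,
    DwellMapConfig,
    HertzCurveConfig,
    MixtureComponent,
    hill_response,
    simulate_beat_trajectory,
    simulate_dose_response,
    simulate_dwell_map,
    simulate_force_curve,
    simulate_thermal_noise,
)

K_B = 1.380649e-23


class TestBeatTrain:
    def test_deterministic_given_seed(self):
        cfg = BeatTrainConfig(duration=10.0, seed=42)
        a = simulate_beat_trajectory(cfg)
        b = simulate_beat_trajectory(cfg)
        np.testing.assert_array_equal(a.force, b.force)

    def test_noiseless_train_peaks_at_configured_amplitude(self):
        cfg = BeatTrainConfig(duration=5.0, beat_rate_mean=1.0, beat_rate_cv=0.0,
                              amplitude_mean=1e-9, amplitude_cv=0.0,
                              fwhm_mean=0.2, fwhm_cv=0.0, noise_sd=0.0, seed=0)
        traj = simulate_beat_trajectory(cfg)
        truth = traj.metadata["truth"]
        for t0 in truth["beat_times"]:
            i = int(round(t0 * cfg.sampling_rate))
            window = traj.force[i - 100:i + 100]
            assert window.max() == pytest.approx(1e-9, rel=1e-3)

    def test_degenerate_cvs_give_uniform_ground_truth(self):
        cfg = BeatTrainConfig(duration=10.0, beat_rate_cv=0.0, amplitude_cv=0.0,
                              fwhm_cv=0.0, seed=7)
        truth = simulate_beat_trajectory(cfg).metadata["truth"]
        assert np.allclose(truth["amplitudes"], truth["amplitudes"][0])
        assert np.allclose(np.diff(truth["beat_times"]),
                           np.diff(truth["beat_times"])[0])

    def test_quiescent_noise_sd_matches_config(self):
        cfg = BeatTrainConfig(duration=120.0, beat_rate_mean=0.0,
                              noise_sd=20e-12, seed=3)
        traj = simulate_beat_trajectory(cfg)
        assert len(traj.metadata["truth"]["beat_times"]) == 0
        assert np.std(traj.force) == pytest.approx(20e-12, rel=0.05)

    def test_unresolvable_peaks_rejected(self):
        with pytest.raises(ConfigError, match="resolvable"):
            simulate_beat_trajectory(
                BeatTrainConfig(sampling_rate=20.0, fwhm_mean=0.2)).validate()

    def test_drift_adds_low_frequency_component(self):
        base = BeatTrainConfig(duration=60.0, beat_rate_mean=0.0, noise_sd=0.0,
                               baseline_drift_amplitude=0.0, seed=5)
        drift = BeatTrainConfig(duration=60.0, beat_rate_mean=0.0, noise_sd=0.0,
                                baseline_drift_amplitude=0.5e-9, seed=5)
        a = simulate_beat_trajectory(base)
        b = simulate_beat_trajectory(drift)
        assert np.ptp(b.force) > np.ptp(a.force)


class TestThermalNoise:
    def test_equipartition_variance(self):
        traj = simulate_thermal_noise(0.04, 310.0, duration=60.0, seed=1)
        target = K_B * 310.0 / 0.04
        assert np.var(traj.deflection) == pytest.approx(target, rel=0.02)

    def test_doubling_spring_constant_halves_variance(self):
        a = simulate_thermal_noise(0.04, 310.0, 30.0, seed=2)
        b = simulate_thermal_noise(0.08, 310.0, 30.0, seed=2)
        ratio = np.var(b.deflection) / np.var(a.deflection)
        assert ratio == pytest.approx(0.5, rel=0.05)

    def test_zero_temperature_is_silent(self):
        traj = simulate_thermal_noise(0.04, 0.0, 1.0, seed=0)
        assert np.all(traj.deflection == 0.0)

    def test_variance_matches_equipartition_across_seeds(self):
        k, T = 0.04, 310.0
        ratios = [np.var(simulate_thermal_noise(k, T, 10.0, seed=s).deflection)
                  / (K_B * T / k) for s in range(20)]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.01)


class TestForceCurve:
    def test_noiseless_cone_follows_sneddon_law(self):
        cfg = HertzCurveConfig(E_true=300.0, noise_sd_deflection=0.0, seed=0)
        curve = simulate_force_curve(cfg)
        d = curve.deflection
        delta = (curve.z - cfg.contact_point) - d
        post = delta > 1e-9
        expected = hertz_force(delta[post], 300.0, "cone", 0.5, 35.0)
        np.testing.assert_allclose(curve.spring_constant * d[post], expected,
                                   rtol=1e-9)

    def test_sphere_force_scales_as_delta_three_halves(self):
        F1 = hertz_force(200e-9, 1000.0, "sphere", 0.5, tip_radius=1e-6)
        F2 = hertz_force(400e-9, 1000.0, "sphere", 0.5, tip_radius=1e-6)
        assert F2 / F1 == pytest.approx(2.0 ** 1.5, rel=1e-12)

    def test_incompressible_prefactor(self):
        # nu = 0.5 -> 1/(1 - nu^2) = 4/3
        F_nu0 = hertz_force(100e-9, 300.0, "cone", 0.0, 35.0)
        F_nu05 = hertz_force(100e-9, 300.0, "cone", 0.5, 35.0)
        assert F_nu05 / F_nu0 == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_z_range_too_short_rejected(self):
        cfg = HertzCurveConfig(max_indentation=500e-9, z_end=1.2e-6,
                               contact_point=1e-6)
        with pytest.raises(ConfigError, match="z_end"):
            simulate_force_curve(cfg)

    def test_exactly_one_tip_parameter(self):
        with pytest.raises(ValueError):
            HertzCurveConfig(geometry="sphere", tip_half_angle_deg=35.0,
                             tip_radius=None).validate()


class TestDwellMap:
    def test_single_component_shares_generating_params(self):
        cfg = DwellMapConfig(
            n_rows=4, n_cols=4, dwell_duration=3.0,
            population_mixture=[MixtureComponent(1.0, 1e-9, 0.0, math.log(300.0), 0.0)],
            seed=1)
        sim = simulate_dwell_map(cfg)
        on_cell = [p for p in sim if p.truth["on_cell"]]
        assert on_cell, "mask left no cell points"
        assert all(p.truth["E"] == pytest.approx(300.0) for p in on_cell)
        assert all(p.truth["beat_amplitude"] == pytest.approx(1e-9) for p in on_cell)

    def test_two_separated_components_cluster_in_joint_plane(self):
        cfg = DwellMapConfig(
            n_rows=8, n_cols=8, dwell_duration=3.0,
            population_mixture=[
                MixtureComponent(0.5, 2e-9, 0.05, math.log(1000.0), 0.1),
                MixtureComponent(0.5, 0.2e-9, 0.05, math.log(50.0), 0.1),
            ],
            seed=2)
        sim = simulate_dwell_map(cfg)
        pts = [(p.truth["beat_amplitude"], math.log(p.truth["E"]), p.truth["component"])
               for p in sim if p.truth["on_cell"]]
        comp0 = [f for f, _, c in pts if c == 0]
        comp1 = [f for f, _, c in pts if c == 1]
        assert comp0 and comp1
        assert min(comp0) > max(comp1)  # well-separated force means

    def test_glass_points_are_quiescent_and_stiff(self):
        sim = simulate_dwell_map(DwellMapConfig(n_rows=5, n_cols=5,
                                                dwell_duration=2.0, seed=3))
        glass = [p for p in sim if not p.truth["on_cell"]]
        assert glass
        for p in glass:
            assert p.truth["E"] == pytest.approx(1e6)
            assert np.std(p.dwell.force) < 100e-12  # noise only, no beats

    def test_empty_mask_rejected(self):
        cfg = DwellMapConfig(n_rows=3, n_cols=3,
                             cell_mask=np.zeros((3, 3), dtype=bool))
        with pytest.raises(ConfigError, match="empty"):
            cfg.validate()

    def test_mixture_weights_must_sum_to_one(self):
        cfg = DwellMapConfig(population_mixture=[
            MixtureComponent(0.4, 1e-9, 0.1, 5.0, 0.5)])
        with pytest.raises(ConfigError, match="weights"):
            cfg.validate()


class TestDoseResponse:
    def test_midpoint_identity_at_ec50(self):
        cfg = DoseResponseConfig(noise_cv=0.0, seed=0)
        mid = hill_response(cfg.ec50_true, cfg.baseline_force, cfg.max_force,
                            cfg.ec50_true, cfg.hill_coefficient)
        assert mid == pytest.approx((cfg.baseline_force + cfg.max_force) / 2,
                                    rel=1e-12)

    def test_asymptotes(self):
        cfg = DoseResponseConfig()
        lo = hill_response(1e-15, cfg.baseline_force, cfg.max_force,
                           cfg.ec50_true, 1.0)
        hi = hill_response(1e3, cfg.baseline_force, cfg.max_force,
                           cfg.ec50_true, 1.0)
        assert lo == pytest.approx(cfg.baseline_force, rel=1e-4)
        assert hi == pytest.approx(cfg.max_force, rel=1e-4)

    def test_noiseless_series_lies_on_hill_curve(self):
        cfg = DoseResponseConfig(noise_cv=0.0, beats_per_dose=3, seed=1)
        series = simulate_dose_response(cfg)
        expected = hill_response(series.dose, cfg.baseline_force, cfg.max_force,
                                 cfg.ec50_true, cfg.hill_coefficient)
        np.testing.assert_allclose(series.force, expected, rtol=1e-12)

    def test_unsorted_doses_rejected(self):
        with pytest.raises(ConfigError, match="sorted"):
            DoseResponseConfig(doses=[1e-6, 1e-7]).validate()
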