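"""Synthetic AFM data generators.

These stand in for the instrument: beat trains as asymmetric force peaks,
thermal-fluctuation series for spring-constant calibration, Hertzian approach
curves, force-volume ("dwell") maps, and Hill dose-response series.  Every
generator is deterministic given its seed and attaches the generating ground
truth to the output metadata so downstream stages are testable by parameter
recovery.

Instrument scales default to the ones typical of soft-cantilever cell work:
2 kHz sampling, ~20 pN force noise, 0.04 N/m spring constant, 100 pN trigger.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.constants import Boltzmann as K_B

from .exceptions import ConfigError
from .hertz import ForceCurve, geometry_exponent, geometry_prefactor
from .trajectory import DeflectionTrajectory, ForceTrajectory

__all__ = [
    "BeatTrainConfig",
    "HertzCurveConfig",
    "MixtureComponent",
    "DwellMapConfig",
    "DoseResponseConfig",
    "DoseResponseSeries",
    "SimulatedDwellPoint",
    "SimulatedDwellMap",
    "simulate_beat_trajectory",
    "simulate_thermal_noise",
    "simulate_force_curve",
    "simulate_dwell_map",
    "simulate_dose_response",
    "healthy_map_config",
    "dcm_map_config",
]

_FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = 2.3548 sigma


# --------------------------------------------------------------------------- beats
@dataclass
class BeatTrainConfig:
    """Parameters of a simulated contraction recording.

    Amplitude/rate/width of each beat are drawn independently from normal
    distributions with the stated means and coefficients of variation;
    ``peak_shape='asymmetric'`` uses a two-sided Gaussian (fast rise, slow
    decay, 35/65 split of the width) mimicking the upstroke/relaxation
    asymmetry of cardiomyocyte beats.  ``beat_rate_mean = 0`` or
    ``amplitude_mean = 0`` yields a quiescent (noise + drift only) recording.
    """

    duration: float = 120.0
    sampling_rate: float = 2000.0
    beat_rate_mean: float = 1.0
    beat_rate_cv: float = 0.10
    amplitude_mean: float = 1e-9
    amplitude_cv: float = 0.10
    fwhm_mean: float = 0.2
    fwhm_cv: float = 0.05
    peak_shape: str = "asymmetric"
    noise_sd: float = 20e-12
    baseline_drift_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ConfigError("duration and sampling_rate must be positive")
        if min(self.beat_rate_mean, self.amplitude_mean) < 0:
            raise ConfigError("rates and amplitudes must be >= 0")
        if self.fwhm_mean <= 0:
            raise ConfigError("fwhm_mean must be positive")
        if min(self.beat_rate_cv, self.amplitude_cv, self.fwhm_cv) < 0:
            raise ConfigError("coefficients of variation must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.sampling_rate * self.fwhm_mean < 10:
            raise ConfigError(
                "peaks not resolvable: sampling_rate * fwhm_mean must be >= 10 samples"
            )
        if self.peak_shape not in ("gaussian", "asymmetric"):
            raise ConfigError(f"unknown peak_shape {self.peak_shape!r}")


def _truncated_normal(rng, mean, cv, size, floor_frac=0.1):
    """Normal(mean, cv*mean) resampled to stay above floor_frac*mean."""
    if mean == 0 or cv == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, cv * mean, size)
    bad = out < floor_frac * mean
    while np.any(bad):
        out[bad] = rng.normal(mean, cv * mean, int(bad.sum()))
        bad = out < floor_frac * mean
    return out


def _peak_waveform(t, t0, amplitude, fwhm, shape):
    """Additive waveform of one beat evaluated on grid t (vectorised window)."""
    s_eq = fwhm / _FWHM_SIGMA
    if shape == "gaussian":
        return amplitude * np.exp(-0.5 * ((t - t0) / s_eq) ** 2)
    # two-sided Gaussian: sigma_rise + sigma_decay = 2*s_eq preserves the FWHM
    s_rise, s_decay = 0.35 * 2 * s_eq, 0.65 * 2 * s_eq
    x = t - t0
    s = np.where(x < 0, s_rise, s_decay)
    return amplitude * np.exp(-0.5 * (x / s) ** 2)


def simulate_beat_trajectory(config: BeatTrainConfig) -> ForceTrajectory:
    """Simulate one dwell recording of spontaneous beats.

    Ground truth (beat times, amplitudes, FWHMs, forward rates) is attached
    under ``metadata['truth']``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) * (1.0 / fs)
    force = np.zeros(n)

    times, amps, widths = [], [], []
    if config.beat_rate_mean > 0 and config.amplitude_mean > 0:
        margin = 2.0 * config.fwhm_mean
        t_next = max(margin, 0.5 / config.beat_rate_mean)
        while t_next < config.duration - margin:
            times.append(t_next)
            rate = float(_truncated_normal(rng, config.beat_rate_mean,
                                           config.beat_rate_cv, (), floor_frac=0.2))
            t_next = t_next + 1.0 / rate
        amps = _truncated_normal(rng, config.amplitude_mean, config.amplitude_cv,
                                 len(times)).tolist()
        widths = _truncated_normal(rng, config.fwhm_mean, config.fwhm_cv,
                                   len(times), floor_frac=0.3).tolist()
        for t0, a, w in zip(times, amps, widths):
            s_eq = w / _FWHM_SIGMA
            lo = max(0, int((t0 - 8 * s_eq) * fs))
            hi = min(n, int((t0 + 8 * s_eq) * fs) + 1)
            force[lo:hi] += _peak_waveform(t[lo:hi], t0, a, w, config.peak_shape)

    if config.baseline_drift_amplitude > 0:
        a = config.baseline_drift_amplitude
        phase = rng.uniform(0, 2 * math.pi)
        f_drift = rng.uniform(0.005, 0.02)  # Hz, well below beat rates
        force += 0.5 * a * np.sin(2 * math.pi * f_drift * t + phase)
        force += 0.5 * a * (t / config.duration)
    if config.noise_sd > 0:
        force += rng.normal(0.0, config.noise_sd, n)

    times_arr = np.asarray(times)
    truth = {
        "beat_times": times_arr,
        "amplitudes": np.asarray(amps),
        "fwhms": np.asarray(widths),
        "rates": 1.0 / np.diff(times_arr) if len(times) > 1 else np.empty(0),
    }
    meta = {"truth": truth, "seed": config.seed, "config": config}
    return ForceTrajectory(t, force, fs, metadata=meta)


# ------------------------------------------------------------------- thermal noise
def simulate_thermal_noise(
    spring_constant: float,
    temperature: float,
    duration: float,
    sampling_rate: float = 2000.0,
    seed: int = 0,
) -> DeflectionTrajectory:
    """Zero-mean deflection series whose variance obeys equipartition,
    var(d) = k_B T / k.  T = 0 yields an all-zero series."""
    if spring_constant <= 0:
        raise ConfigError("spring_constant must be positive")
    if temperature < 0:
        raise ConfigError("temperature must be >= 0")
    if duration <= 0 or sampling_rate <= 0:
        raise ConfigError("duration and sampling_rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) * (1.0 / sampling_rate)
    sd = math.sqrt(K_B * temperature / spring_constant)
    d = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    meta = {"spring_constant": spring_constant, "temperature": temperature, "seed": seed}
    return DeflectionTrajectory(t, d, sampling_rate, metadata=meta)


# ---------------------------------------------------------------------- force curve
@dataclass
class HertzCurveConfig:
    """Parameters of a simulated approach curve.

    The z grid runs from ``contact_point - pre_contact_distance`` up to the z
    at which the indentation reaches ``max_indentation`` (plus the associated
    cantilever deflection).  Exactly one tip parameter is set per geometry.
    """

    E_true: float = 300.0
    nu: float = 0.5
    geometry: str = "cone"
    tip_half_angle_deg: float | None = 35.0
    tip_radius: float | None = None
    contact_point: float = 1e-6
    max_indentation: float = 500e-9
    spring_constant: float = 0.04
    noise_sd_deflection: float = 0.0
    n_points: int = 500
    pre_contact_distance: float | None = None
    z_end: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.E_true <= 0:
            raise ConfigError("E_true must be positive")
        if not 0 <= self.nu <= 0.5:
            raise ConfigError("nu must lie in [0, 0.5]")
        if self.max_indentation <= 0:
            raise ConfigError("max_indentation must be positive")
        if self.spring_constant <= 0:
            raise ConfigError("spring_constant must be positive")
        if self.n_points < 50:
            raise ConfigError("n_points must be >= 50")
        geometry_prefactor(self.geometry, self.tip_half_angle_deg, self.tip_radius)


def _solve_deflection(u: np.ndarray, coeff: float, p: float, k: float) -> np.ndarray:
    """Solve C*(u - d)^p = k*d for d on each u > 0 (Newton; g is convex and
    strictly decreasing in d, so iteration from d = 0 converges monotonically)."""
    d = np.zeros_like(u)
    pos = u > 0
    if not np.any(pos):
        return d
    up = u[pos]
    x = np.zeros_like(up)
    for _ in range(60):
        rem = np.clip(up - x, 0.0, None)
        g = coeff * rem**p - k * x
        gp = -coeff * p * rem ** (p - 1.0) - k
        step = g / gp
        x_new = np.clip(x - step, 0.0, up)
        if np.max(np.abs(x_new - x)) < 1e-18 + 1e-14 * np.max(up):
            x = x_new
            break
        x = x_new
    d[pos] = x
    return d


def simulate_force_curve(config: HertzCurveConfig) -> ForceCurve:
    """Simulate an approach curve: flat (noisy) pre-contact deflection, then
    the geometry's Hertz law with delta = (z - z_c) - d."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = geometry_prefactor(config.geometry, config.tip_half_angle_deg, config.tip_radius)
    p = geometry_exponent(config.geometry)
    coeff = g * config.E_true / (1.0 - config.nu**2)
    k = config.spring_constant

    d_max = coeff * config.max_indentation**p / k
    pre = config.pre_contact_distance
    if pre is None:
        pre = max(config.max_indentation, 200e-9)
    z_needed = config.contact_point + config.max_indentation + d_max
    z_end = config.z_end if config.z_end is not None else z_needed
    if z_end < z_needed * (1 - 1e-12):
        raise ConfigError(
            f"max_indentation requires z up to {z_needed:.4g} m but z_end = {z_end:.4g} m"
        )
    z = np.linspace(config.contact_point - pre, z_end, config.n_points)
    d = _solve_deflection(z - config.contact_point, coeff, p, k)
    if config.noise_sd_deflection > 0:
        d = d + rng.normal(0.0, config.noise_sd_deflection, d.size)
    meta = {
        "truth": {
            "E": config.E_true,
            "contact_point": config.contact_point,
            "nu": config.nu,
            "geometry": config.geometry,
        },
        "seed": config.seed,
        "config": config,
    }
    return ForceCurve(z, d, k, metadata=meta)


# ------------------------------------------------------------------------ dwell map
@dataclass
class MixtureComponent:
    """One population in the joint (beat force, modulus) plane.

    ``force_mean``/``force_cv`` parameterise the normal distribution of the
    per-point beat amplitude (N); ``logE_mean``/``logE_sd`` the natural-log
    normal distribution of the local Young's modulus (Pa)."""

    weight: float
    force_mean: float
    force_cv: float
    logE_mean: float
    logE_sd: float


@dataclass
class DwellMapConfig:
    """Force-volume grid: one approach curve + one 10 s dwell per point.

    ``cell_mask`` marks on-cell points (default: centred ellipse covering
    ~55% of the grid); masked-off points sit on glass — stiff curves, no
    beats.  On-cell generating parameters come either from the population
    mixture or, when given, from explicit per-point ``force_field`` /
    ``modulus_field`` arrays.
    """

    n_rows: int = 15
    n_cols: int = 15
    cell_mask: np.ndarray | None = None
    population_mixture: Sequence[MixtureComponent] = field(
        default_factory=lambda: [MixtureComponent(1.0, 1.35e-9, 0.30, math.log(296.0), 1.0)]
    )
    force_field: np.ndarray | None = None
    modulus_field: np.ndarray | None = None
    dwell_duration: float = 10.0
    grid_spacing: float = 2e-6
    sampling_rate: float = 2000.0
    noise_sd: float = 20e-12
    spring_constant: float = 0.04
    beat_rate_mean: float = 1.0
    beat_rate_cv: float = 0.05
    fwhm_mean: float = 0.2
    fwhm_cv: float = 0.05
    amplitude_cv: float = 0.05
    glass_modulus: float = 1e6
    substrate_z: float = 6e-6
    cell_height_max: float = 4e-6
    trigger_force: float = 100e-12
    curve_n_points: int = 500
    curve_noise_sd_deflection: float = 0.5e-9
    geometry: str = "cone"
    tip_half_angle_deg: float = 35.0
    nu: float = 0.5
    seed: int = 0

    def validate(self) -> np.ndarray:
        if not (1 <= self.n_rows <= 64 and 1 <= self.n_cols <= 64):
            raise ConfigError("grid dimensions must be in [1, 64]")
        mask = self.cell_mask
        if mask is None:
            mask = _ellipse_mask(self.n_rows, self.n_cols)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise ConfigError("cell_mask shape must be (n_rows, n_cols)")
        if not mask.any():
            raise ConfigError("cell_mask is empty: no on-cell points")
        if self.force_field is None or self.modulus_field is None:
            w = np.array([c.weight for c in self.population_mixture], dtype=float)
            if len(w) == 0 or np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
                raise ConfigError("mixture weights must be >= 0 and sum to 1")
        return mask


def _ellipse_mask(n_rows: int, n_cols: int) -> np.ndarray:
    r = (np.arange(n_rows)[:, None] - (n_rows - 1) / 2) / (0.45 * n_rows)
    c = (np.arange(n_cols)[None, :] - (n_cols - 1) / 2) / (0.45 * n_cols)
    return r**2 + c**2 <= 1.0


@dataclass
class SimulatedDwellPoint:
    row: int
    col: int
    x: float
    y: float
    curve: ForceCurve
    dwell: ForceTrajectory
    truth: dict[str, Any]


@dataclass
class SimulatedDwellMap:
    config: DwellMapConfig
    points: list[SimulatedDwellPoint]

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)


def _trigger_indentation(E: float, trigger: float, geometry: str, half_angle: float, nu: float) -> float:
    g = geometry_prefactor(geometry, half_angle if geometry != "sphere" else None,
                           None if geometry != "sphere" else half_angle)
    p = geometry_exponent(geometry)
    return (trigger * (1.0 - nu**2) / (g * E)) ** (1.0 / p)


def simulate_dwell_map(config: DwellMapConfig) -> SimulatedDwellMap:
    """Simulate a full force-volume grid with retained ground truth.

    On-cell points draw a mixture component (beat amplitude mean, modulus);
    glass points get the glass modulus and a quiescent dwell.  Heights follow
    a parabolic dome over the cell mask, zero on glass; each point's curve
    contact point is ``substrate_z - height``.
    """
    mask = config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    comps = list(config.population_mixture)
    weights = np.array([c.weight for c in comps], dtype=float)

    # dome profile for heights over the mask
    rr = (np.arange(config.n_rows)[:, None] - (config.n_rows - 1) / 2) / max(config.n_rows / 2, 1)
    cc = (np.arange(config.n_cols)[None, :] - (config.n_cols - 1) / 2) / max(config.n_cols / 2, 1)
    dome = np.clip(1.0 - (rr**2 + cc**2), 0.05, None) * config.cell_height_max

    points: list[SimulatedDwellPoint] = []
    child_seeds = ss.spawn(config.n_rows * config.n_cols)
    for row in range(config.n_rows):
        for col in range(config.n_cols):
            idx = row * config.n_cols + col
            child = np.random.default_rng(child_seeds[idx])
            sub_seed = int(child.integers(0, 2**31 - 1))
            on_cell = bool(mask[row, col])
            if on_cell:
                if config.force_field is not None and config.modulus_field is not None:
                    comp_idx = -1
                    amp = float(config.force_field[row, col])
                    E = float(config.modulus_field[row, col])
                else:
                    comp_idx = int(rng.choice(len(comps), p=weights))
                    c = comps[comp_idx]
                    if c.force_mean > 0:
                        amp = max(float(rng.normal(c.force_mean,
                                                   c.force_cv * c.force_mean)),
                                  0.06e-9)
                    else:
                        amp = 0.0
                    E = float(np.exp(rng.normal(c.logE_mean, c.logE_sd)))
                height = float(dome[row, col])
                rate = config.beat_rate_mean
            else:
                comp_idx, amp, E, height, rate = -2, 0.0, config.glass_modulus, 0.0, 0.0

            dwell_cfg = BeatTrainConfig(
                duration=config.dwell_duration,
                sampling_rate=config.sampling_rate,
                beat_rate_mean=rate,
                beat_rate_cv=config.beat_rate_cv,
                amplitude_mean=amp,
                amplitude_cv=config.amplitude_cv,
                fwhm_mean=config.fwhm_mean,
                fwhm_cv=config.fwhm_cv,
                noise_sd=config.noise_sd,
                seed=sub_seed,
            )
            dwell = simulate_beat_trajectory(dwell_cfg)

            delta_max = _trigger_indentation(
                E, config.trigger_force, config.geometry, config.tip_half_angle_deg, config.nu
            )
            curve_cfg = HertzCurveConfig(
                E_true=E,
                nu=config.nu,
                geometry=config.geometry,
                tip_half_angle_deg=config.tip_half_angle_deg,
                contact_point=config.substrate_z - height,
                max_indentation=float(np.clip(delta_max, 50e-9, 2.5e-6)),
                spring_constant=config.spring_constant,
                noise_sd_deflection=config.curve_noise_sd_deflection,
                n_points=config.curve_n_points,
                pre_contact_distance=1e-6,
                seed=(sub_seed + 1) % 2**31,
            )
            curve = simulate_force_curve(curve_cfg)
            truth = {
                "on_cell": on_cell,
                "component": comp_idx,
                "E": E,
                "beat_amplitude": amp,
                "height": height,
                "contact_point": config.substrate_z - height,
            }
            points.append(
                SimulatedDwellPoint(
                    row=row, col=col,
                    x=col * config.grid_spacing, y=row * config.grid_spacing,
                    curve=curve, dwell=dwell, truth=truth,
                )
            )
    return SimulatedDwellMap(config=config, points=points)


def healthy_map_config(seed: int = 0, n_rows: int = 15, n_cols: int = 15, **kw) -> DwellMapConfig:
    """Unimodal (healthy-like) map: one population at strong force and
    moderate elasticity (means matched to reported control-cell bootstrap
    means, 1.35 nN and 296 Pa)."""
    return DwellMapConfig(
        n_rows=n_rows, n_cols=n_cols,
        population_mixture=[MixtureComponent(1.0, 1.35e-9, 0.30, math.log(296.0), 1.0)],
        seed=seed, **kw,
    )


def dcm_map_config(seed: int = 0, n_rows: int = 15, n_cols: int = 15, **kw) -> DwellMapConfig:
    """Bimodal (DCM-like) map: the healthy-like population mixed 50/50 with a
    low-force/low-elasticity population, reproducing the bimodal force and
    modulus histograms characteristic of the diseased cell."""
    return DwellMapConfig(
        n_rows=n_rows, n_cols=n_cols,
        population_mixture=[
            MixtureComponent(0.5, 1.0e-9, 0.30, math.log(400.0), 0.8),
            MixtureComponent(0.5, 0.25e-9, 0.30, math.log(60.0), 0.6),
        ],
        seed=seed, **kw,
    )


# -------------------------------------------------------------------- dose response
@dataclass
class DoseResponseConfig:
    """Hill-model dose ladder (defaults: the 10 nmol/L - 32 umol/L
    epinephrine ladder, EC50 260 nmol/L)."""

    doses: Sequence[float] = field(
        default_factory=lambda: list(np.geomspace(10e-9, 32e-6, 8))
    )
    ec50_true: float = 260e-9
    hill_coefficient: float = 1.0
    baseline_force: float = 0.5e-9
    max_force: float = 1.3e-9
    noise_cv: float = 0.10
    beats_per_dose: int = 30
    seed: int = 0

    def validate(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if d.size < 2 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ConfigError("doses must be strictly positive and sorted ascending")
        if self.ec50_true <= 0 or self.hill_coefficient <= 0:
            raise ConfigError("ec50_true and hill_coefficient must be positive")
        if self.max_force <= self.baseline_force:
            raise ConfigError("max_force must exceed baseline_force")
        if self.noise_cv < 0 or self.beats_per_dose < 1:
            raise ConfigError("noise_cv >= 0 and beats_per_dose >= 1 required")


@dataclass
class DoseResponseSeries:
    """Per-beat force observations across a dose ladder (one row per beat)."""

    dose: np.ndarray
    force: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __len__(self):
        return self.dose.size


def hill_response(dose, baseline: float, fmax: float, ec50: float, h: float):
    dose = np.asarray(dose, dtype=float)
    return baseline + (fmax - baseline) * dose**h / (dose**h + ec50**h)


def simulate_dose_response(config: DoseResponseConfig) -> DoseResponseSeries:
    """Beat forces per dose following the Hill law with multiplicative noise."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    doses, forces = [], []
    for d in config.doses:
        mu = float(hill_response(d, config.baseline_force, config.max_force,
                                 config.ec50_true, config.hill_coefficient))
        f = mu * (1.0 + config.noise_cv * rng.standard_normal(config.beats_per_dose))
        f = np.clip(f, 0.05 * mu, None)
        doses.append(np.full(config.beats_per_dose, d))
        forces.append(f)
    meta = {"truth": {"ec50": config.ec50_true, "hill": config.hill_coefficient,
                      "baseline": config.baseline_force, "max": config.max_force},
            "seed": config.seed, "config": config}
    return DoseResponseSeries(np.concatenate(doses), np.concatenate(forces), meta)
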