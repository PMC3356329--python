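"""Cantilever calibration: thermal-noise spring constant and
deflection-to-force conversion.

The equipartition theorem assigns (1/2) k <d^2> = (1/2) k_B T to the
cantilever's fundamental bending mode, so k = k_B T / var(d) from a thermal
fluctuation recording.  Because only ~97% of the thermal variance sits in the
first mode, an opt-in corrected estimator k = beta_1 k_B T / var(d) with
beta_1 = 0.971 is provided; the plain equipartition estimator is the default.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Boltzmann as K_B

from .exceptions import DegenerateInputError
from .trajectory import DeflectionTrajectory, ForceTrajectory

__all__ = [
    "CantileverCalibration",
    "calibrate_spring_constant",
    "deflection_to_force",
    "force_to_deflection",
    "DEFAULT_TEMPERATURE",
    "MODE1_CORRECTION",
]

#: bath temperature of the experiments, 36 degC
DEFAULT_TEMPERATURE = 309.15
#: fraction of total thermal variance carried by the first bending mode
MODE1_CORRECTION = 0.971

_METHODS = ("equipartition", "equipartition_mode1_corrected")


@dataclass
class CantileverCalibration:
    spring_constant: float  # N/m
    temperature: float  # K
    method: str
    variance_used: float  # m^2

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.method not in _METHODS:
            raise ValueError(f"unknown calibration method {self.method!r}")


def calibrate_spring_constant(
    deflection_series: DeflectionTrajectory | np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    method: str = "equipartition",
) -> CantileverCalibration:
    """Estimate the spring constant from a thermal fluctuation recording.

    The series mean is removed before the variance is computed (sample
    variance, n-1 denominator).  Requires >= 1000 samples and a genuinely
    fluctuating series.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if method not in _METHODS:
        raise ValueError(f"unknown calibration method {method!r}")
    d = (
        deflection_series.deflection
        if isinstance(deflection_series, DeflectionTrajectory)
        else np.asarray(deflection_series, dtype=float)
    )
    if d.size < 1000:
        raise ValueError("thermal calibration needs >= 1000 samples")
    var = float(np.var(d - np.mean(d), ddof=1))
    if var <= 1e-30:
        raise DegenerateInputError("deflection variance is (near) zero; cannot calibrate")
    k = K_B * temperature / var
    if method == "equipartition_mode1_corrected":
        k *= MODE1_CORRECTION
    return CantileverCalibration(
        spring_constant=k, temperature=temperature, method=method, variance_used=var
    )


def deflection_to_force(deflection, spring_constant: float):
    """F = k * d, elementwise.

    Accepts a scalar, an array, or a :class:`DeflectionTrajectory` (returning
    a :class:`ForceTrajectory` whose metadata records the spring constant).
    """
    if spring_constant is None or spring_constant <= 0:
        raise ValueError("a positive spring constant (calibration) is required")
    if isinstance(deflection, DeflectionTrajectory):
        meta = dict(deflection.metadata)
        meta["spring_constant"] = spring_constant
        return ForceTrajectory(
            deflection.time,
            spring_constant * deflection.deflection,
            deflection.sampling_rate,
            metadata=meta,
        )
    return spring_constant * np.asarray(deflection, dtype=float) if np.ndim(deflection) else spring_constant * float(deflection)


def force_to_deflection(force, spring_constant: float):
    """Inverse of :func:`deflection_to_force`: d = F / k."""
    if spring_constant is None or spring_constant <= 0:
        raise ValueError("a positive spring constant is required")
    if isinstance(force, ForceTrajectory):
        meta = dict(force.metadata)
        meta["spring_constant"] = spring_constant
        return DeflectionTrajectory(
            force.time, force.force / spring_constant, force.sampling_rate, metadata=meta
        )
    return np.asarray(force, dtype=float) / spring_constant if np.ndim(force) else float(force) / spring_constant
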