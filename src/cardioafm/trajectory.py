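"""Time-series containers for AFM recordings.

Everything is SI internally: seconds, metres, newtons. A trajectory lives on
a strictly uniform time grid; the sampling rate is carried alongside so
downstream window/separation parameters expressed in seconds convert to
sample counts without re-deriving the grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ForceTrajectory", "DeflectionTrajectory"]

#: maximum tolerated relative deviation of the time grid from uniformity
GRID_RTOL = 1e-9


def _validate_grid(time: np.ndarray) -> None:
    if time.ndim != 1 or time.size < 2:
        raise ValueError("trajectory needs a 1-D time grid with >= 2 samples")
    dt = np.diff(time)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise ValueError(f"time must be strictly increasing (violated at row {i + 1})")
    dt0 = float(np.mean(dt))
    if np.max(np.abs(dt - dt0)) > GRID_RTOL * dt0:
        i = int(np.argmax(np.abs(dt - dt0) > GRID_RTOL * dt0))
        raise ValueError(f"non-uniform time grid (first offending row {i + 1})")


@dataclass
class ForceTrajectory:
    """Force versus time from one cantilever dwell.

    Attributes
    ----------
    time : ndarray, s — uniform grid, strictly increasing.
    force : ndarray, N.
    sampling_rate : float, Hz.
    metadata : dict — provenance (seed, calibration, ground truth for
        synthetic data).
    """

    time: np.ndarray
    force: np.ndarray
    sampling_rate: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        _validate_grid(self.time)
        if self.force.shape != self.time.shape:
            raise ValueError("time and force must have identical shape")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class DeflectionTrajectory:
    """Cantilever deflection (m) versus time; pre-calibration counterpart of
    :class:`ForceTrajectory`."""

    time: np.ndarray
    deflection: np.ndarray
    sampling_rate: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        _validate_grid(self.time)
        if self.deflection.shape != self.time.shape:
            raise ValueError("time and deflection must have identical shape")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.time.size
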