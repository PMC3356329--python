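"""Dwell mapping: spatial grids of elasticity, height and contraction force.

Each grid point contributes one approach curve (contact point + Young's
modulus) and one dwell trajectory (beats).  A point is "beating" when at
least ``min_beats`` contractions are detected during the dwell; beating
points with a successful modulus fit form the joint (beat force, modulus)
point set that feeds the statistical comparison of cells.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .beats import BeatEvent, detect_beats
from .exceptions import CardioAFMError, FitError, NoContactError
from .hertz import ForceCurve, HertzModel
from .synthetic import SimulatedDwellMap, SimulatedDwellPoint
from .trajectory import ForceTrajectory

__all__ = [
    "DwellAnalysisParams",
    "DwellPoint",
    "DwellMap",
    "MechanoPointSet",
    "analyze_dwell_point",
    "assemble_map",
    "analyze_dwell_map",
    "extract_point_set",
    "bimodality_diagnostic",
]


@dataclass
class DwellAnalysisParams:
    """Knobs of the per-point analysis.

    ``min_beats`` (default 2) is the threshold for calling a point beating;
    ``expected_rate`` flags dwells shorter than two expected beat periods as
    low-confidence calls.
    """

    geometry: str = "cone"
    tip_half_angle_deg: float | None = 35.0
    tip_radius: float | None = None
    nu: float = 0.5
    fit_range: float | None = None
    min_beats: int = 2
    min_separation: float = 0.25
    min_height: float | str = "auto"
    expected_rate: float = 1.0
    stiff_modulus_threshold: float = 5e4  # Pa; marks probable substrate


@dataclass
class DwellPoint:
    """Analysed grid point."""

    row: int
    col: int
    x: float
    y: float
    contact_z: float  # m; NaN when contact search failed
    E: float  # Pa; NaN when the Hertz fit failed
    fit_ok: bool
    beats: list[BeatEvent]
    beat_force: float  # N; mean peak force over the dwell, NaN if not beating
    is_beating: bool
    low_confidence: bool
    height: float = float("nan")  # m; filled in at map assembly
    notes: str = ""

    @property
    def n_beats(self) -> int:
        return len(self.beats)


def analyze_dwell_point(
    curve: ForceCurve,
    dwell: ForceTrajectory,
    params: DwellAnalysisParams | None = None,
    row: int = 0,
    col: int = 0,
    x: float = 0.0,
    y: float = 0.0,
) -> DwellPoint:
    """Run the indentation fit and beat detection for one grid point.

    Hertz failures and zero beats are recorded on the point, never fatal:
    a stiff flat-ish curve with no beats is exactly what glass looks like.
    """
    p = params or DwellAnalysisParams()
    notes = []
    contact_z = E = float("nan")
    fit_ok = False
    try:
        model = HertzModel(curve, p.geometry, p.tip_half_angle_deg, p.tip_radius, p.nu)
        fit = model.fit(fit_range=p.fit_range)
        contact_z = fit.contact_point
        if fit.ok:
            E, fit_ok = fit.E, True
        else:
            notes.append(f"hertz: {fit.message}")
    except (NoContactError, FitError, ValueError) as exc:
        notes.append(f"hertz: {exc}")

    beats = detect_beats(dwell, min_height=p.min_height, min_separation=p.min_separation)
    is_beating = len(beats) >= p.min_beats
    beat_force = (float(np.mean([b.force for b in beats])) if is_beating else float("nan"))
    low_conf = dwell.duration < 2.0 / p.expected_rate
    if low_conf:
        notes.append("dwell shorter than two expected beat periods")
    return DwellPoint(
        row=row, col=col, x=x, y=y,
        contact_z=contact_z, E=E, fit_ok=fit_ok,
        beats=beats, beat_force=beat_force, is_beating=is_beating,
        low_confidence=low_conf, notes="; ".join(notes),
    )


@dataclass
class DwellMap:
    """Complete analysed grid; exactly one point per cell."""

    n_rows: int
    n_cols: int
    grid_spacing: float
    points: list[DwellPoint]
    substrate_z: float = float("nan")
    provenance: dict[str, Any] = field(default_factory=dict)

    def matrix(self, quantity: str) -> np.ndarray:
        """Matrix view of one per-point quantity, NaN where missing."""
        out = np.full((self.n_rows, self.n_cols), np.nan)
        for pt in self.points:
            if quantity == "n_beats":
                out[pt.row, pt.col] = pt.n_beats
            elif quantity == "is_beating":
                out[pt.row, pt.col] = float(pt.is_beating)
            else:
                out[pt.row, pt.col] = getattr(pt, quantity)
        return out

    def counts(self) -> dict[str, int]:
        beating = sum(pt.is_beating for pt in self.points)
        failed = sum(not pt.fit_ok for pt in self.points)
        return {
            "total": len(self.points),
            "beating": beating,
            "non_beating": len(self.points) - beating,
            "fit_failed": failed,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "row": [p.row for p in self.points],
            "col": [p.col for p in self.points],
            "x_m": [p.x for p in self.points],
            "y_m": [p.y for p in self.points],
            "height_m": [p.height for p in self.points],
            "E_Pa": [p.E for p in self.points],
            "beat_force_N": [p.beat_force for p in self.points],
            "n_beats": [p.n_beats for p in self.points],
            "is_beating": [p.is_beating for p in self.points],
        })


def assemble_map(
    points: Sequence[DwellPoint],
    n_rows: int | None = None,
    n_cols: int | None = None,
    grid_spacing: float | None = None,
    provenance: dict | None = None,
) -> DwellMap:
    """Assemble per-point results into a map (order-independent).

    Validates grid completeness, sorts row-major, and converts contact points
    to local heights against the substrate reference — the median contact z of
    non-beating points (they sit on or near glass), falling back to the
    deepest contact on all-beating maps.
    """
    pts = sorted(points, key=lambda p: (p.row, p.col))
    if n_rows is None:
        n_rows = max(p.row for p in pts) + 1
    if n_cols is None:
        n_cols = max(p.col for p in pts) + 1
    seen = set()
    for p in pts:
        key = (p.row, p.col)
        if key in seen:
            raise CardioAFMError(f"duplicate grid cell {key}")
        seen.add(key)
    if len(seen) != n_rows * n_cols:
        missing = {(r, c) for r in range(n_rows) for c in range(n_cols)} - seen
        raise CardioAFMError(f"incomplete grid; missing cells {sorted(missing)[:5]}...")
    if grid_spacing is None:
        xs = sorted({p.x for p in pts})
        grid_spacing = xs[1] - xs[0] if len(xs) > 1 else float("nan")

    glass_z = [p.contact_z for p in pts if not p.is_beating and math.isfinite(p.contact_z)]
    if glass_z:
        substrate_z = float(np.median(glass_z))
    else:
        finite = [p.contact_z for p in pts if math.isfinite(p.contact_z)]
        substrate_z = float(np.max(finite)) if finite else float("nan")
    for p in pts:
        p.height = substrate_z - p.contact_z if math.isfinite(p.contact_z) else float("nan")
    return DwellMap(n_rows=n_rows, n_cols=n_cols, grid_spacing=grid_spacing,
                    points=pts, substrate_z=substrate_z,
                    provenance=provenance or {})


def analyze_dwell_map(
    sim: SimulatedDwellMap | Sequence[SimulatedDwellPoint],
    params: DwellAnalysisParams | None = None,
) -> DwellMap:
    """Analyse every point of a (simulated or file-loaded) raw dwell map."""
    raw = list(sim)
    analysed = [
        analyze_dwell_point(p.curve, p.dwell, params, row=p.row, col=p.col, x=p.x, y=p.y)
        for p in raw
    ]
    prov: dict[str, Any] = {}
    if isinstance(sim, SimulatedDwellMap):
        prov = {"config": sim.config, "seed": sim.config.seed}
        return assemble_map(analysed, sim.config.n_rows, sim.config.n_cols,
                            sim.config.grid_spacing, provenance=prov)
    return assemble_map(analysed, provenance=prov)


@dataclass
class MechanoPointSet:
    """Paired (beat force, Young's modulus) observations from beating points.

    This is the object the two-sample comparisons run on; glass and
    non-beating points never enter it.
    """

    force: np.ndarray  # N
    modulus: np.ndarray  # Pa
    label: str = ""
    reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.modulus = np.asarray(self.modulus, dtype=float)
        if self.force.shape != self.modulus.shape:
            raise ValueError("force and modulus must be paired")
        if np.any(~np.isfinite(self.force)) or np.any(~np.isfinite(self.modulus)):
            raise ValueError("point set must not contain missing values")
        if self.force.size and (np.any(self.force <= 0) or np.any(self.modulus <= 0)):
            raise ValueError("force and modulus must be positive")

    def __len__(self) -> int:
        return self.force.size

    @property
    def log10_modulus(self) -> np.ndarray:
        return np.log10(self.modulus)

    def to_xy(self) -> np.ndarray:
        return np.column_stack([self.force, self.modulus])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"force_N": self.force, "E_Pa": self.modulus,
                             "log10_E": self.log10_modulus})


def extract_point_set(dmap: DwellMap, label: str = "") -> MechanoPointSet:
    """Beating points with successful modulus fits, as a point set."""
    force, modulus = [], []
    reasons = {"not_beating": 0, "fit_failed": 0, "nonpositive": 0}
    for p in dmap.points:
        if not p.is_beating:
            reasons["not_beating"] += 1
        elif not (p.fit_ok and math.isfinite(p.E)):
            reasons["fit_failed"] += 1
        elif p.E <= 0 or not math.isfinite(p.beat_force) or p.beat_force <= 0:
            reasons["nonpositive"] += 1
        else:
            force.append(p.beat_force)
            modulus.append(p.E)
    if not force:
        warnings.warn(f"empty point set: no beating points with valid fits ({reasons})",
                      stacklevel=2)
    return MechanoPointSet(np.array(force), np.array(modulus), label=label,
                           reasons=reasons)


def bimodality_diagnostic(values, seed: int = 0) -> dict[str, float | bool]:
    """1- vs 2-component Gaussian-mixture BIC on a 1-D sample (diagnostic for
    the bimodal distributions a diseased cell's map produces, not a gate)."""
    from sklearn.mixture import GaussianMixture

    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if v.shape[0] < 10:
        raise ValueError("need >= 10 values for the mixture diagnostic")
    bic = {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=seed).fit(v)
        bic[k] = float(gm.bic(v))
    return {"bic_1": bic[1], "bic_2": bic[2],
            "delta_bic": bic[1] - bic[2], "bimodal": bic[2] < bic[1]}
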