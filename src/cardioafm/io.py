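"""Readers and writers for the project's plain-text tabular dialects.

All files are CSV/TSV with '#'-prefixed ``key=value`` metadata lines before
the header.  Units are baked into the column names (time_s, force_N,
deflection_m, z_m) so nothing silently changes scale.  Floats are written at
full precision (%.17g) so write/read round-trips are exact.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .calibration import deflection_to_force
from .dwellmap import DwellMap, MechanoPointSet
from .exceptions import ConfigError, FileFormatError
from .hertz import ForceCurve
from .synthetic import (
    DoseResponseSeries,
    SimulatedDwellMap,
    SimulatedDwellPoint,
)
from .trajectory import DeflectionTrajectory, ForceTrajectory

__all__ = [
    "read_trajectory", "write_trajectory", "read_deflection_trajectory",
    "read_force_curve", "write_force_curve",
    "write_dwell_map", "read_dwell_map",
    "write_point_set", "read_point_set",
    "write_dose_series", "read_dose_series",
    "load_run_config", "RUN_CONFIG_SCHEMA",
]

_FLOAT_FMT = "%.17g"


def _write_table(path, df: pd.DataFrame, metadata: dict[str, Any]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for key, val in metadata.items():
        buf.write(f"# {key}={val}\n")
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    path.write_text(buf.getvalue())


def _read_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def _require_columns(df: pd.DataFrame, path, *options: tuple[str, ...]) -> tuple[str, ...]:
    """Return the first column set fully present; raise naming what's missing."""
    for cols in options:
        if all(c in df.columns for c in cols):
            return cols
    wanted = " or ".join("(" + ", ".join(c) + ")" for c in options)
    missing = sorted(set(options[0]) - set(df.columns))
    raise FileFormatError(
        f"{path}: missing column(s) {missing}; expected columns {wanted}"
    )


# ------------------------------------------------------------------- trajectories
def write_trajectory(path, traj: ForceTrajectory | DeflectionTrajectory,
                     extra_metadata: dict | None = None) -> None:
    meta = {"sampling_rate_hz": traj.sampling_rate}
    for key in ("spring_constant", "seed"):
        if key in traj.metadata:
            meta["spring_constant_N_per_m" if key == "spring_constant" else key] = \
                traj.metadata[key]
    meta.update(extra_metadata or {})
    if isinstance(traj, ForceTrajectory):
        df = pd.DataFrame({"time_s": traj.time, "force_N": traj.force})
    else:
        df = pd.DataFrame({"time_s": traj.time, "deflection_m": traj.deflection})
    _write_table(path, df, meta)


def read_trajectory(path, spring_constant: float | None = None) -> ForceTrajectory:
    """Read a trajectory file; deflection files are converted to force, which
    requires a spring constant (metadata key ``spring_constant_N_per_m`` or
    the ``spring_constant`` argument)."""
    df, meta = _read_table(path)
    cols = _require_columns(df, path, ("time_s", "force_N"), ("time_s", "deflection_m"))
    t = df["time_s"].to_numpy(dtype=float)
    _validate_time(t, path)
    fs = float(meta.get("sampling_rate_hz", 1.0 / np.mean(np.diff(t))))
    # rebuild an exactly uniform grid (text formatting may perturb spacing)
    t = t[0] + np.arange(t.size) * float(np.mean(np.diff(t)))
    metadata: dict[str, Any] = {k: v for k, v in meta.items()}
    if cols[1] == "force_N":
        return ForceTrajectory(t, df["force_N"].to_numpy(dtype=float), fs, metadata)
    k = spring_constant
    if k is None and "spring_constant_N_per_m" in meta:
        k = float(meta["spring_constant_N_per_m"])
    if k is None:
        raise FileFormatError(
            f"{path}: deflection_m column requires a spring constant "
            "(metadata spring_constant_N_per_m or the spring_constant argument)"
        )
    d = DeflectionTrajectory(t, df["deflection_m"].to_numpy(dtype=float), fs, metadata)
    return deflection_to_force(d, k)


def read_deflection_trajectory(path) -> DeflectionTrajectory:
    """Read a deflection trajectory without converting to force."""
    df, meta = _read_table(path)
    _require_columns(df, path, ("time_s", "deflection_m"))
    t = df["time_s"].to_numpy(dtype=float)
    _validate_time(t, path)
    fs = float(meta.get("sampling_rate_hz", 1.0 / np.mean(np.diff(t))))
    t = t[0] + np.arange(t.size) * float(np.mean(np.diff(t)))
    return DeflectionTrajectory(t, df["deflection_m"].to_numpy(dtype=float), fs,
                                dict(meta))


def _validate_time(t: np.ndarray, path) -> None:
    if t.size < 2:
        raise FileFormatError(f"{path}: trajectory needs >= 2 rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 2  # +1 for 0-base, +1 for header row
        raise FileFormatError(f"{path}: time not strictly increasing at data row {row}")
    dt0 = float(np.mean(dt))
    bad = np.abs(dt - dt0) > 1e-6 * dt0
    if np.any(bad):
        row = int(np.argmax(bad)) + 2
        raise FileFormatError(f"{path}: non-uniform time grid at data row {row}")


# -------------------------------------------------------------------- force curves
def write_force_curve(path, curve: ForceCurve, extra_metadata: dict | None = None) -> None:
    meta = {"spring_constant_N_per_m": curve.spring_constant, "direction": "approach"}
    meta.update(extra_metadata or {})
    df = pd.DataFrame({"z_m": curve.z, "deflection_m": curve.deflection})
    _write_table(path, df, meta)


def read_force_curve(path, spring_constant: float | None = None) -> ForceCurve:
    df, meta = _read_table(path)
    _require_columns(df, path, ("z_m", "deflection_m"))
    z = df["z_m"].to_numpy(dtype=float)
    d = df["deflection_m"].to_numpy(dtype=float)
    if z.size < 2 or np.any(np.diff(z) <= 0):
        raise FileFormatError(
            f"{path}: approach segment missing (z must be strictly increasing)"
        )
    k = spring_constant
    if k is None:
        if "spring_constant_N_per_m" not in meta:
            raise FileFormatError(f"{path}: missing spring_constant_N_per_m metadata")
        k = float(meta["spring_constant_N_per_m"])
    return ForceCurve(z, d, k, metadata=dict(meta))


# ----------------------------------------------------------------------- dwell maps
def write_dwell_map(dirpath, sim: SimulatedDwellMap) -> Path:
    """Directory layout: index.tsv (row, col, x_m, y_m, curve_file, dwell_file)
    plus one curve CSV and one dwell CSV per grid point."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in sim.points:
        stem = f"r{p.row:03d}_c{p.col:03d}"
        curve_file, dwell_file = f"curve_{stem}.csv", f"dwell_{stem}.csv"
        write_force_curve(dirpath / curve_file, p.curve)
        write_trajectory(dirpath / dwell_file, p.dwell)
        rows.append({"row": p.row, "col": p.col, "x_m": p.x, "y_m": p.y,
                     "curve_file": curve_file, "dwell_file": dwell_file})
    index = dirpath / "index.tsv"
    pd.DataFrame(rows).to_csv(index, sep="\t", index=False, float_format=_FLOAT_FMT)
    return index


def read_dwell_map(index_path) -> list[SimulatedDwellPoint]:
    """Load a dwell-map directory back into raw per-point records."""
    index_path = Path(index_path)
    base = index_path.parent
    df = pd.read_csv(index_path, sep="\t")
    for col in ("row", "col", "x_m", "y_m", "curve_file", "dwell_file"):
        if col not in df.columns:
            raise FileFormatError(f"{index_path}: missing column(s) ['{col}']")
    points = []
    for rec in df.itertuples(index=False):
        curve = read_force_curve(base / rec.curve_file)
        dwell = read_trajectory(base / rec.dwell_file)
        points.append(SimulatedDwellPoint(
            row=int(rec.row), col=int(rec.col), x=float(rec.x_m), y=float(rec.y_m),
            curve=curve, dwell=dwell, truth={},
        ))
    return points


def write_map_tables(dirpath, dmap: DwellMap) -> None:
    """Long-format TSV plus one matrix TSV per mapped quantity."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    dmap.to_frame().to_csv(dirpath / "map_long.tsv", sep="\t", index=False,
                           float_format=_FLOAT_FMT)
    for q in ("height", "E", "beat_force", "n_beats"):
        np.savetxt(dirpath / f"map_{q}.tsv", dmap.matrix(q), delimiter="\t",
                   fmt=_FLOAT_FMT)


# ----------------------------------------------------------------------- point sets
def write_point_set(path, ps: MechanoPointSet) -> None:
    _write_table(path, pd.DataFrame({"force_N": ps.force, "E_Pa": ps.modulus}),
                 {"label": ps.label})


def read_point_set(path) -> MechanoPointSet:
    df, meta = _read_table(path)
    _require_columns(df, path, ("force_N", "E_Pa"))
    return MechanoPointSet(df["force_N"].to_numpy(dtype=float),
                           df["E_Pa"].to_numpy(dtype=float),
                           label=meta.get("label", ""))


# -------------------------------------------------------------------- dose series
def write_dose_series(path, series: DoseResponseSeries) -> None:
    _write_table(path, pd.DataFrame({"dose_mol_L": series.dose,
                                     "force_N": series.force}), {})


def read_dose_series(path) -> DoseResponseSeries:
    df, meta = _read_table(path)
    _require_columns(df, path, ("dose_mol_L", "force_N"))
    return DoseResponseSeries(df["dose_mol_L"].to_numpy(dtype=float),
                              df["force_N"].to_numpy(dtype=float),
                              metadata=dict(meta))


# --------------------------------------------------------------------- run configs
def _schema_from_dataclass(cls) -> set[str]:
    return set(cls.__dataclass_fields__)


def _run_config_schema() -> dict[str, set[str]]:
    from . import synthetic
    from .dwellmap import DwellAnalysisParams

    return {
        "beats": _schema_from_dataclass(synthetic.BeatTrainConfig),
        "thermal": {"spring_constant", "temperature", "duration", "sampling_rate", "seed"},
        "curve": _schema_from_dataclass(synthetic.HertzCurveConfig),
        "dwellmap": _schema_from_dataclass(synthetic.DwellMapConfig),
        "doseresponse": _schema_from_dataclass(synthetic.DoseResponseConfig),
        "analysis": _schema_from_dataclass(DwellAnalysisParams),
        "stats": {"method", "n_perm", "seed", "bootstrap_B"},
        "seed": None,  # scalar master seed
    }


RUN_CONFIG_SCHEMA = _run_config_schema()


def load_run_config(path) -> dict[str, Any]:
    """Load a YAML run configuration, rejecting unknown keys by name."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: run config must be a mapping")
    for section, val in cfg.items():
        if section not in RUN_CONFIG_SCHEMA:
            raise ConfigError(f"{path}: unknown config section '{section}'")
        allowed = RUN_CONFIG_SCHEMA[section]
        if allowed is None:
            continue
        if not isinstance(val, dict):
            raise ConfigError(f"{path}: section '{section}' must be a mapping")
        for key in val:
            if key not in allowed:
                raise ConfigError(f"{path}: unknown key '{section}.{key}'")
    return cfg
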