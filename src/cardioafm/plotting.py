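"""Quick-look plots for trajectories, dwell maps and point sets.

These are working plots (matplotlib), not publication figures; the joint
density view mirrors the usual contour-plus-marginal presentation of
(beat force, modulus) point clouds.
"""
from __future__ import annotations

import numpy as np

from .beats import BeatEvent
from .dwellmap import DwellMap, MechanoPointSet
from .trajectory import ForceTrajectory

__all__ = ["plot_trajectory", "plot_dwell_map", "plot_point_sets"]


def plot_trajectory(traj: ForceTrajectory, events: list[BeatEvent] | None = None,
                    ax=None):
    """Force trajectory with detected beats marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(traj.time, traj.force * 1e9, lw=0.5, color="0.3")
    if events:
        ax.plot([e.t_peak for e in events],
                [e.force * 1e9 for e in events], "rv", ms=4, label="beats")
        ax.legend(frameon=False)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("force (nN)")
    return ax


def plot_dwell_map(dmap: DwellMap, quantity: str = "beat_force", ax=None):
    """Matrix view of one mapped quantity (NaN cells blank)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    mat = dmap.matrix(quantity)
    scale, unit = (1e9, "nN") if quantity == "beat_force" else (1.0, "")
    im = ax.imshow(mat * scale, origin="upper", interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, label=f"{quantity} {unit}".strip())
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    return ax


def plot_point_sets(sets: list[MechanoPointSet], ax=None, contour: bool = False):
    """Joint (beat force, log10 modulus) scatter for one or more conditions,
    optionally with a kernel-density contour overlay."""
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for ps in sets:
        ax.scatter(ps.log10_modulus, ps.force * 1e9, s=12, alpha=0.6,
                   label=ps.label or None)
        if contour and len(ps) >= 10:
            xy = np.vstack([ps.log10_modulus, ps.force * 1e9])
            kde = gaussian_kde(xy)
            xg = np.linspace(xy[0].min(), xy[0].max(), 60)
            yg = np.linspace(xy[1].min(), xy[1].max(), 60)
            X, Y = np.meshgrid(xg, yg)
            Z = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(X.shape)
            ax.contour(X, Y, Z, levels=5, linewidths=0.8)
    ax.set_xlabel("log10 Young's modulus (Pa)")
    ax.set_ylabel("beat force (nN)")
    if any(ps.label for ps in sets):
        ax.legend(frameon=False)
    return ax
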