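"""Hertz-family contact mechanics: force curves, contact-point search,
Young's-modulus fitting.

The instrument ramps the z piezo toward the cell while recording cantilever
deflection d.  Before contact the deflection is flat (offset d0); beyond the
contact point z_c the tip indents the cell by

    delta = (z - z_c) - (d - d0)

and the force F = k * (d - d0) follows the geometry's contact law

    cone    (Sneddon)   F = (2/pi) * tan(alpha) * E/(1-nu^2) * delta^2
    sphere  (Hertz)     F = (4/3)  * sqrt(R)    * E/(1-nu^2) * delta^(3/2)
    pyramid (Bilodeau)  F = 0.7453 * tan(alpha) * E/(1-nu^2) * delta^2

``HertzModel`` is a statsmodels-style model object: build it from a
:class:`ForceCurve`, call :meth:`~HertzModel.fit`, get a :class:`HertzFit`
results object with estimates, residuals and ``summary()``.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, NamedTuple

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitError, NoContactError

__all__ = [
    "ForceCurve",
    "ContactPoint",
    "HertzModel",
    "HertzFit",
    "geometry_prefactor",
    "geometry_exponent",
    "hertz_force",
    "find_contact_point",
    "fit_hertz",
    "indentation_at_trigger",
    "cell_height",
]

_EXPONENT = {"cone": 2.0, "pyramid": 2.0, "sphere": 1.5}
_BILODEAU = 0.7453  # four-sided pyramid constant


def geometry_exponent(geometry: str) -> float:
    try:
        return _EXPONENT[geometry]
    except KeyError:
        raise ValueError(f"unknown tip geometry {geometry!r}") from None


def geometry_prefactor(
    geometry: str,
    tip_half_angle_deg: float | None = None,
    tip_radius: float | None = None,
) -> float:
    """Geometric factor g such that F = g * E/(1-nu^2) * delta^p.

    Cone and pyramid take ``tip_half_angle_deg`` (half-opening angle from the
    indentation axis); sphere takes ``tip_radius`` in metres.  Exactly one tip
    parameter must be supplied for the chosen geometry.
    """
    if geometry in ("cone", "pyramid"):
        if tip_half_angle_deg is None or tip_radius is not None:
            raise ValueError(f"{geometry} geometry requires tip_half_angle_deg only")
        if not 0 < tip_half_angle_deg < 90:
            raise ValueError("tip half-angle must be in (0, 90) degrees")
        t = math.tan(math.radians(tip_half_angle_deg))
        return (2.0 / math.pi) * t if geometry == "cone" else _BILODEAU * t
    if geometry == "sphere":
        if tip_radius is None or tip_half_angle_deg is not None:
            raise ValueError("sphere geometry requires tip_radius only")
        if tip_radius <= 0:
            raise ValueError("tip_radius must be positive")
        return (4.0 / 3.0) * math.sqrt(tip_radius)
    raise ValueError(f"unknown tip geometry {geometry!r}")


def hertz_force(
    delta,
    E: float,
    geometry: str = "cone",
    nu: float = 0.5,
    tip_half_angle_deg: float | None = None,
    tip_radius: float | None = None,
):
    """Contact force (N) at indentation ``delta`` (m); vectorised."""
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0 <= nu <= 0.5:
        raise ValueError("Poisson ratio must lie in [0, 0.5]")
    g = geometry_prefactor(geometry, tip_half_angle_deg, tip_radius)
    p = geometry_exponent(geometry)
    d = np.clip(np.asarray(delta, dtype=float), 0.0, None)
    return g * E / (1.0 - nu**2) * d**p


@dataclass
class ForceCurve:
    """Approach segment of a force-distance curve.

    z is the piezo extension in metres, increasing toward the sample;
    deflection is in metres. ``force`` derives from the spring constant.
    """

    z: np.ndarray
    deflection: np.ndarray
    spring_constant: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z.ndim != 1 or self.z.size < 2:
            raise ValueError("force curve needs >= 2 samples")
        if self.deflection.shape != self.z.shape:
            raise ValueError("z and deflection must have identical shape")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("approach segment requires strictly increasing z")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")

    def __len__(self) -> int:
        return self.z.size

    @property
    def force(self) -> np.ndarray:
        return self.spring_constant * self.deflection


class ContactPoint(NamedTuple):
    z_c: float
    d0: float
    index: int


def _robust_noise(d: np.ndarray) -> float:
    dd = np.diff(d)
    return 1.4826 * float(np.median(np.abs(dd - np.median(dd)))) / math.sqrt(2.0)


def find_contact_point(
    curve: ForceCurve,
    geometry: str = "cone",
    min_pre_points: int = 10,
    n_coarse: int = 128,
) -> ContactPoint:
    """Locate the contact point by piecewise least squares.

    Every candidate index splits the curve into a flat pre-contact segment
    (level d0 = mean of the segment) and a post-contact segment modelled as
    d - d0 = a * delta^p with delta = (z - z_c) - (d - d0); the candidate
    minimising the total squared deflection residual wins.  A coarse grid is
    scanned first and the winner refined at full resolution.
    """
    z, d = curve.z, curve.deflection
    n = z.size
    if n < 50:
        raise ValueError("contact-point search needs >= 50 points")
    p = geometry_exponent(geometry)

    sigma = _robust_noise(d)
    n_pre = max(5, n // 10)
    rise = float(np.mean(d[-5:]) - np.mean(d[:n_pre]))
    rise_sd = sigma * math.sqrt(1.0 / 5.0 + 1.0 / n_pre)
    if rise < max(5.0 * rise_sd, 1e-15):
        raise NoContactError("no deflection rise anywhere on the curve")

    cum_d = np.concatenate(([0.0], np.cumsum(d)))
    cum_d2 = np.concatenate(([0.0], np.cumsum(d * d)))

    def sse(i: int) -> float:
        d0 = cum_d[i] / i
        pre = cum_d2[i] - i * d0 * d0
        dd = d[i:] - d0
        delta = np.clip((z[i:] - z[i]) - dd, 0.0, None)
        x = delta**p
        xx = float(x @ x)
        a = max(float(x @ dd) / xx, 0.0) if xx > 0 else 0.0
        r = dd - a * x
        return pre + float(r @ r)

    i_min = max(min_pre_points, int(0.02 * n))
    i_max = n - 20
    if i_max <= i_min:
        raise ValueError("pre-contact span too short for contact search")
    step = max(1, (i_max - i_min) // n_coarse)
    coarse = range(i_min, i_max, step)
    best = min(coarse, key=sse)
    lo, hi = max(i_min, best - step), min(i_max, best + step + 1)
    best = min(range(lo, hi), key=sse)
    d0 = cum_d[best] / best
    return ContactPoint(z_c=float(z[best]), d0=float(d0), index=best)


@dataclass
class HertzFit:
    """Results of a Hertz fit; carries the estimate, its provenance and
    goodness-of-fit. ``E_linear`` is the closed-form linearised estimate
    (regression of F on delta^p) used as an internal cross-check."""

    E: float
    nu: float
    geometry: str
    tip_half_angle_deg: float | None
    tip_radius: float | None
    contact_point: float
    deflection_offset: float
    residual_rms: float
    n_points: int
    fit_range: float | None
    E_linear: float
    max_force: float
    ok: bool
    message: str = "ok"

    @property
    def prefactor(self) -> float:
        return geometry_prefactor(self.geometry, self.tip_half_angle_deg, self.tip_radius)

    @property
    def exponent(self) -> float:
        return geometry_exponent(self.geometry)

    def predict(self, delta):
        return hertz_force(
            delta, self.E, self.geometry, self.nu,
            self.tip_half_angle_deg, self.tip_radius,
        )

    def summary(self) -> str:
        tip = (
            f"half-angle {self.tip_half_angle_deg:g} deg"
            if self.tip_half_angle_deg is not None
            else f"radius {self.tip_radius:.3g} m"
        )
        lines = [
            "Hertz contact fit",
            "=================",
            f"geometry:          {self.geometry} ({tip}), nu = {self.nu:g}",
            f"Young's modulus E: {self.E:.6g} Pa (linearised cross-check {self.E_linear:.6g} Pa)",
            f"contact point z_c: {self.contact_point * 1e6:.4f} um",
            f"deflection offset: {self.deflection_offset * 1e9:.3f} nm",
            f"residual RMS:      {self.residual_rms * 1e12:.3f} pN over {self.n_points} points",
            f"max force in fit:  {self.max_force * 1e12:.1f} pN",
            f"status:            {'ok' if self.ok else 'FAILED'} ({self.message})",
        ]
        return "\n".join(lines)


class HertzModel:
    """Hertz contact model for one approach curve.

    Parameters
    ----------
    curve : ForceCurve
    geometry : {'cone', 'sphere', 'pyramid'}
    tip_half_angle_deg / tip_radius : exactly one, per geometry.
    nu : Poisson ratio; 0.5 treats the cell as incompressible.
    """

    def __init__(
        self,
        curve: ForceCurve,
        geometry: str = "cone",
        tip_half_angle_deg: float | None = 35.0,
        tip_radius: float | None = None,
        nu: float = 0.5,
    ) -> None:
        if geometry == "sphere" and tip_radius is not None:
            tip_half_angle_deg = None
        self.curve = curve
        self.geometry = geometry
        self.tip_half_angle_deg = tip_half_angle_deg
        self.tip_radius = tip_radius
        self.nu = nu
        self.prefactor = geometry_prefactor(geometry, tip_half_angle_deg, tip_radius)
        self.exponent = geometry_exponent(geometry)

    def _post_contact(self, contact: ContactPoint, fit_range: float | None):
        z, d, k = self.curve.z, self.curve.deflection, self.curve.spring_constant
        dd = d[contact.index:] - contact.d0
        delta = (z[contact.index:] - contact.z_c) - dd
        mask = delta > 0
        if fit_range is not None:
            mask &= delta <= fit_range
        return delta[mask], k * dd[mask]

    def fit(
        self,
        fit_range: float | None = None,
        contact: ContactPoint | None = None,
        refine_contact: bool = False,
    ) -> HertzFit:
        """Estimate E.

        Two-stage by default: grid search for the contact point, then a
        least-squares estimate of E with (z_c, d0) fixed (linear in E, so the
        solution is closed-form; it is also run through a bounded nonlinear
        solver when ``refine_contact`` to co-refine z_c and d0).
        """
        if contact is None:
            contact = find_contact_point(self.curve, self.geometry)
        delta, F = self._post_contact(contact, fit_range)
        if delta.size < 20:
            raise FitError(f"only {delta.size} post-contact points (need >= 20)")
        c = self.prefactor / (1.0 - self.nu**2)
        x = delta**self.exponent
        a = float(x @ F) / float(x @ x)
        E_lin = a / c
        E, z_c, d0 = E_lin, contact.z_c, contact.d0
        if refine_contact and E_lin > 0:
            E, z_c, d0 = self._joint_refine(E_lin, contact, fit_range)
            contact = ContactPoint(z_c, d0, contact.index)
            delta, F = self._post_contact(contact, fit_range)
        resid = F - c * E * np.clip(delta, 0, None) ** self.exponent
        rms = float(np.sqrt(np.mean(resid**2))) if delta.size else float("nan")
        ok = np.isfinite(E) and E > 0
        return HertzFit(
            E=float(E),
            nu=self.nu,
            geometry=self.geometry,
            tip_half_angle_deg=self.tip_half_angle_deg,
            tip_radius=self.tip_radius,
            contact_point=float(z_c),
            deflection_offset=float(d0),
            residual_rms=rms,
            n_points=int(delta.size),
            fit_range=fit_range,
            E_linear=float(E_lin),
            max_force=float(np.max(F)) if F.size else float("nan"),
            ok=bool(ok),
            message="ok" if ok else "nonpositive modulus estimate",
        )

    def _joint_refine(self, E0: float, contact: ContactPoint, fit_range: float | None):
        """Nonlinear co-refinement of (log E, z_c, d0) on the deflection residuals
        of the full piecewise model."""
        z, d, k = self.curve.z, self.curve.deflection, self.curve.spring_constant
        c = self.prefactor / (1.0 - self.nu**2)
        p = self.exponent
        dz = float(np.mean(np.diff(z)))

        def residuals(theta):
            logE, z_c, d0 = theta
            a = c * math.exp(logE) / k  # deflection-space coefficient
            dd = d - d0
            delta = np.clip((z - z_c) - dd, 0.0, None)
            if fit_range is not None:
                delta = np.where(delta <= fit_range, delta, 0.0)
            return dd - a * delta**p

        res = least_squares(
            residuals,
            x0=[math.log(E0), contact.z_c, contact.d0],
            bounds=(
                [math.log(E0) - 5, contact.z_c - 50 * dz, -np.inf],
                [math.log(E0) + 5, contact.z_c + 50 * dz, np.inf],
            ),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        logE, z_c, d0 = res.x
        return math.exp(logE), float(z_c), float(d0)


def fit_hertz(
    curve: ForceCurve,
    geometry: str = "cone",
    tip_half_angle_deg: float | None = 35.0,
    tip_radius: float | None = None,
    nu: float = 0.5,
    fit_range: float | None = None,
    refine_contact: bool = False,
) -> HertzFit:
    """Convenience wrapper: build a :class:`HertzModel` and fit it."""
    return HertzModel(curve, geometry, tip_half_angle_deg, tip_radius, nu).fit(
        fit_range=fit_range, refine_contact=refine_contact
    )


def indentation_at_trigger(fit: HertzFit, trigger: float) -> float:
    """Indentation depth (m) at which the fitted force law reaches ``trigger`` (N)."""
    if trigger < 0:
        raise ValueError("trigger force must be >= 0")
    if trigger == 0:
        return 0.0
    if not fit.ok:
        raise FitError("cannot invert a failed Hertz fit")
    if np.isfinite(fit.max_force) and trigger > fit.max_force * (1 + 1e-9):
        raise ValueError(
            f"trigger {trigger:.3g} N above the maximum fitted force {fit.max_force:.3g} N"
        )
    c = fit.prefactor * fit.E / (1.0 - fit.nu**2)
    return float((trigger / c) ** (1.0 / fit.exponent))


def cell_height(cell: HertzFit | float, substrate_z_c: float) -> float:
    """Local cell height: extra piezo extension needed to reach the glass.

    height = z_c(substrate) - z_c(cell); negative values are flagged with a
    warning (probable mis-ordered reference) but returned unchanged.
    """
    z_cell = cell.contact_point if isinstance(cell, HertzFit) else float(cell)
    h = float(substrate_z_c) - z_cell
    if h < 0:
        warnings.warn(
            "negative cell height: substrate contact precedes cell contact "
            "(reference probably mis-ordered)",
            stacklevel=2,
        )
    return h
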