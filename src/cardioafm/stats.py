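"""Statistical layer: nonparametric bootstrap, Mann-Whitney,
two-dimensional two-sample Kolmogorov-Smirnov (Fasano-Franceschini), and
Hill-equation EC50 fitting.

The 2D KS statistic generalises the classic KS distance to bivariate point
clouds: each observation of each sample in turn serves as the origin of four
quadrants; D is the average, over the two samples' per-origin maxima, of the
largest absolute difference between the two samples' quadrant occupation
fractions.  Its null distribution depends on the (unknown) dependence
structure, so the defensible p-value is by permutation of the pooled labels;
the correlation-corrected asymptotic formula is offered for speed and for
p-values far below permutation resolution.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy import stats as spstats

from .exceptions import UnidentifiableEC50Error
from .synthetic import DoseResponseSeries, hill_response

__all__ = [
    "BootstrapResult",
    "bootstrap_ci",
    "MannWhitneyResult",
    "mann_whitney",
    "ks2d_statistic",
    "ks2d_test",
    "KS2DResult",
    "HillModel",
    "HillFit",
    "fit_hill",
]


# ------------------------------------------------------------------------ bootstrap
@dataclass
class BootstrapResult:
    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    B: int
    seed: int
    transform: str
    n: int

    def summary(self) -> str:
        return (f"{self.statistic} = {self.estimate:.6g} "
                f"(95% CI {self.ci_low:.6g} - {self.ci_high:.6g}; "
                f"B = {self.B}, n = {self.n}, transform = {self.transform})")


def bootstrap_ci(
    values,
    statistic: str = "mean",
    B: int = 10000,
    seed: int = 0,
    transform: str = "identity",
    ci: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap CI for the mean.

    ``transform='log'`` works on natural-log values and back-transforms the
    estimate and interval, i.e. reports the geometric mean — the convention
    for right-skewed moduli.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("bootstrap needs n >= 2")
    if statistic != "mean":
        raise ValueError("only statistic='mean' is supported")
    if B < 1000:
        raise ValueError("B must be >= 1000 for a stable percentile CI")
    if transform == "log":
        if np.any(v <= 0):
            raise ValueError("log transform requires strictly positive values")
        w = np.log(v)
    elif transform == "identity":
        w = v
    else:
        raise ValueError(f"unknown transform {transform!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, w.size, size=(B, w.size))
    boots = w[idx].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    est = float(np.mean(w))
    if transform == "log":
        est, lo, hi = math.exp(est), math.exp(lo), math.exp(hi)
    return BootstrapResult(statistic="mean", estimate=est, ci_low=float(lo),
                           ci_high=float(hi), B=B, seed=seed, transform=transform,
                           n=v.size)


# ---------------------------------------------------------------------- Mann-Whitney
@dataclass
class MannWhitneyResult:
    U: float
    p: float
    method: str
    n1: int
    n2: int


def mann_whitney(x, y, alternative: str = "two-sided") -> MannWhitneyResult:
    """Mann-Whitney U test.

    Exact enumeration p when both samples are tie-free and n1 + n2 <= 16;
    otherwise the normal approximation with midranks and tie-corrected
    variance.  U is the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size + y.size <= 16
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = spstats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue),
                             method=method, n1=x.size, n2=y.size)


# --------------------------------------------------------------------------- 2D KS
def _as_xy(sample) -> np.ndarray:
    if hasattr(sample, "to_xy"):
        return sample.to_xy()
    a = np.asarray(sample, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("2D KS expects (n, 2) observations")
    return a


def _quadrant_fraction_diff(origins: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Max over origins and the four open quadrants of |frac_a - frac_b|."""
    best = 0.0
    for ox, oy in origins:
        gx_a, gy_a = a[:, 0] > ox, a[:, 1] > oy
        gx_b, gy_b = b[:, 0] > ox, b[:, 1] > oy
        lx_a, ly_a = a[:, 0] < ox, a[:, 1] < oy
        lx_b, ly_b = b[:, 0] < ox, b[:, 1] < oy
        for qa, qb in (
            (gx_a & gy_a, gx_b & gy_b),
            (lx_a & gy_a, lx_b & gy_b),
            (lx_a & ly_a, lx_b & ly_b),
            (gx_a & ly_a, gx_b & ly_b),
        ):
            best = max(best, abs(qa.mean() - qb.mean()))
    return best


def ks2d_statistic(a, b) -> float:
    """Fasano-Franceschini two-sample statistic on bivariate samples.

    Points lying exactly on an origin's axes belong to no open quadrant (a
    measure-zero event for continuous data); fractions are relative to each
    sample's full size.
    """
    A, B_ = _as_xy(a), _as_xy(b)
    if A.shape[0] < 3 or B_.shape[0] < 3:
        raise ValueError("2D KS needs >= 3 points per sample")
    d1 = _quadrant_fraction_diff(A, A, B_)
    d2 = _quadrant_fraction_diff(B_, A, B_)
    return 0.5 * (d1 + d2)


def _quadrant_matrices(pts: np.ndarray) -> np.ndarray:
    """(4, N, N) float32 indicators: Q[q, i, j] = point j in quadrant q of
    origin i (open quadrants)."""
    x, y = pts[:, 0], pts[:, 1]
    gx = x[None, :] > x[:, None]
    lx = x[None, :] < x[:, None]
    gy = y[None, :] > y[:, None]
    ly = y[None, :] < y[:, None]
    return np.stack([gx & gy, lx & gy, lx & ly, gx & ly]).astype(np.float64)


def _d_from_membership(Q: np.ndarray, in_a: np.ndarray) -> float:
    """D for one labelling, via 4 matvecs on precomputed quadrant indicators."""
    za = in_a.astype(np.float64)
    zb = 1.0 - za
    n1, n2 = za.sum(), zb.sum()
    fa = Q @ za / n1  # (4, N) quadrant fractions of sample a at every origin
    fb = Q @ zb / n2
    diff = np.abs(fa - fb).max(axis=0)  # per-origin max over quadrants
    d1 = diff[in_a].max()
    d2 = diff[~in_a].max()
    return 0.5 * float(d1 + d2)


@dataclass
class KS2DResult:
    D: float
    p: float
    n1: int
    n2: int
    method: str
    seed: int | None
    H: bool  # reject at the 5% level

    def summary(self) -> str:
        return (f"2D KS: D = {self.D:.4f}, p = {self.p:.4g} ({self.method}), "
                f"n = {self.n1} vs {self.n2}, H = {int(self.H)}")


def _ks2d_asymptotic_p(D: float, a: np.ndarray, b: np.ndarray) -> float:
    """Correlation-corrected asymptotic tail probability (Press et al.)."""
    def corr(s):
        if np.std(s[:, 0]) == 0 or np.std(s[:, 1]) == 0:
            return 0.0
        return float(np.corrcoef(s[:, 0], s[:, 1])[0, 1])

    n1, n2 = a.shape[0], b.shape[0]
    n_eff = n1 * n2 / (n1 + n2)
    rr = math.sqrt(max(0.0, 1.0 - 0.5 * (corr(a) ** 2 + corr(b) ** 2)))
    sq = math.sqrt(n_eff)
    lam = sq * D / (1.0 + rr * (0.25 - 0.75 / sq))
    return float(min(max(special.kolmogorov(lam), 1e-300), 1.0))


def ks2d_test(
    a,
    b,
    method: str = "permutation",
    n_perm: int = 10000,
    seed: int = 0,
) -> KS2DResult:
    """Two-sample 2D KS test.

    Permutation p (default): pool the observations, reshuffle the sample
    labels ``n_perm`` times, p = (1 + #{D* >= D_obs}) / (1 + n_perm).
    Asymptotic p: Press et al.'s correlation-corrected KS tail — the only
    route to p-values far below permutation resolution.
    """
    A, B_ = _as_xy(a), _as_xy(b)
    if A.shape[0] < 3 or B_.shape[0] < 3:
        raise ValueError("2D KS needs >= 3 points per sample")
    n1, n2 = A.shape[0], B_.shape[0]
    pooled = np.concatenate([A, B_], axis=0)
    Q = _quadrant_matrices(pooled)
    in_a = np.zeros(n1 + n2, dtype=bool)
    in_a[:n1] = True
    D_obs = _d_from_membership(Q, in_a)

    if method == "asymptotic":
        p = _ks2d_asymptotic_p(D_obs, A, B_)
        return KS2DResult(D=D_obs, p=p, n1=n1, n2=n2, method="asymptotic",
                          seed=None, H=p < 0.05)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    count = 0
    membership = in_a.copy()
    for _ in range(n_perm):
        rng.shuffle(membership)
        if _d_from_membership(Q, membership) >= D_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return KS2DResult(D=D_obs, p=p, n1=n1, n2=n2, method="permutation",
                      seed=seed, H=p < 0.05)


# ----------------------------------------------------------------------------- Hill
@dataclass
class HillFit:
    """Results of a Hill-equation dose-response fit."""

    ec50: float
    hill: float
    baseline: float
    fmax: float
    residual_rms: float
    ec50_ci_low: float
    ec50_ci_high: float
    n: int
    bootstrap_B: int

    def predict(self, dose):
        return hill_response(dose, self.baseline, self.fmax, self.ec50, self.hill)

    def summary(self) -> str:
        ci = (f"(95% bootstrap CI {self.ec50_ci_low:.4g} - {self.ec50_ci_high:.4g}, "
              f"B = {self.bootstrap_B})" if self.bootstrap_B else "(no bootstrap)")
        return "\n".join([
            "Hill dose-response fit",
            "======================",
            f"EC50:        {self.ec50:.6g} mol/L {ci}",
            f"Hill coeff:  {self.hill:.4g}",
            f"baseline:    {self.baseline:.6g} N",
            f"max:         {self.fmax:.6g} N",
            f"residualRMS: {self.residual_rms:.4g} N over {self.n} observations",
        ])


class HillModel:
    """Hill dose-response model, response = baseline + (max - baseline) /
    (1 + (EC50/dose)^h), fitted by least squares with the dose axis handled
    on a log10 scale.

    Requires >= 4 distinct doses spanning >= 2 decades.
    """

    def __init__(self, dose, response) -> None:
        self.dose = np.asarray(dose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.dose.shape != self.response.shape or self.dose.ndim != 1:
            raise ValueError("dose and response must be matching 1-D arrays")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be strictly positive")
        distinct = np.unique(self.dose)
        if distinct.size < 4:
            raise ValueError("need >= 4 distinct doses")
        if distinct.max() / distinct.min() < 100:
            raise ValueError("dose ladder must span >= 2 decades")

    @classmethod
    def from_series(cls, series: DoseResponseSeries) -> "HillModel":
        return cls(series.dose, series.force)

    def _fit_params(self, dose, resp, fix_hill):
        logd = np.log10(dose)

        lo_mask = dose <= np.quantile(dose, 0.15)
        hi_mask = dose >= np.quantile(dose, 0.85)
        # responses are ~nN while log-dose and Hill slope are O(1); fit in
        # span-normalised units so the optimiser sees comparable scales
        scale = max(float(np.max(np.abs(resp))), 1e-15)
        y = resp / scale
        b0 = float(np.mean(y[lo_mask]))
        m0 = float(np.mean(y[hi_mask]))
        e0 = float(np.median(logd))

        if fix_hill is None:
            def model(ld, b, m, le, h):
                return b + (m - b) / (1.0 + 10.0 ** (h * (le - ld)))
            p0 = [b0, m0, e0, 1.0]
            bounds = ([-np.inf, -np.inf, logd.min() - 3, 0.1],
                      [np.inf, np.inf, logd.max() + 3, 10.0])
        else:
            h_fixed = float(fix_hill)

            def model(ld, b, m, le):
                return b + (m - b) / (1.0 + 10.0 ** (h_fixed * (le - ld)))
            p0 = [b0, m0, e0]
            bounds = ([-np.inf, -np.inf, logd.min() - 3],
                      [np.inf, np.inf, logd.max() + 3])
        popt, _ = optimize.curve_fit(model, logd, y, p0=p0, bounds=bounds,
                                     maxfev=20000, xtol=1e-14, ftol=1e-14,
                                     gtol=1e-14)
        resid = scale * (y - model(logd, *popt))
        if fix_hill is None:
            b, m, le, h = popt
        else:
            b, m, le = popt
            h = float(fix_hill)
        return (float(b) * scale, float(m) * scale, float(10.0 ** le), float(h),
                resid, scale)

    def fit(self, fix_hill: float | None = None, bootstrap_B: int = 500,
            seed: int = 0) -> HillFit:
        """Fit and (optionally) bootstrap the EC50 by resampling observations."""
        b, m, ec50, h, resid, scale = self._fit_params(self.dose, self.response, fix_hill)
        rms = float(np.sqrt(np.mean(resid**2)))
        span = m - b
        if span <= 0 or span <= 2.0 * rms:
            raise UnidentifiableEC50Error(
                f"response span {span:.3g} N not distinguishable from noise "
                f"(residual RMS {rms:.3g} N); EC50 unidentifiable"
            )
        lo = hi = float("nan")
        B = 0
        if bootstrap_B:
            rng = np.random.default_rng(seed)
            boots = []
            n = self.dose.size
            for _ in range(bootstrap_B):
                idx = rng.integers(0, n, n)
                if np.unique(self.dose[idx]).size < 4:
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        _, _, e_b, _, _, _ = self._fit_params(
                            self.dose[idx], self.response[idx], fix_hill)
                    boots.append(e_b)
                except Exception:
                    continue
            if len(boots) >= max(100, bootstrap_B // 2):
                lo, hi = np.quantile(boots, [0.025, 0.975])
                B = len(boots)
        return HillFit(ec50=ec50, hill=h, baseline=b, fmax=m, residual_rms=rms,
                       ec50_ci_low=float(lo), ec50_ci_high=float(hi),
                       n=self.dose.size, bootstrap_B=B)


def fit_hill(series, fix_hill: float | None = None, bootstrap_B: int = 500,
             seed: int = 0) -> HillFit:
    """Fit the Hill model to a :class:`DoseResponseSeries` or (dose, response)."""
    if isinstance(series, DoseResponseSeries):
        model = HillModel.from_series(series)
    elif isinstance(series, tuple) and len(series) == 2:
        model = HillModel(*series)
    else:
        raise TypeError("series must be a DoseResponseSeries or (dose, response)")
    return model.fit(fix_hill=fix_hill, bootstrap_B=bootstrap_B, seed=seed)
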