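"""PAM fluorometry: quantum yields, rETR light curves and their fits.

From a dark-adapted sample, the maximum PSII quantum yield is
Fv/Fm = (Fm − F0)/Fm; during actinic illumination the effective yield is
ΔF/Fm′ = (Fm′ − F)/Fm′.  The relative electron transport rate at each
actinic step is rETR = ΔF/Fm′ · PAR · 0.5 (two photons per electron).
The rETR-vs-PAR rapid light curve is summarised by fitting the
rectangular hyperbola (saturating-exponential) model

    rETR(PAR) = rETR_max · (1 − exp(−α·PAR / rETR_max))

whose initial slope is α and whose saturation irradiance is
E_k = rETR_max / α.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PAMTrace",
    "RLCFit",
    "fv_fm",
    "effective_yield",
    "retr",
    "rectangular_hyperbola",
    "build_light_curve",
    "RapidLightCurveRegressor",
    "fit_rlc",
]

HEALTHY_FV_FM = (0.7, 0.8)  # typical range for unstressed green microalgae


@dataclass
class PAMTrace:
    """One rapid-light-curve measurement.

    ``steps`` columns: PAR (μmol·m⁻²·s⁻¹, non-decreasing), steady
    fluorescence F, and light-adapted maximal fluorescence Fm′.
    """

    F0: float
    Fm: float
    steps: np.ndarray  # (n, 3): PAR, F, Fm'

    def __post_init__(self) -> None:
        if not (self.Fm > self.F0 > 0):
            raise ValueError("require Fm > F0 > 0")
        self.steps = np.asarray(self.steps, dtype=float)
        if self.steps.ndim != 2 or self.steps.shape[1] != 3:
            raise ValueError("steps must have columns (PAR, F, Fm')")
        par, F, fmp = self.steps.T
        if np.any(par < 0) or np.any(np.diff(par) < 0):
            raise ValueError("PAR must be non-negative and non-decreasing")
        if np.any(F <= 0) or np.any(fmp < F):
            raise ValueError("require Fm' >= F > 0 at every step")

    @property
    def fv_fm(self) -> float:
        return fv_fm(self.F0, self.Fm)


@dataclass(frozen=True)
class RLCFit:
    """Rapid-light-curve parameters; e_k == retr_max/alpha by construction."""

    retr_max: float
    alpha: float
    rss: float = np.nan
    converged: bool = True

    @property
    def e_k(self) -> float:
        """Saturation PAR, rETR_max / α."""
        return self.retr_max / self.alpha


def fv_fm(F0: float, Fm: float) -> float:
    """Maximum PSII quantum yield (Fm − F0)/Fm after dark adaptation."""
    if Fm <= 0:
        raise ValueError("Fm must be > 0")
    if Fm <= F0:
        warnings.warn("Fm <= F0 is physically implausible", stacklevel=2)
    return (Fm - F0) / Fm


def effective_yield(F: float, Fm_prime: float) -> float:
    """Effective PSII quantum yield in light, ΔF/Fm′ = (Fm′ − F)/Fm′."""
    if Fm_prime <= 0:
        raise ValueError("Fm' must be > 0")
    if Fm_prime < F:
        warnings.warn("Fm' < F is physically implausible", stacklevel=2)
    return (Fm_prime - F) / Fm_prime


def retr(delta_yield, par):
    """Relative electron transport rate ΔF/Fm′ · PAR · 0.5."""
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise ValueError("PAR must be >= 0")
    out = np.asarray(delta_yield, dtype=float) * par * 0.5
    return out if out.ndim else float(out)


def rectangular_hyperbola(par, retr_max: float, alpha: float):
    """Saturating rETR model rETR_max·(1 − exp(−α·PAR/rETR_max))."""
    par = np.asarray(par, dtype=float)
    out = retr_max * (1.0 - np.exp(-alpha * par / retr_max))
    return out if out.ndim else float(out)


def build_light_curve(trace: PAMTrace) -> tuple[np.ndarray, np.ndarray]:
    """(PAR, rETR) points from a PAM trace via the yield and rETR formulas."""
    par, F, fmp = trace.steps.T
    dy = (fmp - F) / fmp
    return par, retr(dy, par)


class RapidLightCurveRegressor(RegressorMixin, BaseEstimator):
    """Least-squares rectangular-hyperbola fit to (PAR, rETR) points.

    Nelder–Mead on log-parameters (positivity without bounds);
    rETR_max₀ = max observed rETR, α₀ = slope of the first two nonzero-PAR
    points.  ``include_zero_par`` keeps the (0, 0) anchor point in the fit
    (default); some instruments exclude it, hence the flag.

    Attributes (after ``fit``): ``retr_max_``, ``alpha_``, ``e_k_``,
    ``rss_``, ``converged_``.
    """

    def __init__(self, include_zero_par: bool = True, xatol: float = 1e-8,
                 fatol: float = 1e-8, maxiter: int = 5000):
        self.include_zero_par = include_zero_par
        self.xatol = xatol
        self.fatol = fatol
        self.maxiter = maxiter

    def fit(self, X, y, sample_weight=None):
        par = np.asarray(X, dtype=float)
        if par.ndim == 2 and par.shape[1] == 1:
            par = par.ravel()
        yv = np.asarray(y, dtype=float)
        if par.shape != yv.shape:
            raise ValueError("X and y lengths differ")
        w = np.ones_like(par) if sample_weight is None else np.asarray(
            sample_weight, dtype=float)
        if not self.include_zero_par:
            keep = par > 0
            par, yv, w = par[keep], yv[keep], w[keep]
        if (par > 0).sum() < 3:
            raise ValueError(
                "rapid-light-curve fit needs at least 3 points with PAR > 0"
            )

        order = np.argsort(par)
        p_s, y_s = par[order], yv[order]
        retr_max0 = max(float(y_s.max()), 1e-6)
        pos = p_s > 0
        pp, yp = p_s[pos], y_s[pos]
        if pp.size >= 2 and pp[1] > pp[0]:
            alpha0 = (yp[1] - yp[0]) / (pp[1] - pp[0])
        else:
            alpha0 = yp[0] / pp[0]
        if not np.isfinite(alpha0) or alpha0 <= 0:
            alpha0 = retr_max0 / pp.max()

        def rss(log_theta):
            rmax, alpha = np.exp(log_theta)
            return float(np.sum(w * (yv - rectangular_hyperbola(par, rmax, alpha)) ** 2))

        res = minimize(
            rss,
            np.log([retr_max0, alpha0]),
            method="Nelder-Mead",
            options={"xatol": self.xatol, "fatol": self.fatol,
                     "maxiter": self.maxiter, "maxfev": self.maxiter},
        )
        if not res.success:
            warnings.warn(f"RLC fit did not converge: {res.message}", stacklevel=2)
        self.retr_max_, self.alpha_ = (float(v) for v in np.exp(res.x))
        self.e_k_ = self.retr_max_ / self.alpha_
        self.rss_ = float(res.fun)
        self.converged_ = bool(res.success)
        return self

    def predict(self, X):
        return rectangular_hyperbola(np.asarray(X, dtype=float),
                                     self.retr_max_, self.alpha_)


def fit_rlc(par, retr_values, **kwargs) -> RLCFit:
    """Fit the rectangular hyperbola to a rapid light curve."""
    est = RapidLightCurveRegressor(**kwargs).fit(np.asarray(par),
                                                 np.asarray(retr_values))
    return RLCFit(est.retr_max_, est.alpha_, est.rss_, est.converged_)
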