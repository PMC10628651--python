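"""Haldane growth–irradiance model and rotating-reactor productivity.

The Haldane (substrate-inhibition) form describes photosynthetic growth
that rises with irradiance up to an optimum and declines beyond it
(photoinhibition):

    μ_L(I) = μ_max · I / (I + (μ_max/α)·(I/I_opt − 1)²)

with μ_max the gross rate at the optimum I_opt and α the initial slope of
the curve.  Under a square-wave light/dark cycle with duty cycle ε and
constant respiration R, the no-mitigation prediction for the net rate is

    μ(I) = μ_L(I_peak)·ε − R

i.e. gross growth only during the light fraction, respiration throughout.
Growth yield (μ per unit of average light) and footprint productivity of a
rotating-biofilm reactor (P_f = μ·(1/ε)·ρ·h, with ρ the dry biomass
density and h the biofilm thickness) follow directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "HaldaneParams",
    "ReactorSpec",
    "haldane_mu_L",
    "net_growth_intermittent",
    "HaldaneRegressor",
    "fit_haldane",
    "growth_yield",
    "footprint_productivity",
    "productivity_scan",
]


@dataclass(frozen=True)
class HaldaneParams:
    """Haldane growth–irradiance parameters.

    mu_max : maximal gross growth rate at the optimum, d⁻¹.
    alpha : initial slope, d⁻¹ per μmol·m⁻²·s⁻¹.
    i_opt : optimal PPFD, μmol·m⁻²·s⁻¹.
    """

    mu_max: float
    alpha: float
    i_opt: float

    def __post_init__(self) -> None:
        for name in ("mu_max", "alpha", "i_opt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ReactorSpec:
    """Rotating-biofilm reactor geometry and biomass properties.

    epsilon : duty cycle of the rotation (fraction of the cycle a biofilm
        element spends illuminated); the growth-area to footprint ratio is
        S_T/S_f = 1/ε.
    rho : dry-weight volumetric biomass density, g·m⁻³.
    h : biofilm thickness, m.
    """

    epsilon: float
    rho: float = 1.40e5
    h: float = 1.0e-4

    def __post_init__(self) -> None:
        if not (0 < self.epsilon <= 1):
            raise ValueError(f"epsilon must be in (0, 1], got {self.epsilon}")
        if self.rho <= 0 or self.h <= 0:
            raise ValueError("rho and h must be > 0")

    @property
    def area_ratio(self) -> float:
        """Total growth area over footprint, S_T/S_f = 1/ε."""
        return 1.0 / self.epsilon


def haldane_mu_L(I, p: HaldaneParams):
    """Gross light-phase growth rate μ_L(I), d⁻¹.  Vectorised over I."""
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("irradiance must be >= 0")
    denom = I + (p.mu_max / p.alpha) * (I / p.i_opt - 1.0) ** 2
    out = p.mu_max * I / denom
    return out if out.ndim else float(out)


def net_growth_intermittent(i_peak, epsilon: float, p: HaldaneParams, R: float):
    """Net growth rate under a light/dark cycle without inhibition mitigation.

    μ(I) = μ_L(I_peak)·ε − R; ε = 1 recovers the continuous-light curve.
    """
    if not (0 < epsilon <= 1):
        raise ValueError(f"epsilon must be in (0, 1], got {epsilon}")
    return haldane_mu_L(i_peak, p) * epsilon - R


class HaldaneRegressor(RegressorMixin, BaseEstimator):
    """Least-squares Haldane fit to (irradiance, gross growth rate) points.

    Minimises the residual sum of squares with the Nelder–Mead simplex on
    log-parameters (which keeps μ_max, α, I_opt positive without explicit
    bounds).  Initialisation: μ_max₀ = max observed rate, I_opt₀ = light
    level of that maximum, α₀ = slope of the two lowest-light points.

    Attributes (after ``fit``): ``mu_max_``, ``alpha_``, ``i_opt_``,
    ``params_`` (:class:`HaldaneParams`), ``rss_``, ``converged_``,
    ``n_iter_``.
    """

    def __init__(self, xatol: float = 1e-8, fatol: float = 1e-8,
                 maxiter: int = 5000):
        self.xatol = xatol
        self.fatol = fatol
        self.maxiter = maxiter

    def fit(self, X, y):
        I = np.asarray(X, dtype=float)
        if I.ndim == 2 and I.shape[1] == 1:
            I = I.ravel()
        mu = np.asarray(y, dtype=float)
        if I.shape != mu.shape:
            raise ValueError("X and y lengths differ")
        if np.unique(I).size < 3:
            raise ValueError(
                "Haldane fit is unidentifiable with fewer than 3 distinct "
                f"light levels (got {np.unique(I).size})"
            )

        order = np.argsort(I)
        I_s, mu_s = I[order], mu[order]
        mu_max0 = max(float(mu_s.max()), 1e-6)
        i_opt0 = max(float(I_s[np.argmax(mu_s)]), 1e-6)
        pos = I_s > 0
        if pos.sum() >= 2 and I_s[pos][1] > I_s[pos][0]:
            alpha0 = (mu_s[pos][1] - mu_s[pos][0]) / (I_s[pos][1] - I_s[pos][0])
        else:
            alpha0 = mu_max0 / i_opt0
        if not np.isfinite(alpha0) or alpha0 <= 0:
            alpha0 = mu_max0 / i_opt0

        def rss(log_theta):
            p = HaldaneParams(*np.exp(log_theta))
            return float(np.sum((mu - haldane_mu_L(I, p)) ** 2))

        res = minimize(
            rss,
            np.log([mu_max0, alpha0, i_opt0]),
            method="Nelder-Mead",
            options={"xatol": self.xatol, "fatol": self.fatol,
                     "maxiter": self.maxiter, "maxfev": self.maxiter},
        )
        if not res.success:
            warnings.warn(f"Haldane fit did not converge: {res.message}",
                          stacklevel=2)
        self.mu_max_, self.alpha_, self.i_opt_ = (float(v) for v in np.exp(res.x))
        self.params_ = HaldaneParams(self.mu_max_, self.alpha_, self.i_opt_)
        self.rss_ = float(res.fun)
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        return self

    def predict(self, X):
        return haldane_mu_L(np.asarray(X, dtype=float), self.params_)


def fit_haldane(I, mu_L, **kwargs) -> HaldaneRegressor:
    """Fit the Haldane curve to gross light-phase rates; returns the fitted
    :class:`HaldaneRegressor` (parameters in ``.params_``, diagnostics in
    ``.rss_``/``.converged_``)."""
    return HaldaneRegressor(**kwargs).fit(np.asarray(I), np.asarray(mu_L))


def growth_yield(mu: float, i_ave: float) -> float:
    """Growth yield μ/I_ave, d⁻¹·μmol⁻¹·m²·s (net rate per unit light dose)."""
    if i_ave <= 0:
        raise ValueError("average light must be > 0")
    return mu / i_ave


def footprint_productivity(mu: float, spec: ReactorSpec) -> float:
    """Net footprint productivity P_f = μ·(S_T/S_f)·ρ·h, g·m⁻²·d⁻¹.

    A rotating system with duty cycle ε carries 1/ε times more biofilm area
    than its illuminated footprint, so area-specific output is multiplied
    accordingly.
    """
    return mu * spec.area_ratio * spec.rho * spec.h


def productivity_scan(
    p: HaldaneParams,
    R: float,
    i_peaks,
    epsilons,
    rho: float = 1.40e5,
    h: float = 1.0e-4,
    observed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Evaluate the no-mitigation model over an (I_peak, ε) grid.

    Returns a tidy table with μ_L, net μ, I_ave, growth yield and footprint
    productivity per grid point.  If ``observed`` is given (columns
    ``i_peak``, ``epsilon``, ``mu``), measured rows are appended with
    ``source='observed'`` for comparison against the prediction curve.
    """
    i_peaks = np.atleast_1d(np.asarray(i_peaks, dtype=float))
    epsilons = np.atleast_1d(np.asarray(epsilons, dtype=float))
    if i_peaks.size == 0 or epsilons.size == 0:
        raise ValueError("grid must be nonempty")
    rows = []
    for eps in epsilons:
        mu_l = haldane_mu_L(i_peaks, p)
        mu_net = mu_l * eps - R
        i_ave = i_peaks * eps
        with np.errstate(divide="ignore", invalid="ignore"):
            yld = np.where(i_ave > 0, mu_net / i_ave, np.nan)
        pf = mu_net * (1.0 / eps) * rho * h
        rows.append(pd.DataFrame({
            "i_peak": i_peaks, "epsilon": eps, "i_ave": i_ave,
            "mu_L": mu_l, "mu": mu_net, "yield": yld, "P_f": pf,
            "source": "model",
        }))
    table = pd.concat(rows, ignore_index=True)
    if observed is not None:
        obs = observed.copy()
        obs["i_ave"] = obs["i_peak"] * obs["epsilon"]
        obs["mu_L"] = (obs["mu"] + R) / obs["epsilon"]
        obs["yield"] = obs["mu"] / obs["i_ave"]
        obs["P_f"] = obs["mu"] / obs["epsilon"] * rho * h
        obs["source"] = "observed"
        table = pd.concat([table, obs[table.columns]], ignore_index=True)
    return table
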