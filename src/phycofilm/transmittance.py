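"""Biofilm growth estimation from light transmittance.

Light crossing a biofilm of areal biomass density ``X`` (g·m⁻²) follows the
Lambert–Beer law ``I_out = I_in · exp(−k·X)`` with extinction coefficient
``k`` (m²·g⁻¹).  For exponential growth ``X(t) = X0·exp(μ·t)`` the double
logarithm

    ln(ln(I_in / I_out)) = ln(k·X0) + μ·t

is linear in time with slope μ and the unknown ``k`` absorbed into the
intercept — so the net specific growth rate can be read off transmitted
light alone, without calibrating the sensor against biomass.

The estimator scans every contiguous window of at least ``min_points``
daily readings and reports the window of maximum ordinary-least-squares
slope, i.e. the steepest (exponential-phase) portion of the record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TransmittanceSeries",
    "GrowthEstimate",
    "RespirationModel",
    "attenuation",
    "biomass_proxy",
    "GrowthRateEstimator",
    "estimate_growth_rate",
    "gross_light_phase_rate",
]

#: Minimum optical depth ln(I_in/I_out) for a reading to count as real
#: attenuation rather than sensor noise (≈ 5× a 2 % sensor repeatability).
DETECTION_LIMIT = 0.1


@dataclass
class TransmittanceSeries:
    """Timed incident/transmitted PPFD readings for one flow-cell channel.

    ``i_out`` may be 1-D (one sensor position) or 2-D with shape
    (n_times, n_positions); positions are averaged before analysis, matching
    the practice of reading transmitted light at several points along the
    channel.
    """

    times: np.ndarray          # days, monotone increasing
    i_in: np.ndarray           # PPFD per time point
    i_out: np.ndarray          # PPFD, (n,) or (n, n_positions)
    regime_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.i_in = np.asarray(self.i_in, dtype=float)
        self.i_out = np.asarray(self.i_out, dtype=float)
        if self.times.size < 2:
            raise ValueError("need at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.i_in <= 0):
            raise ValueError("incident light must be positive")
        if self.i_out.shape[0] != self.times.size:
            raise ValueError("i_out length does not match times")

    @property
    def i_out_mean(self) -> np.ndarray:
        """Transmitted PPFD averaged over sensor positions."""
        if self.i_out.ndim == 1:
            return self.i_out
        return self.i_out.mean(axis=1)

    @property
    def transmittance(self) -> np.ndarray:
        """Position-averaged I_out / I_in."""
        return self.i_out_mean / self.i_in


@dataclass(frozen=True)
class GrowthEstimate:
    """Result of the maximum-slope window regression."""

    mu: float                  # net specific growth rate, d⁻¹
    window: tuple[int, int]    # (start, end) indices into the series, inclusive
    r_squared: float
    n_points: int
    intercept: float = field(default=np.nan)


@dataclass(frozen=True)
class RespirationModel:
    """Constant respiration rate R (d⁻¹), identical in light and darkness."""

    R: float

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError(f"respiration rate must be >= 0, got {self.R}")


def attenuation(i_in, i_out) -> float:
    """Percent light attenuation (I_in − I_out)/I_in × 100.

    ``i_out`` given per position is averaged first.
    """
    i_in = float(np.asarray(i_in, dtype=float))
    if i_in <= 0:
        raise ValueError("incident light must be positive")
    i_out_mean = float(np.mean(np.asarray(i_out, dtype=float)))
    if i_out_mean < 0:
        raise ValueError("transmitted light must be >= 0")
    return (i_in - i_out_mean) / i_in * 100.0


def biomass_proxy(
    series: TransmittanceSeries, detection_limit: float = DETECTION_LIMIT
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Double-log biomass proxy ln(ln(I_in/I_out)) per usable time point.

    Returns ``(times, proxy, used)`` where ``used`` is the boolean mask of
    points with optical depth above ``detection_limit``.  Degenerate points
    (no measurable attenuation, or I_out ≥ I_in) are excluded with a
    warning rather than clamped — clamping would bias the slope.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        optical_depth = np.log(series.i_in / series.i_out_mean)
    used = np.isfinite(optical_depth) & (optical_depth >= detection_limit)
    n_dropped = int((~used).sum())
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} point(s) with attenuation at or below the "
            f"detection limit (optical depth < {detection_limit})",
            stacklevel=2,
        )
    proxy = np.log(optical_depth[used])
    return series.times[used], proxy, used


class GrowthRateEstimator(RegressorMixin, BaseEstimator):
    """Maximum-slope window estimator of the net specific growth rate.

    ``fit(X, y)`` takes times in days (``X``, shape (n,) or (n, 1)) and the
    position-averaged transmittance fraction I_out/I_in (``y``).  Every
    contiguous window of at least ``min_points`` usable points is scanned
    with ordinary least squares on the double-log proxy; the fitted slope of
    the steepest window is the growth rate.  Ties on slope prefer the
    larger window, then the earlier start.

    Attributes
    ----------
    mu_ : float
        Net specific growth rate, d⁻¹ (slope of the best window).
    intercept_ : float
        Proxy intercept of the best window.
    window_ : tuple of int
        Inclusive (start, end) indices of the best window in the input.
    r_squared_ : float
    n_points_ : int
        Points in the best window.
    used_mask_ : ndarray of bool
        Which input points survived the degenerate-point exclusion.
    """

    def __init__(self, min_points: int = 4, detection_limit: float = DETECTION_LIMIT):
        self.min_points = min_points
        self.detection_limit = detection_limit

    def fit(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t.ravel()
        if t.ndim != 1:
            raise ValueError("X must be 1-D times or a single column")
        ratio = np.asarray(y, dtype=float)
        if ratio.shape != t.shape:
            raise ValueError("X and y lengths differ")

        with np.errstate(divide="ignore", invalid="ignore"):
            optical_depth = -np.log(ratio)
        used = (
            np.isfinite(optical_depth)
            & (ratio > 0)
            & (optical_depth >= self.detection_limit)
        )
        n_dropped = int((~used).sum())
        if n_dropped:
            warnings.warn(
                f"excluded {n_dropped} degenerate/below-detection point(s)",
                stacklevel=2,
            )
        tu = t[used]
        proxy = np.log(optical_depth[used])
        m = tu.size
        if m < self.min_points:
            raise ValueError(
                f"insufficient points: {m} usable, {self.min_points} required"
            )

        orig_idx = np.flatnonzero(used)
        best_key = None
        best = None
        for i in range(m):
            for j in range(i + self.min_points, m + 1):
                res = stats.linregress(tu[i:j], proxy[i:j])
                key = (res.slope, j - i, -i)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (i, j, res)
        i, j, res = best
        self.mu_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.n_points_ = j - i
        self.window_ = (int(orig_idx[i]), int(orig_idx[j - 1]))
        self.used_mask_ = used
        return self

    def predict(self, X):
        """Predicted double-log proxy at the given times."""
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t.ravel()
        return self.intercept_ + self.mu_ * t


def estimate_growth_rate(
    series: TransmittanceSeries,
    min_points: int = 4,
    detection_limit: float = DETECTION_LIMIT,
    per_position: bool = False,
):
    """Net specific growth rate from a transmittance series.

    With ``per_position=True`` returns a list of one :class:`GrowthEstimate`
    per sensor position (for dispersion estimates); otherwise positions are
    averaged first and a single estimate is returned.
    """
    if per_position and series.i_out.ndim == 2:
        out = []
        for p in range(series.i_out.shape[1]):
            est = GrowthRateEstimator(min_points, detection_limit).fit(
                series.times, series.i_out[:, p] / series.i_in
            )
            out.append(
                GrowthEstimate(est.mu_, est.window_, est.r_squared_,
                               est.n_points_, est.intercept_)
            )
        return out
    est = GrowthRateEstimator(min_points, detection_limit).fit(
        series.times, series.transmittance
    )
    return GrowthEstimate(est.mu_, est.window_, est.r_squared_,
                          est.n_points_, est.intercept_)


def gross_light_phase_rate(mu: float, R: float, epsilon: float) -> float:
    """Gross growth rate during light phases, μ_L = (μ + R)/ε (d⁻¹).

    Inverts the intermittent-light balance μ = μ_L·ε − R: the measured net
    rate is gross photosynthetic growth during the light fraction ε of the
    cycle minus round-the-clock respiration R.
    """
    if epsilon <= 0 or epsilon > 1:
        raise ValueError(f"duty cycle must be in (0, 1], got {epsilon}")
    if R < 0:
        raise ValueError("respiration rate must be >= 0")
    return (mu + R) / epsilon
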