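"""Light/dark illumination programs and flow-cell hydraulics.

A light regime is a square-wave alternation of a light phase (duration
``t_light`` at intensity ``i_peak``, in μmol photons m⁻² s⁻¹ PPFD) and a
dark phase (``t_dark``).  Continuous light is the degenerate case
``t_dark = 0``.  Two derived quantities govern everything downstream:

* the duty cycle (light fraction) ``ε = t_light / (t_light + t_dark)``,
* the time-averaged PPFD ``I_ave = i_peak · ε`` — the light dose a cell
  receives per cycle.

The flow cell is a rectangular millifluidic duct; its hydraulic numbers
(mean velocity, Reynolds number, wall shear) characterise the laminar,
low-shear environment the biofilm grows in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LightRegime",
    "FlowCell",
    "average_ppfd",
    "waveform",
    "mean_velocity",
    "reynolds",
    "wall_shear",
    "study_regimes",
]


@dataclass(frozen=True)
class LightRegime:
    """Square-wave illumination program.

    Parameters
    ----------
    label : str
        Human-readable name, e.g. ``"300-5s-0-10s"`` (300 μmol·m⁻²·s⁻¹ for
        5 s, darkness for 10 s).
    i_peak : float
        Peak PPFD during the light phase, μmol·m⁻²·s⁻¹.
    t_light : float
        Light-phase duration, seconds (> 0).
    t_dark : float
        Dark-phase duration, seconds (≥ 0; 0 means continuous light).
    """

    label: str
    i_peak: float
    t_light: float
    t_dark: float = 0.0

    def __post_init__(self) -> None:
        if self.i_peak < 0:
            raise ValueError(f"i_peak must be >= 0, got {self.i_peak}")
        if self.t_light <= 0:
            raise ValueError(f"t_light must be > 0, got {self.t_light}")
        if self.t_dark < 0:
            raise ValueError(f"t_dark must be >= 0, got {self.t_dark}")

    @property
    def period(self) -> float:
        """Cycle time T = t_light + t_dark, seconds."""
        return self.t_light + self.t_dark

    @property
    def epsilon(self) -> float:
        """Duty cycle (light fraction) ε ∈ (0, 1]."""
        return self.t_light / self.period

    @property
    def i_ave(self) -> float:
        """Time-averaged PPFD over one cycle, μmol·m⁻²·s⁻¹."""
        return self.i_peak * self.epsilon

    @property
    def is_continuous(self) -> bool:
        return self.t_dark == 0.0


def average_ppfd(regime: LightRegime) -> float:
    """Time-averaged PPFD of a regime, ``i_peak · t_light / (t_light + t_dark)``."""
    return regime.i_ave


def waveform(regime: LightRegime, t):
    """Instantaneous PPFD at time(s) ``t`` (seconds, ≥ 0).

    The cycle starts with the light phase at t = 0 and is periodic with
    period ``regime.period``.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    phase = np.mod(t, regime.period)
    out = np.where(phase < regime.t_light, regime.i_peak, 0.0)
    return out if out.ndim else float(out)


def study_regimes() -> tuple[LightRegime, ...]:
    """The five illumination profiles of the reference flow-cell study.

    One continuous control at ~100 μmol·m⁻²·s⁻¹ and four intermittent
    regimes sharing the same ~100 μmol·m⁻²·s⁻¹ average: three at peak 310
    with ε = 1/3 (cycle times 15 s, 90 s, 3 min) and one at peak 496 with
    ε = 1/5 (cycle time 25 s).
    """
    return (
        LightRegime("100 cont", 106.0, 1.0, 0.0),
        LightRegime("300-5s-0-10s", 310.0, 5.0, 10.0),
        LightRegime("300-30s-0-60s", 310.0, 30.0, 60.0),
        LightRegime("300-1min-0-2min", 310.0, 60.0, 120.0),
        LightRegime("500-5s-0-20s", 496.0, 5.0, 20.0),
    )


@dataclass(frozen=True)
class FlowCell:
    """Rectangular flow-cell channel with laminar medium flow.

    Dimensions in mm; ``flow_rate`` in mL·min⁻¹; fluid defaults are water
    near room temperature (ρ = 1000 kg·m⁻³, μ = 1.0 mPa·s).
    """

    length: float = 40.0
    width: float = 6.0
    height: float = 3.0
    flow_rate: float = 0.1
    fluid_density: float = 1000.0      # kg·m⁻³
    fluid_viscosity: float = 1.0       # mPa·s

    def __post_init__(self) -> None:
        for name in ("length", "width", "height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.flow_rate < 0:
            raise ValueError("flow_rate must be >= 0")
        if self.fluid_viscosity <= 0:
            raise ValueError("fluid_viscosity must be > 0")

    @property
    def cross_section_mm2(self) -> float:
        """Cross-sectional area width × height, mm²."""
        return self.width * self.height

    @property
    def hydraulic_diameter_mm(self) -> float:
        """D_h = 4·A / P for the rectangular duct, mm."""
        return 4.0 * self.cross_section_mm2 / (2.0 * (self.width + self.height))

    @property
    def substratum_area_cm2(self) -> float:
        """Channel floor area length × width, cm²."""
        return self.length * self.width / 100.0


def mean_velocity(fc: FlowCell) -> float:
    """Mean flow velocity in the channel, mm·s⁻¹ (volumetric flow / area)."""
    if fc.cross_section_mm2 <= 0:
        raise ValueError("zero cross-section area")
    q_mm3_s = fc.flow_rate * 1000.0 / 60.0  # mL·min⁻¹ → mm³·s⁻¹
    return q_mm3_s / fc.cross_section_mm2


def reynolds(fc: FlowCell) -> float:
    """Reynolds number ρ·v·D_h/μ (dimensionless) with D_h = 4A/P."""
    v = mean_velocity(fc) * 1e-3              # m·s⁻¹
    d_h = fc.hydraulic_diameter_mm * 1e-3     # m
    mu = fc.fluid_viscosity * 1e-3            # Pa·s
    return fc.fluid_density * v * d_h / mu


def wall_shear(fc: FlowCell) -> float:
    """Wall shear stress of laminar flow between parallel plates, mPa.

    Uses the parallel-plate approximation τ = 6·μ·Q/(w·h²), appropriate for
    a wide shallow duct.  Reported as an approximation: side-wall effects in
    a 2:1 duct are ignored.
    """
    q = fc.flow_rate * 1e-6 / 60.0            # m³·s⁻¹
    mu = fc.fluid_viscosity * 1e-3            # Pa·s
    w = fc.width * 1e-3
    h = fc.height * 1e-3
    tau_pa = 6.0 * mu * q / (w * h * h)
    return tau_pa * 1000.0
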