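"""Synthetic data with the statistical structure the analysis assumes.

Every generator is a deterministic function of (configuration, seed) and
has a zero-noise mode in which its analysis counterpart recovers the
generating parameters exactly — the closure property the test suite leans
on.  The default :class:`ScenarioConfig` mirrors the reference flow-cell
experiment: the five-regime illumination set (one continuous control and
four intermittent regimes averaging ~100 μmol·m⁻²·s⁻¹), 15 days of daily
transmittance readings at three sensor positions, seven-step rapid light
curves, and confocal-sized voxel stacks.

Noise models (conventional, since none is prescribed by the emulated
protocols): multiplicative lognormal on light sensors, additive Gaussian
truncated to (0, 1) on fluorescence yields, integer-slice jitter on stack
column heights.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .growth_model import HaldaneParams, haldane_mu_L, net_growth_intermittent
from .morphometrics import CellMaskImage
from .photosynthesis import PAMTrace, rectangular_hyperbola
from .regimes import LightRegime, study_regimes
from .structure3d import BiofilmStack
from .transmittance import TransmittanceSeries

__all__ = [
    "ScenarioConfig",
    "net_rate",
    "gen_growth_trajectory",
    "gen_transmittance",
    "gen_pam_trace",
    "gen_stack",
    "gen_cell_image",
]


@dataclass
class ScenarioConfig:
    """Ground truth and noise levels for one simulated experiment.

    The optical defaults (k = 1.0 m²·g⁻¹, X0 = 0.1 g·m⁻²) give ~10 %
    initial attenuation and near-opaque mature biofilms, consistent with
    confocal-scale biovolumes at a dry density of 1.4·10⁵ g·m⁻³.

    ``integration_time_s`` switches on partial light integration: the net
    rate blends the full-integration limit (growth follows the average
    light) and the no-integration limit (instantaneous light) with weight
    λ = exp(−T/τ_I) on the former.  ``None`` (default) keeps the pure
    no-mitigation forward model μ = μ_L(I_peak)·ε − R.
    """

    regimes: tuple[LightRegime, ...] = field(default_factory=study_regimes)
    haldane: HaldaneParams = field(
        default_factory=lambda: HaldaneParams(mu_max=1.0, alpha=0.02, i_opt=150.0))
    respiration: float = 0.05          # d⁻¹ (placeholder value)
    extinction_k: float = 1.0          # m²·g⁻¹
    x0: float = 0.1                    # g·m⁻²
    duration_d: int = 15
    n_positions: int = 3
    sigma_transmittance: float = 0.02  # lognormal σ on I_out
    sigma_yield: float = 0.01          # Gaussian σ on ΔF/Fm′
    stack_jitter: int = 1              # ± slices on layered column heights
    integration_time_s: float | None = None
    seed: int = 0

    def rng(self, *keys: str) -> np.random.Generator:
        """Deterministic per-purpose generator derived from the seed."""
        return np.random.default_rng(
            [self.seed % 2**31] + [zlib.crc32(k.encode()) for k in keys])


def net_rate(cfg: ScenarioConfig, regime: LightRegime) -> float:
    """Ground-truth net growth rate for a regime (d⁻¹).

    Without ``integration_time_s`` this is the no-mitigation balance
    μ_L(I_peak)·ε − R; with it, a λ-weighted blend with the
    full-integration limit μ_L(I_ave) − R, λ = exp(−T/τ_I) (continuous
    light always uses the plain curve).
    """
    p, R = cfg.haldane, cfg.respiration
    mu_none = net_growth_intermittent(regime.i_peak, regime.epsilon, p, R)
    if cfg.integration_time_s is None or regime.is_continuous:
        return float(mu_none)
    lam = float(np.exp(-regime.period / cfg.integration_time_s))
    mu_full = haldane_mu_L(regime.i_ave, p) - R
    return lam * mu_full + (1.0 - lam) * mu_none


def gen_growth_trajectory(
    cfg: ScenarioConfig, regime: LightRegime, duration_d: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Daily areal biomass X(t) = X0·exp(μ·t), g·m⁻² (noise-free)."""
    d = cfg.duration_d if duration_d is None else duration_d
    if d < 2:
        raise ValueError("duration must be >= 2 days")
    times = np.arange(d, dtype=float)
    mu = net_rate(cfg, regime)
    return times, cfg.x0 * np.exp(mu * times)


def gen_transmittance(
    cfg: ScenarioConfig,
    regime: LightRegime,
    trajectory: tuple[np.ndarray, np.ndarray] | None = None,
    sigma: float | None = None,
) -> TransmittanceSeries:
    """Beer–Lambert transmitted light for a growth trajectory.

    I_out = I_in·exp(−k·X(t)) with independent multiplicative lognormal
    noise per sensor position; incident light is the regime's peak (the
    sensor reads during a light phase).  Same config + seed → identical
    series.
    """
    times, X = trajectory if trajectory is not None else gen_growth_trajectory(cfg, regime)
    sig = cfg.sigma_transmittance if sigma is None else sigma
    i_in = np.full(times.size, regime.i_peak)
    i_out_true = i_in[:, None] * np.exp(-cfg.extinction_k * X[:, None])
    if sig > 0:
        rng = cfg.rng("transmittance", regime.label)
        noise = np.exp(rng.normal(0.0, sig, size=(times.size, cfg.n_positions)))
    else:
        noise = np.ones((times.size, cfg.n_positions))
    return TransmittanceSeries(times, i_in, i_out_true * noise, regime.label)


PAM_PAR_LEVELS = np.linspace(0.0, 1000.0, 7)  # seven-step actinic protocol


def gen_pam_trace(
    cfg: ScenarioConfig,
    retr_max: float = 60.0,
    alpha: float = 0.3,
    fv_fm: float | None = None,
    fm: float = 1000.0,
    sigma: float | None = None,
    label: str = "",
) -> PAMTrace:
    """Seven-step rapid-light-curve trace with hyperbola-implied yields.

    Effective yields are back-computed so that rETR(PAR) follows the
    rectangular hyperbola exactly at zero noise; Fm′ declines smoothly
    with PAR (quenching-like), F follows from the yield.  A healthy
    Fv/Fm is drawn in 0.7–0.8 when not specified.
    """
    if retr_max <= 0 or alpha <= 0:
        raise ValueError("retr_max and alpha must be > 0")
    rng = cfg.rng("pam", label)
    if fv_fm is None:
        fv_fm = float(rng.uniform(0.7, 0.8))
    sig = cfg.sigma_yield if sigma is None else sigma
    par = PAM_PAR_LEVELS.copy()
    target = rectangular_hyperbola(par, retr_max, alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        yields = np.where(par > 0, target / (0.5 * par), fv_fm)
    if sig > 0:
        yields = yields + rng.normal(0.0, sig, size=par.size)
    yields = np.clip(yields, 1e-6, 0.999)
    fm_prime = fm * np.exp(-par / 2000.0)  # gentle light-adapted quenching
    F = fm_prime * (1.0 - yields)
    f0 = (1.0 - fv_fm) * fm
    return PAMTrace(F0=f0, Fm=fm, steps=np.column_stack([par, F, fm_prime]))


def gen_stack(
    cfg: ScenarioConfig,
    mode: str,
    target_biovolume: float,
    shape: tuple[int, int, int] = (40, 96, 96),
    n_colonies: int = 5,
    voxel_xy: float = 1.25,
    voxel_z: float = 3.94,
    label: str = "",
) -> BiofilmStack:
    """Binary biofilm stack of a given biovolume (μm³·μm⁻²).

    ``mode='layered'``: uniform slab with jittered column heights —
    conformal growth.  ``mode='clustered'``: hemispherical colonies at
    seeded positions, radius solved so the stack hits the biovolume
    target — colony growth.  Same config + seed → identical stack.
    """
    if mode not in ("layered", "clustered"):
        raise ValueError(f"mode must be 'layered' or 'clustered', got {mode!r}")
    if target_biovolume < 0:
        raise ValueError("target_biovolume must be >= 0")
    nz, ny, nx = shape
    rng = cfg.rng("stack", mode, label)
    if mode == "layered":
        base = target_biovolume / voxel_z  # slices; slab biovolume == thickness
        heights = np.full((ny, nx), base)
        if cfg.stack_jitter > 0:
            heights = heights + rng.integers(
                -cfg.stack_jitter, cfg.stack_jitter + 1, size=(ny, nx))
        heights = np.clip(np.round(heights), 0, nz).astype(int)
        grid = np.arange(nz)[:, None, None] < heights[None, :, :]
        return BiofilmStack(grid, voxel_xy, voxel_z)

    # clustered: union of hemispheres, bisect on radius for the target
    centers = rng.uniform([0.15 * ny, 0.15 * nx], [0.85 * ny, 0.85 * nx],
                          size=(n_colonies, 2))
    zc = (np.arange(nz)[:, None, None] + 0.5) * voxel_z
    yy = (np.arange(ny)[None, :, None] + 0.5) * voxel_xy
    xx = (np.arange(nx)[None, None, :] + 0.5) * voxel_xy
    voxel_vol = voxel_xy**2 * voxel_z
    area = ny * nx * voxel_xy**2
    target_voxels = target_biovolume * area / voxel_vol

    def grid_at(r: float) -> np.ndarray:
        g = np.zeros((nz, ny, nx), dtype=bool)
        for cy, cx in centers:
            d2 = (yy - cy * voxel_xy) ** 2 + (xx - cx * voxel_xy) ** 2 + zc**2
            g |= d2 < r * r
        return g

    lo, hi = 0.0, max(ny, nx) * voxel_xy + nz * voxel_z
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if grid_at(mid).sum() < target_voxels:
            lo = mid
        else:
            hi = mid
    return BiofilmStack(grid_at(hi), voxel_xy, voxel_z)


def gen_cell_image(
    cfg: ScenarioConfig,
    n_cells: int = 50,
    radius_mean: float = 2.5,
    radius_sd: float = 0.5,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.32,
    label: str = "",
) -> tuple[CellMaskImage, np.ndarray]:
    """Non-overlapping rasterised disks emulating a binary micrograph mask.

    Returns the mask and the ground-truth record array (y, x, radius in
    μm); if placement becomes infeasible, fewer cells are drawn with a
    warning.
    """
    import warnings

    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = cfg.rng("cells", label)
    ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < n_cells and attempts < 200 * max(n_cells, 1):
        attempts += 1
        r_um = max(float(rng.normal(radius_mean, radius_sd)), 0.5)
        r_px = r_um / pixel_size
        cy = rng.uniform(r_px, ny - r_px)
        cx = rng.uniform(r_px, nx - r_px)
        if any((cy - py) ** 2 + (cx - px) ** 2 < (r_px + pr / pixel_size + 1) ** 2
               for py, px, pr in placed):
            continue
        yy, xx = np.ogrid[:ny, :nx]
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        placed.append((cy, cx, r_um))
    if len(placed) < n_cells:
        warnings.warn(
            f"placed only {len(placed)} of {n_cells} cells (packing limit)",
            stacklevel=2)
    truth = np.array(placed, dtype=float).reshape(-1, 3)
    return CellMaskImage(mask, pixel_size), truth
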