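"""File formats: transmittance/PAM CSV, binary TIFF masks and stacks, config.

Transmittance CSV columns: ``time_d, I_in, I_out_pos1..I_out_posN``.
PAM CSV: two header rows ``F0,<value>`` and ``Fm,<value>`` followed by a
step table with columns ``PAR,F,Fm_prime``.  Stacks are multi-page TIFFs
(one page per z-slice, nonzero = biomass) with voxel dimensions supplied
separately.  Configs are YAML with sections regimes/model/reactor/synth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .growth_model import HaldaneParams
from .morphometrics import CellMaskImage
from .photosynthesis import PAMTrace
from .regimes import LightRegime
from .structure3d import BiofilmStack
from .transmittance import TransmittanceSeries

__all__ = [
    "read_transmittance_csv", "write_transmittance_csv",
    "read_pam_csv", "write_pam_csv",
    "read_stack_tiff", "write_stack_tiff",
    "read_mask_tiff", "write_mask_tiff",
    "load_config", "regimes_from_config",
]


def write_transmittance_csv(series: TransmittanceSeries, path) -> None:
    i_out = series.i_out if series.i_out.ndim == 2 else series.i_out[:, None]
    cols = {"time_d": series.times, "I_in": series.i_in}
    for p in range(i_out.shape[1]):
        cols[f"I_out_pos{p + 1}"] = i_out[:, p]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_transmittance_csv(path, regime_label: str = "") -> TransmittanceSeries:
    df = pd.read_csv(path)
    out_cols = [c for c in df.columns if c.startswith("I_out")]
    if not out_cols:
        raise ValueError(f"{path}: no I_out columns found")
    i_out = df[out_cols].to_numpy()
    if i_out.shape[1] == 1:
        i_out = i_out[:, 0]
    return TransmittanceSeries(df["time_d"].to_numpy(), df["I_in"].to_numpy(),
                               i_out, regime_label)


def write_pam_csv(trace: PAMTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"F0,{trace.F0}\nFm,{trace.Fm}\nPAR,F,Fm_prime\n")
        for par, F, fmp in trace.steps:
            fh.write(f"{par},{F},{fmp}\n")


def read_pam_csv(path) -> PAMTrace:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    header = dict(ln.split(",", 1) for ln in lines[:2])
    try:
        f0, fm = float(header["F0"]), float(header["Fm"])
    except KeyError as e:
        raise ValueError(f"{path}: missing {e} header row") from None
    steps = np.array([[float(v) for v in ln.split(",")] for ln in lines[3:]])
    return PAMTrace(F0=f0, Fm=fm, steps=steps)


def write_stack_tiff(stack: BiofilmStack, path) -> None:
    tifffile.imwrite(path, stack.grid.astype(np.uint8) * 255)


def read_stack_tiff(path, voxel_xy: float = 1.25, voxel_z: float = 3.94) -> BiofilmStack:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return BiofilmStack(data > 0, voxel_xy, voxel_z)


def write_mask_tiff(img: CellMaskImage, path) -> None:
    tifffile.imwrite(path, img.mask.astype(np.uint8) * 255)


def read_mask_tiff(path, pixel_size: float) -> CellMaskImage:
    return CellMaskImage(tifffile.imread(path) > 0, pixel_size)


def load_config(path) -> dict:
    """Parse a YAML run config; returns the raw nested dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def regimes_from_config(cfg: dict) -> tuple[LightRegime, ...]:
    """Build regimes from config entries {label, peak, light_s, dark_s}."""
    return tuple(
        LightRegime(r["label"], float(r["peak"]), float(r["light_s"]),
                    float(r.get("dark_s", 0.0)))
        for r in cfg.get("regimes", [])
    )


def haldane_from_config(cfg: dict) -> HaldaneParams:
    m = cfg["model"]
    return HaldaneParams(float(m["mu_max"]), float(m["alpha"]), float(m["i_opt"]))


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
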