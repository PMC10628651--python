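# phycofilm

Analysis toolkit for **microalgal biofilms grown under light/dark cycles**:
from raw flow-cell measurements (light transmittance, PAM fluorometry,
micrographs, confocal stacks) to growth rates, photoinhibition modelling and
rotating-reactor productivity predictions.

Phototrophic biofilms in partially submerged rotating reactors see square-wave
light: a peak intensity `I_peak` for a fraction `ε` (duty cycle) of each cycle
of period `T`, giving an average dose `I_ave = I_peak·ε`. Diluting light in
time this way can *mitigate photoinhibition* — cells under short cycles grow
faster than the continuous-light growth–irradiance curve predicts at the same
peak. This package implements the quantitative chain needed to measure and
model that effect in a millifluidic flow-cell experiment.

## What it computes

* **Growth from transmitted light.** Light through a biofilm obeys
  Beer–Lambert, `I_out = I_in·e^(−kX)`; for exponential growth the double
  logarithm `ln(ln(I_in/I_out)) = ln(kX₀) + μ·t` is linear with slope μ, so
  the net specific growth rate is the maximum OLS slope over windows of ≥ 4
  daily readings — no biomass calibration needed
  (`GrowthRateEstimator`, `estimate_growth_rate`).
* **Haldane growth–irradiance model** with photoinhibition,
  `μ_L(I) = μ_max·I / (I + (μ_max/α)·(I/I_opt − 1)²)`, its intermittent-light
  balance `μ = μ_L(I_peak)·ε − R`, Nelder–Mead least-squares fitting,
  growth yield `μ/I_ave` and rotating-reactor footprint productivity
  `P_f = μ·(1/ε)·ρ·h` (`HaldaneRegressor`, `productivity_scan`).
* **PAM fluorometry**: `Fv/Fm`, effective yields, `rETR = ΔF/Fm′·PAR·0.5`,
  and rectangular-hyperbola rapid-light-curve fits giving
  (`rETR_max`, `α`, `E_k`) (`RapidLightCurveRegressor`, `fit_rlc`).
* **Structure and morphometry**: COMSTAT-style biovolume, thickness and
  roughness on binary confocal stacks, the clustered-vs-conformal growth
  slope diagnostic, particle areas and sphere-equivalent cell volumes,
  chlorophyll-a from DMSO-extract absorbances
  (`structure3d`, `morphometrics`).
* **Synthetic experiment generator** reproducing the statistical structure of
  all of the above, used for testing and the demo pipeline (`synthetic`).

## Worked example

```python
import numpy as np
import phycofilm as pf

# a 1/3-duty-cycle regime, 310 peak → 103 μmol·m⁻²·s⁻¹ average
regime = pf.LightRegime("300-5s-0-10s", i_peak=310, t_light=5, t_dark=10)
print(round(regime.i_ave, 2), round(regime.epsilon, 3))   # 103.33 0.333

# growth rate from a synthetic transmittance record
cfg = pf.ScenarioConfig(seed=1)
series = pf.gen_transmittance(cfg, regime)
est = pf.estimate_growth_rate(series)
print(round(est.mu, 3))                                    # 0.249  (d⁻¹)

# gross light-phase rate and the Haldane curve
mu_L = pf.gross_light_phase_rate(est.mu, R=0.05, epsilon=regime.epsilon)
print(round(mu_L, 3))                                      # 0.897  (d⁻¹)
p = pf.HaldaneParams(mu_max=1.0, alpha=0.02, i_opt=150)
print(round(pf.haldane_mu_L(310, p), 3))                   # 0.845  (d⁻¹)

# footprint productivity of a rotating reactor at ε = 1/3
spec = pf.ReactorSpec(epsilon=1/3, rho=1.4e5, h=1e-4)
print(round(pf.footprint_productivity(0.5, spec), 1))      # 21.0 g·m⁻²·d⁻¹
```

The estimated `μ = 0.249 d⁻¹` sits within sensor noise of the scenario's
ground truth (`μ_L(310)·ε − R = 0.845/3 − 0.05 = 0.232 d⁻¹`), and the reactor at ε = 1/3 triples the
per-footprint biomass relative to a fully illuminated surface.

The full demo pipeline (growth estimates for five regimes, Haldane fit,
mitigation comparison, productivity scan, structure metrics) runs from the
shell:

```bash
phycofilm run-all --outdir demo_out --seed 1
phycofilm regimes describe
```

`demo_out/mitigation_comparison.csv` then shows gross light-phase rates for
the 15-s cycle more than twofold above the continuous-light curve at the same
peak — the photoinhibition-mitigation signature the demo scenario is built
around.

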