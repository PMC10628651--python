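# Methods

## Light regimes and hydraulics

An illumination program is a square wave: PPFD `I_peak` for `t_light`
seconds, darkness for `t_dark`, repeating with period `T = t_light + t_dark`;
the cycle starts with the light phase at t = 0. The duty cycle is
`ε = t_light/T` and the average dose `I_ave = I_peak·ε`; these identities are
exact and tested against a quadrature oracle on the waveform. The packaged
study set is one continuous control (106 μmol·m⁻²·s⁻¹) plus three ε = 1/3
regimes at peak 310 (cycle times 15 s, 90 s, 3 min) and one ε = 1/5 regime at
peak 496, all averaging ≈100 μmol·m⁻²·s⁻¹, so regimes differ in *how* light
is delivered, not how much.

Flow-cell hydraulics use water properties (ρ = 1000 kg·m⁻³, μ = 1.0 mPa·s,
overridable) and the hydraulic diameter `D_h = 4A/P` of the rectangular duct;
for the default 40 × 6 × 3 mm channel at 0.1 mL·min⁻¹ this gives
v = 0.093 mm·s⁻¹ and Re = 0.37 — creeping laminar flow. Wall shear uses the
parallel-plate law τ = 6μQ/(w·h²) = 0.185 mPa for that geometry. Shear values
several-fold larger are sometimes quoted for comparable cells from
entrance-region or lubrication corrections; we report the standard
parallel-plate value and label it as such in the docstring.

## Growth from transmitted light

Under Beer–Lambert attenuation `I_out = I_in·e^(−kX)` and exponential growth,
`ln(ln(I_in/I_out))` is affine in time with slope equal to the net specific
growth rate μ, for *any* extinction coefficient k — k only shifts the
intercept. The estimator:

* averages sensor positions on `I_out` before transforming (the measurement
  protocol records transmitted light at three positions; per-position
  estimation is available for dispersion),
* excludes points whose optical depth `ln(I_in/I_out)` is below a detection
  limit (default 0.1, ≈5× the 2 % repeatability typical of quantum sensors):
  near-zero attenuation readings carry noise through two logarithms and would
  otherwise dominate the regression. Points with `I_out ≥ I_in` are likewise
  excluded (never clamped — clamping biases the slope). Every exclusion is
  warned about, keeping the analysis auditable.
* scans **every** contiguous window of ≥ 4 usable points and returns the
  window with the maximum OLS slope (ties: larger window, then earlier
  start — a deterministic choice). This is the literal "maximum slope over at
  least four points" rule; it targets the exponential phase but, like any
  max-statistic, has a mild upward bias under noise. Under the packaged
  conditions (2 % multiplicative sensor noise, 15 daily points, 3 positions)
  the median recovery error is ≈2 %, comfortably within the 10 % the test
  suite requires.

The net rate μ combines gross photosynthesis during light phases with
round-the-clock respiration R (assumed constant), so the gross light-phase
rate is `μ_L = (μ + R)/ε` — the algebraic inverse of the intermittent-light
balance below.

## Haldane model, fitting, and reactor predictions

Gross growth versus irradiance follows the Haldane form

    μ_L(I) = μ_max·I / (I + (μ_max/α)·(I/I_opt − 1)²)

which is zero at I = 0 with initial slope α (d⁻¹ per μmol·m⁻²·s⁻¹), peaks at
exactly μ_max at I_opt, and declines beyond it (photoinhibition). α is stored
in rate-per-PPFD units so that the low-light limit μ_L ≈ α·I is dimensionally
consistent. Without mitigation, a cycle with duty ε gives net growth
`μ = μ_L(I_peak)·ε − R`; ε = 1 recovers the continuous curve.

Fitting minimises the residual sum of squares with the Nelder–Mead simplex —
the standard derivative-free choice for this 3-parameter curve — on
*log-parameters*, which enforces positivity without constraints.
Initialisation: μ_max₀ = max observed rate, I_opt₀ = its light level,
α₀ = slope of the two lowest-light points; tolerances 1e-8 on parameters and
objective, ≤ 5000 iterations; non-convergence raises a warning and is
recorded on the estimator, never silent. Noiseless 6-level data are recovered
to < 1e-3 relative; the fit is invariant to point order and transforms
correctly under light-unit rescaling.

Reactor predictions: growth yield `μ/I_ave` (net growth per unit light dose)
and footprint productivity `P_f = μ·(1/ε)·ρ·h`, where a rotating reactor with
duty cycle ε carries `S_T/S_f = 1/ε` times more biofilm area than its
illuminated footprint. Defaults ρ = 1.4·10⁵ g·m⁻³ (dry-weight volumetric
density of packed Chlorella biofilm) and h = 1·10⁻⁴ m are config values, not
constants: h should be set to the largest maximum thickness observed in the
data being analysed, and the default R = 0.05 d⁻¹ is a placeholder of the
right order for Chlorella respiration, to be replaced by a measured value.

## PAM fluorometry

`Fv/Fm = (Fm − F0)/Fm` after dark adaptation (healthy green microalgae:
0.7–0.8); `ΔF/Fm′ = (Fm′ − F)/Fm′` per actinic step;
`rETR = ΔF/Fm′·PAR·0.5` (two photons per transported electron). The rapid
light curve is fitted with the two-parameter saturating exponential
`rETR_max·(1 − e^(−α·PAR/rETR_max))`; no photoinhibition (β) term is
included because the summary statistics of interest are rETR_max, α and
`E_k = rETR_max/α` only, and a β-term is unidentifiable from 7-step curves.
The PAR = 0 step contributes rETR = 0 and anchors the fit by default;
`include_zero_par=False` reproduces instruments that drop it. Same simplex
settings as the Haldane fit.

## Morphometry and 3-D structure

Particle areas use 8-connected component labelling on binary masks (the
default of common particle-analysis tools); touching cells merge — a
documented limitation, no watershed splitting is attempted, and
border-touching particles are retained. Cell volume assumes sphericity:
`V = (4/3)·A·√(A/π)`, the sphere whose cross-section is the measured area.
Chlorophyll-a of a DMSO extract is `12.19·A₆₆₅ − 3.45·A₆₄₉` μg·mL⁻¹, then
normalised per cell (pg) and per cell volume (fg·μm⁻³). Thresholding raw
micrographs is out of scope: binary masks are the input boundary, because
operator-set thresholds are not reproducible.

Stack metrics (COMSTAT conventions): biovolume is occupied voxel volume per
substratum area; column thickness runs from the substratum to the highest
occupied voxel, bridging internal voids (so biovolume = mean thickness only
for solid-from-substratum morphologies — the generator produces both to
exercise the distinction); the roughness coefficient is
`Ra* = (1/N)·Σ|L_i − L̄|/L̄` over all columns, empty columns included at
L = 0 (an `occupied_only` variant is provided since conventions differ).
Ra* is scale-invariant, 0 for a flat film, and bounded by 2(N−1)/N. Stacks
arrive binary; confocal gain/laser settings are operator-dependent, and
chlorophyll autofluorescence quantifies biomass only as a proxy, not cell
counts — metrics inherit that caveat. The cluster diagnostic is the OLS
slope (with adjusted R²) of maximum thickness against biovolume over the
early days: conformal layer growth gives slope ≈ 1 (for full-coverage
slabs, exactly the Δthickness/Δbiovolume ratio), colony-forming growth gives
a distinctly larger slope because a hemisphere's height grows as the cube
root of its volume from a small base.

## Synthetic scenario

The generator is a deterministic function of (config, seed); per-purpose
substreams are derived from the seed so adding one output never perturbs
another. Defaults emulate the flow-cell study design: five regimes, 15 days
of daily transmittance at 3 positions, 7-step rapid light curves
(0–1000 μmol·m⁻²·s⁻¹), confocal voxel dimensions 1.25 × 1.25 × 3.94 μm.
Optical defaults k = 1.0 m²·g⁻¹ and X₀ = 0.1 g·m⁻² give ~10 % initial
attenuation and near-opaque mature films, the magnitudes implied by
confocal-scale biovolumes at ρ = 1.4·10⁵ g·m⁻³. Ground-truth Haldane
parameters (μ_max = 1.0 d⁻¹, α = 0.02, I_opt = 150) put the continuous
control near the optimum and the 310/496 peaks well into the photoinhibited
limb, mirroring the experimental design logic. Noise models are
conventional: multiplicative lognormal (σ = 0.02) for light sensors,
additive Gaussian truncated to (0, 1) for fluorescence yields, ± 1-slice
jitter for stack columns.

The default forward model applies the no-mitigation balance
`μ = μ_L(I_peak)·ε − R`, so estimator→generator closure is exact at zero
noise. The *demo* scenario additionally enables partial light integration:
`μ = λ·(μ_L(I_ave) − R) + (1 − λ)·(μ_L(I_peak)·ε − R)` with
`λ = exp(−T/τ_I)`, τ_I = 60 s. This interpolates the two classical bounding
regimes — growth following the average light at fast cycling, the
instantaneous light at slow cycling — and is a *descriptive* kernel chosen
to reproduce the qualitative observation that 15-s cycles recover more than
twice the continuous-light gross rate while 3-min cycles barely mitigate;
it is not a mechanistic photosystem model (dynamic PSU/photoinhibition ODE
models are out of scope).

What passing tests on synthetic data do **not** show: real biofilms
saturate (growth here is exponential throughout), real sensor noise can be
correlated across days, real stacks have partial-volume voxels and
point-spread blur, and real light curves exhibit NPQ-driven β-decline. The
synthetic suite validates the *estimators and algebra*, not instrument
physics.

## Problem sizes and runtime

Defaults are desk-scale: 15-point series (100 replicates in robustness
checks), 8-level fits (50 replicates), 96 × 96 × 40 stacks, 24 × 3
productivity grids. The full demo pipeline runs in a few seconds and is
bit-reproducible for a given seed (the manifest stores SHA-256 checksums of
every output).

## Known limitations

* The max-slope window rule is positively biased under noise near the
  detection limit; the detection-limit guard controls but does not remove
  this.
* Merged touching cells inflate area estimates at high densities.
* The roughness variant (all columns vs. occupied-only) changes values for
  sparse films; both are available, the all-columns form is the default.
* R, ρ and h are configuration inputs; productivity predictions are only as
  good as those three numbers.
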