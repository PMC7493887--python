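# Methods

## Dynamical model

The core system tracks uninfected hosts [H], free infective virions [V]
and infected hosts [I], all in individuals per liter, in a well-mixed
batch culture:

    dH/dt = μH − d_H·H − kHV + μ_I·I
    dV/dt = r_s·B·k_L·I − k·(H + s·I)·V − d_V·V
    dI/dt = kHV − r_s·k_L·I − d_H·I

Adsorption is mass-action with rate constant `k`; in the laboratory a
constant kernel is a good approximation (the spatially explicit kernels
below matter in the field). `s ∈ {0, 1}` selects superinfection (free
virions are also lost to already-infected hosts, the default) versus
exclusive infection (`s = 0`, virions attach only to uninfected hosts);
the choice does not alter qualitative behavior. Lysis releases `B` virions
per cell at rate `k_L`, the reciprocal of the mean latent period `L`.
Dormant infected hosts replicate like healthy ones, and their offspring
are assumed uninfected — the resident virus is not passed to daughters —
which is why sparse pre-infected cultures outgrow their infection: by the
time induction arrives, most of the population descends (uninfected) from
originally infected cells.

Host growth is a phenomenological logistic with a time-varying rate,

    μ(t) = μ_eff(t) · (1 − (H + (1 − r_s)·I)/K)
    μ_eff(t) = μ_max            for t < 2 d
             = s_μ·t + n_μ      for 2 d < t < t_μ
             = μ_min            for t > t_μ,

emulating batch-culture aging: full growth for two days, then a linear
slide to a floor. The slope and intercept are derived from continuity at
both breakpoints, so the schedule is specified by (μ_max, μ_min, t_μ, K)
alone and continuity can never be violated by configuration. At the
breakpoints the continuous shared value is returned. Dormant infected
hosts count toward the density feedback (they consume the same resources)
and grow at μ_I = (1 − r_s)·μ; induced or virulent-infected cells neither
grow nor contribute feedback pressure.

### The induction switch

`r_s` is 0 while the resident virus is temperate and 1 once it is lytic;
it never reverts within a run. Three rules are implemented:

* **virulent** — `r_s = 1` throughout; equivalently the temperate model
  with induction imposed at t_s = 0, and the two code paths are verified
  to agree to better than 1e−6 relative across random parameter draws.
* **phenomenological temperate** — `r_s = 1` for t ≥ t_s, with t_s
  supplied per culture or per initial-density bin, in practice from the
  stress onset of the matching F_v/F_m curve.
* **self-regulated temperate** — `r_s` latches the first time the realized
  per-capita growth rate μ(t) falls below `stress_fraction · μ_max`
  (default 0.5). This is a deliberately minimal stand-in for the
  intracellular stress signalling (autophagy onset, declining
  photochemistry) that precedes induction: stress is a scalar trigger
  derived from growth, not a molecular model. Because μ(t) compounds the
  density feedback (1 − H/K) with the time decline of μ_eff, induction
  arrives through whichever bites first — crowding or aging.

The switch time is located exactly — t_s directly, or the stress-threshold
crossing by the integrator's event detection — and the ODE system is
integrated piecewise with `r_s` constant on each side, so the
discontinuity never passes through the error estimator. The exact state at
the switch is recorded on the trajectory (`state_at_induction`); the
model's *lytic density* — the host density at which lysis begins — is read
from it rather than interpolated off the output grid, which would blend in
post-induction decline on coarse (daily) grids.

### Delayed virulent variant

To represent a latent period explicitly rather than as an exponential
residence time, the delayed virulent model replaces the single infected
pool with an Erlang chain of `n_stages` compartments, each leaving at rate
`n_stages · k_L`, keeping the mean delay at `L` while sharpening its
distribution. `n_stages = 1` recovers the classic model exactly;
`n_stages = 10` is the default sharpness. This keeps the system as ODEs
with a controlled approximation instead of a true delay equation.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| μ_max | 1.0 | d⁻¹ | typical exponential growth of healthy cultures |
| μ_min | 0.1 | d⁻¹ | residual growth in aged cultures |
| t_μ | 12 | d | aging midpoint for a mid-density inoculum |
| K | 6.6e9 | L⁻¹ | pooled nutrient-replete carrying capacity, 6.6e6 cells/mL |
| k | 5.53e-9 | L ind⁻¹ d⁻¹ | calibrated so 2 h at 1e7 virions/mL infects 99% (≈2.3e-7 mL h⁻¹) |
| B | 500 | virions | conservative EhV-like burst size |
| k_L | 1/1.5 | d⁻¹ | latent period L = 1.5 d |
| d_V | 1.0 | d⁻¹ | free virions lose infectiousness in ~3 days |
| d_H | 0.05 | d⁻¹ | background host mortality |
| stress_fraction | 0.5 | — | induction at half-maximal realized growth |
| extinction floor | 1e3 | L⁻¹ | 1 cell/mL, the reporting convention for host extinction |

All are configurable (YAML/JSON via `RunConfig`). The adsorption default is
defined by the calibration itself (`default_adsorption_rate`), not a
hard-coded number. Internally everything is per liter; every I/O surface
(tidy tables, trajectory export, `from_per_ml`) is per mL, with the
conversion confined to those boundaries.

Host extinction is reported when H + I falls to the floor *and stays
there* for the rest of the grid; the slow exponential tail of the infected
pool means a collapsed culture can sit above 1 cell/mL for weeks without
recovering.

## Model selection

Residuals are taken on log10-transformed densities (the data span decades
and growth/death are multiplicative), with the model curve interpolated
onto observation times linearly in (t, log10 density). Censored or
invalid observations are excluded; both sides are clamped at a detection
floor before the transform and the number of clamped comparisons is
reported. Then

    AIC = 2M + N·ln(RSS/N),      MAE = Σ|residual|/N,

with M the free-parameter count (9 shared dynamical parameters; +1 per
density bin for the phenomenological t_s; +1 for stress_fraction). The
residuals are generally not normal, so the AIC's Gaussian analogy is used
in lieu of a better option and the MAE — linear rather than quadratic in
residual amplitude — is carried as the robustness check; the suite
verifies both statistics agree in sign wherever |ΔAIC| > 2. The natural
log is the default in the AIC (statistical convention; the log base
rescales magnitudes without changing preference ordering at fixed N and is
configurable). Pooling follows the experimental design: replicates and
treatments are pooled within one treatment × initial-density bin in one
medium, never across media or across seawater experiments with different
carrying capacities. RSS is computed on host densities by default (the
model curves being compared are host curves); a virus-density mode exists.

## Empirical feature extraction

All rules are deliberately simple scans, with thresholds chosen to be
robust to ~15% counting CV and exposed as parameters:

* **carrying capacity** — stationary phase is called after two consecutive
  sampling intervals with per-capita growth below 0.1 d⁻¹ (an order below
  the default μ_max) on the 3-point median-smoothed series; the value
  reported is the *median of the stationary-phase samples*. For a clean
  saturating curve this equals the maximum observed density; under
  multiplicative noise a running maximum is biased upward by the largest
  positive excursion (at 10% CV the max of ~6 near-plateau samples
  overshoots by >15% in roughly a fifth of realizations), while the
  stationary median meets the 15% recovery tolerance.
* **lytic density** — the highest observed density at or before the first
  of: a sustained decline (2 consecutive decreases totalling ≥2-fold), or
  a sustained divergence (2 consecutive samples ≥2-fold below the paired
  uninfected control, interpolated in log space onto the infected grid).
  A decline visible only at the final sample is flagged, not called.
  Without a control the divergence rule is skipped and flagged.
* **stress onset** — the F_v/F_m series is 3-point median smoothed; the
  plateau reference is the median of the first five valid smoothed
  samples; onset is where the smoothed curve falls below 95% of the
  plateau *and remains below to the end of the series* (transient dips are
  not onsets), with the crossing back-interpolated between samples so the
  estimate is not quantized to the sampling grid. Five reference samples
  (not three) keep the 5% threshold outside the plateau's own noise band;
  without back-interpolation the estimate is late by up to a full interval
  whenever induction falls just after a sample.
* **scaling fit** — OLS of log10 lytic density on log10 carrying capacity
  (statsmodels), reporting the slope with 95% CI and the mean vertical
  offset from the 1:1 line.
* **dilution assay** — infected fraction = 1 − after/((before/dilution)·g),
  clamped to [0, 100]%, assuming infected cells neither divide nor are
  counted after lysis; g is the 24 h growth factor of uninfected cells,
  estimated from controls or supplied.

## Encounter rates

The field-scale encounter kernel is additive,
β = β_b + β_s + β_t, with

    β_b = (2/3)(k_B·T/η)(r_V + r_H)²/(r_V·r_H)       (Brownian)
    β_s = π·w_H·(r_V + r_H)²                          (differential sinking)
    β_t = 1.3·(ε/ν)^(1/2)·(r_V + r_H)³               (turbulent shear)

with `w_H` from Stokes' law, (2/9)(ρ_cell − ρ_sw)g·r_H²/η; viral sinking
is negligible, and a buoyant cell contributes zero sinking kernel. The
reference hosts are naked (5 µm, 1050 kg/m³) and calcified (6 µm,
1190 kg/m³) cells; the regimes are calm (ε = 1e−8 m² s⁻³) and strongly
turbulent (ε = 1e−4 m² s⁻³) near-surface water. Constants not fixed by
the problem are declared defaults: virus radius 90 nm (≈180 nm capsid;
immaterial in β_s and β_t since r_V ≪ r_H), ρ_sw = 1025 kg/m³,
η = 1.07e−3 Pa·s, ν = 1.05e−6 m²/s, T = 291 K. The Sherwood-number
(advection–diffusion) framework is intentionally not implemented: it lacks
a turbulence term, and additive kernels err on the side of *higher*
encounter rates, making the >10-day encounter-time conclusion
conservative. `1/(β·C_H)` gives the expected search time of one virion.

## Synthetic experiments

The generator emulates the laboratory design, not any particular dataset:
four treatments (uninfected control; 10:1 MOI coincubation; pre-infected
— the 2 h × 1e7 virions/mL protocol moves the adsorbed fraction
1 − exp(−kVt) ≈ 0.99 into I and washes V to zero; pre-infected plus 1e6
virions/mL added back), initial densities at the decade midpoints of
10¹–10⁶ cells/mL, daily sampling for 7–21 days, and replicates. Seawater
medium reduces K by a configurable factor (default 100, up to ~1000) with
per-experiment lognormal jitter.

Each bin gets its own growth schedule: t_μ is set from the closed-form
logistic solution so cumulative effective growth carries the inoculum to
95% of K before aging dominates, reflecting how μ_eff(t) would be fitted
per bin to that bin's uninfected curve — sparser inocula age later. With a
single global t_μ, sparse cultures would stop growing orders of magnitude
below K on a pure time trigger, which no uninfected-culture fit would
produce.

The observation model is instrument emulation with declared, not inferred,
parameters: multiplicative lognormal counting noise (CV 0.15) followed by
Poisson counting in a 100 µL analyzed volume; host densities censored at
10 cells/mL and extracellular virus at the 1e5 virions/mL qPCR limit
(censored points carry the floor value and a flag); stain percentages
(dead/autophagy/UV⁺) as saturating functions of the induced-infected
fraction over a 0.5% false-positive baseline; F_v/F_m at a healthy plateau
of 0.6 declining linearly to 0.1 over 3 days after induction, with 0.02
additive noise; stain and F_v/F_m points invalid below 1e3 cells/mL. These
choices are generator-side truth for testing the pipeline, not claims
about the underlying cell biology. Real data differ in ways the generator
does not attempt: replicate-to-replicate biological variance, gating
drift, non-stationary noise at the flow-cytometry detection edge, and
missed maxima between samplings — so passing recovery tests demonstrates
the extractors' correctness against their own assumptions, not field
performance.

All randomness flows from a single integer seed through one generator, and
a generated experiment is bitwise reproducible from (design, parameters,
seed).

## Numerical choices

* Integration: LSODA (stiff-capable) with rtol 1e−8, atol 1e−3
  individuals per liter; outputs clamped at zero; state components inside
  the right-hand side clipped at zero so transient negative excursions
  cannot feed back. Adaptive solutions agree with fixed-step RK4
  (dt = 1e−3 d) to 1e−4 relative.
* Switch handling: piecewise integration around the exact switch time
  (event location for the self-regulated trigger), as above.
* Interpolation of model onto data: linear in (t, log10 density).
* Breakpoint values of μ_eff: the continuous shared value.
* Ties and degenerate inputs: empty observation overlap, all-censored
  series, perfect fits (RSS = 0), degenerate regressor variance and
  zero-kernel encounter times raise descriptive errors rather than
  returning sentinel numbers.

## Problem sizes in the test suite

The suite exercises the full pipeline at deliberately compact sizes — 2–5
density bins, 1–3 replicates, 14–21 day horizons, 100-seed recovery loops,
a 9-point carrying-capacity grid for the scaling survey — chosen as the
smallest designs that still display each phenomenon distinctly.

## Known limitations

* Stress is a scalar growth-rate trigger; there is no intracellular model
  of autophagy or metabolic remodelling, and no host heterogeneity — all
  cells in a culture share one physiological state.
* The self-regulated rule is one plausible formalization of
  physiology-triggered induction, selected for minimality; alternative
  triggers (nutrient quota, absolute density, cumulative stress) would
  shift induction times without changing the sparse/crowded dichotomy.
* Cultures are deterministic and well-mixed: no demographic stochasticity,
  no spatial structure, no aggregation or adsorption to particles, which
  in nature further impede extracellular transmission.
* The decline-based lytic-density extractor requires a population-level
  decline; in very sparse cultures where induction lyses only a small
  infected minority it correctly reports no event, so model-level and
  extracted lytic densities diverge at low K.
* The AIC is used with non-normal residuals, as a relative — not
  absolute — measure of fit, with the MAE as the cross-check.
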