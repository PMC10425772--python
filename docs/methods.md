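# Methods

`cropchamber` analyses crop tests run in a gas-tight, climate-controlled
cultivation chamber: a fixed atmosphere over a hydroponic deep-water loop, a
canopy observed only through an overhead camera, and a nutrient solution
sampled every other day. This note describes the models the package
implements, the assumptions behind them, and what the synthetic chamber does
and does not emulate.

## Atmosphere mole accounting

The chamber atmosphere (default volume 4.9 m³) is treated as a well-mixed
ideal gas: total moles are `n = P·V/(R·T)` with `R = 8.314 J·mol⁻¹·K⁻¹`,
and species inventories follow from the measured O₂ vol-% and CO₂ ppmv.
Three species are tracked — O₂, CO₂, and "inert" (everything else, chiefly
N₂ and Ar). The crop exchanges only O₂ and CO₂.

**Leak estimation.** The chamber leaks at a small fractional rate
(≈0.08 %·h⁻¹). Because the inert inventory has no biological source or
sink, its decay isolates the leak: for each day we fit `ln(n_inert)`
against time over the 24 h window by ordinary least squares and convert the
slope `s` to a per-hour loss fraction `r = 1 − e^s`. The estimate is
crop-independent by construction. Windows containing a venting event are
rejected; those days inherit the mean of their neighbours' estimates.

**Daily O₂ production.** Net production for a day is the change in chamber
O₂ moles plus the O₂ lost through the leak over that day. The leak loss
over a sampling interval ending at `t` is reconstructed as
`n_O₂(t)·r·Δt/(1 − r·Δt)`, which is exact when gas is removed with a
per-interval survival factor `(1 − r·Δt)` and accurate to O((r·Δt)²)
otherwise. Day boundaries sit at lights-on, so each accounting day contains
one full light and one full dark phase. Days interrupted by venting carry
no direct estimate: their production is linearly interpolated from the
neighbouring days and flagged, and phase totals exclude them — matching the
convention of reporting a 28-day test as 26.6 accounted days.

**Normalisation.** Phase summaries satisfy `avg_daily = total/duration` and
`pla_specific = avg_daily / avg_PLA` exactly before any rounding; the
time-mean PLA over a phase is the trapezoidal average of linearly
interpolated 2-day samples. Daily series are optionally smoothed with a
least-squares cubic before normalising by PLA.

## Canopy growth

Projected Leaf Area Index (PLAI) is the top-view silhouette area of all
plants divided by the cultivation floor area (default 1.8 m²); it is
dimensionless and bounded by 1. The specific growth rate
`µ_PLAI = (dPLAI/dt)/PLAI` is discretised as the central log-difference
`(ln p_{i+1} − ln p_{i−1})/(t_{i+1} − t_{i−1})`, which is exact for
exponential growth — the regime the metric describes. Endpoints use
one-sided differences and are flagged lower-confidence. The exponential
regression is OLS of `ln(PLAI)` on time (the spreadsheet "exponential
trendline" convention), with R² reported on the log scale; log-linear OLS
was chosen over nonlinear least squares because observed fits in this kind
of data reach R² > 0.999, where the two coincide.

## Image segmentation

Vegetation is separated from the grey chamber floor by the excess-green
index `ExG = 2G − R − B` thresholded at 20 on the 0–255 scale, followed by
removal of connected components under 16 px (8-connectivity) to suppress
sensor speckle. Projected area is the mask pixel count times the pixel
area; images are assumed orthorectified (no lens or perspective
correction). The threshold and blob filter were calibrated on the package's
own canopy renderer, which draws leaf-like green ellipse clusters on a
textured grey floor and returns the exact rendered foreground area as
ground truth.

## Nutrient solution and nitrogen mass balance

Ion inventories are concentration (mM) × volume (L) × 10⁻³; every sample
carries its own volume, since the loop volume drifts (sampling, dosing)
within its 265–275 L envelope. Sampled concentration series are smoothed
with a centred moving average (default window 3, truncated at the ends) to
filter analysis uncertainty.

The nitrogen balance is

    consumption = start + net additions − end        [mol N]
    closure     = 100 · biomass N / consumption      [%]

summed over NO₃⁻, NH₄⁺ and NO₂⁻. Additions are net of the 25 mL samples
removed every two days. NO₂⁻ is counted in the end inventory (it holds N)
but consumption is never attributed to it; its appearance is flagged as
possible nitrification. Closure is reported both unrounded and at the
nearest integer percent. The ledger accepts independently stated totals
alongside the species rows because printed tables round each row
separately; when totals are absent they default to the species sums.

The apparent NH₄⁺:N consumption ratio is `NH₄⁺ consumed / total N
consumed`. Top-up projections answer a closed-loop design question: after
replenishing the end-of-test solution to its initial total N with a stock
of fixed NH₄⁺:N ratio, the new solution ratio is
`(NH₄⁺_end + ratio·ΔN)/target` — always between the end-state ratio and the
stock ratio, so successive cultivations drift toward lower NH₄⁺:N whenever
the crop prefers ammonium.

## Harvest statistics

Per-plant metrics follow the standard definitions: dry-weight content
(% of fresh weight), harvest index (shoot DW / total DW), root:shoot ratio
(dry weight). Group summaries are per-plant-then-mean; the pooled-ratio
alternatives (ratio of summed masses) are reported separately rather than
silently substituted, because a mean of ratios is not a ratio of means.
Two-group contrasts report the percent difference plus both a Welch
(unequal-variance) t-test and a Mann–Whitney U test; Welch was chosen over
the pooled t because variance heterogeneity between treatments is the norm
in these data. A Shapiro–Wilk screen at α = 0.05 on each group selects
which p-value is the headline; both are always emitted.

## The synthetic chamber

The simulator provides ground truth for every estimator. It advances the
chamber by explicit Euler steps (default 1 h, required to divide 24 h):

- **Photoperiod** 16/8 h at 26/20 °C day/night; CO₂ floor 1000 ppmv held by
  computing the exact injection that restores the setpoint mole fraction
  within the step; at night respiration is allowed to raise CO₂.
- **Canopy**: logistic PLAI, `dPLAI/dt = µ·PLAI·(1 − PLAI/PLAI_max)`,
  integrated with the closed-form logistic solution per step (exact); the
  state is anchored so the 2-DAT sample equals `plai0` (default 0.010).
  An infinite ceiling gives pure exponential growth.
- **Gas fluxes**: daytime net O₂ production `p_spec · PLA` per day (default
  1.25 mol·d⁻¹·m⁻², chosen so net daily production per PLA lands in the
  observed 1.0–1.3 range), spread over the light phase; night respiration
  is a fixed fraction (default 0.15) of the daytime flux, spread over the
  dark phase. CO₂ moves opposite to O₂ with a photosynthetic quotient of 1.
- **Leak**: every species is multiplied by `(1 − r·Δt)` per step (default
  `r = 8.2·10⁻⁴ h⁻¹`), the well-mixed assumption — the leak does not
  discriminate between species. Nothing replenishes the atmosphere, so
  total moles (and pressure) decline a few tens of percent over four weeks;
  the pressure-compensation tank of the real facility is abstracted into
  this leak/vent bookkeeping rather than modelled as a separate reservoir.
  One consequence: O₂ vol-% can re-cross the 25 % safety cap late in a long
  test and trigger a second, unscheduled vent; the analysis treats it like
  the scheduled one.
- **Venting**: an instantaneous reset of mole fractions to ambient
  (20.95 % O₂, 420 ppmv CO₂) at constant total moles, scheduled one hour
  into the vent day (default day 19) so the neighbouring 24 h
  leak-estimation windows stay clean, plus the O₂-threshold trigger.
- **Nitrogen**: biomass gain couples to canopy expansion through a fixed
  shoot DW per projected area (default 0.27 kg·m⁻²); N demand is
  3.1 mol·kg⁻¹ DW, drawn preferentially from NH₄⁺ (fraction `nh4_pref`
  while NH₄⁺ lasts, then NO₃⁻). Stock dosing restores NO₃⁻ to its setpoint
  exactly each step, carrying NH₄⁺ at the stock's own NH₄⁺:N ratio; base
  addition is logged mole-per-mole with NH₄⁺ uptake (the proton balance of
  ammonium nutrition). A 25 mL sample is withdrawn every two days.
- **Noise**: independent seeded Gaussians per sensor channel (defaults:
  0.002 vol-% O₂, 2 ppmv CO₂, 10 Pa, 0.02 K) and 2.5 % multiplicative
  noise on PLAI samples, emulating segmentation uncertainty. The PLAI noise
  default was set from the observed realism bound that exponential fits of
  such data reach R² > 0.999 in ≥90 % of runs. With all channels at zero
  the output is deterministic and independent of the seed.

The truth ledger satisfies exact per-day mole conservation
(ΔO₂ = production − leak − vent) and exact nitrogen conservation
(start + additions − samples − uptake = end); the test suite asserts both
at ~10⁻¹² relative.

The two built-in scenarios differ in nutrient solution (9.7/1.3 vs
5.6/5.3 mM NO₃⁻/NH₄⁺), growth rate (µ = 0.22 vs 0.18 d⁻¹), canopy ceiling
(0.75 vs 0.42), and ammonium preference (0.31 vs 1.0).

### What the simulator does not emulate

No humidity, transpiration or condensate water; no mechanistic
photosynthesis (light response, CO₂ dependence) — the net flux is an
area-scaled rate; no microbial nitrification dynamics; no separate
compensation-tank composition; no plant-to-plant variation before harvest
(the harvest sampler splits crop totals with gamma-distributed weights).
Passing recovery tests therefore shows the estimators are correct under
the stated model, not that the model captures every feature of real
chamber data — in particular, real daily O₂ estimates inherit uncertainty
from the compensation-tank composition that the simulator sidesteps.

## Numerical choices and degenerate inputs

- Integration step 1 h; accounting tolerances are asserted against closed
  forms, not against the integrator itself.
- Leak estimation requires a full 24 h vent-free window; daily production
  requires sampling gaps ≤ 2 h (an estimated day with a larger hole is
  refused, naming the gap).
- A zero PLA refuses normalisation at that point; zero total N refuses a
  ratio; a 0/0 consumption ratio returns NaN with a flag rather than a
  number.
- Uptake that would drive a solution ion negative raises an error naming
  the depleted ion and the shortfall.
- Reporting rounds to the printed conventions (integer percent closure,
  two decimals for productivities); all internal arithmetic is unrounded.

## Problem sizes

Simulated crop tests run 28 days at a 1 h step (673 sensor rows); recovery
statistics use 100 seeds for growth-rate fits, 50 for segmentation
round-trips and noisy leak estimates. These sizes make every property
deterministic to assert while keeping the full suite fast.
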