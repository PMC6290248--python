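# Methods

## Model structure and assumptions

The model treats a dormant, leafless walnut branch as a closed two-pool
carbon system: starch (reserve) and GFS (glucose + fructose + sucrose,
the osmotically active soluble fraction, ~90 % of soluble carbohydrates
in walnut), both in mg per g dry matter, with respiration as the only
loss. There is no photosynthetic input (leafless period), no export to
buds (pre-budburst only), and no within-day dynamics: the state advances
once per day from daily mean air temperature, interpolated water content
and the dormancy stage.

### Dormancy phenology

Endo- and ecodormancy are strictly sequential. Chilling units (CU) are
the inverse Richardson function of the daily mean temperature, summed
from day-of-year 244 (1 September) with CU = 0 on the start day; forcing
units (FU) start accumulating the day after CU first reaches CU_crit.
Constants (walnut cv. Franquette): T_low = 3.1 °C, T_high = 26.7 °C,
CU_crit = 2298.8, slp = 0.244 °C⁻¹, T50 = 13.46 °C, FU_crit = 21.2.
The stage index is PS = min(CU/CU_crit, 1) + min(FU/FU_crit, 1) ∈ [0, 2].

Two conventions needed fixing where the source material is ambiguous:

* The forcing slope is taken **positive** (+0.244 °C⁻¹) so that warmth
  accelerates ecodormancy release; the sigmoid's exponent already carries
  the minus sign. T50 is used at its full precision, 13.46 °C.
* The chilling term of PS is capped at 1 (raw CU is kept in the output
  for diagnostics); otherwise PS could pass 1 before forcing begins.

Daily mean temperature is the `tmean` column when present, otherwise the
tmin/tmax midpoint. Seasons span two calendar years and are keyed to the
day-of-year-244 of the starting year; leap years are handled by calendar
arithmetic.

### Rate laws

Each catalytic activity i ∈ {cold hydrolysis, mild hydrolysis,
re-synthesis} is a linear function of PS times a symmetric Gaussian in
temperature, clamped at zero:

    k_i = max[0, (a_i PS + b_i) · exp(−(θ − μ_i)² / (σ_i · 2π))]

The Gaussian denominator is σ·2π **as printed in the source relation**,
not the classical 2σ²; since σ is a free fitted parameter the functional
family is identical and only σ's interpretation changes (thermal SD
≈ √(σπ)). The phase coefficients are reparameterised through the rate at
the endo→eco transition, a + b = k_trans in both phases, which makes the
rate continuous at PS = 1 by construction; the eco-phase b is
(k_trans − d_eco)/2, mirroring the endo phase (the alternative printed
sign would break the transition equality). At exactly PS = 1 the eco
branch applies — harmless by continuity.

Respiration is zero-order in substrate:
R = R_max / (1 + e^{a₃(WC − b₃)}) · Q₁₀^{(θ−15)/10}. With a₃ < 0
respiration increases with water content, matching the observation that
hydrated tissue respires more at warm temperature.

### Daily update and mass balance

GFS(t+1) = GFS(t) + H − S − R and Starch(t+1) = Starch(t) − ΔGFS − R.
Substituting shows the −R terms in the starch balance cancel: starch
changes by S − H and total NSC declines by exactly R per day. This
literal algebra is adopted (respiration drawn from the GFS pool); the
alternative reading, NSC declining by 2R, is rejected as inconsistent
with the printed update equations.

The update equations are silent on pool exhaustion, which matters
because zero-order terms (simple-variant fluxes, respiration) can
overdraw a pool. Rule adopted: per day, each pool's outgoing fluxes are
rescaled by available/demanded when they exceed the pool at the start of
the day (hydrolysis is capped at the starch pool; re-synthesis and
respiration are scaled jointly against GFS). This keeps pools
nonnegative, preserves the NSC balance with the *realized* respiration,
and flags the day as floored in the trajectory.

Water content is piecewise-linear between sampling dates and held at the
nearest observation outside their span (flagged). In the cold-room
emulation, detached branches keep the water content of their sampling
day (cut ends sealed) while phenology keeps accumulating at the constant
treatment temperature.

## Calibration

The objective is the pooled residual sum of squares of simulated vs
observed GFS and starch (equal weights — no weighting is prescribed),
over one or more datasets tagged calibration or validation; metrics are
reported as RMSE/Eff on calibration data and RMSEP/Eff on validation
data, never mixed. Simulation failures inside the objective return +∞ so
the optimiser retreats rather than crashes.

Nelder–Mead is restarted from a Latin hypercube sample over per-parameter
bounds; default protocol 100 starts × 200 000 evaluations per start at
relative tolerance 10⁻⁸ ("up to 200 000" is read as a per-start budget;
both are configurable). Nelder–Mead is unconstrained, so each parameter
is mapped to the real line by a logit transform of its bounds — smoother
than penalty barriers. After all starts, the simplex is restarted from
the incumbent up to three times (restarting a collapsed simplex is the
standard remedy for premature termination in high dimension).

Default bounds: μ₁c ∈ [−5, 5] °C, μ₁m ∈ [10, 25] °C, μ₂ ∈ [8, 20] °C
(anchored on the published seasonal response-curve ranges), σ ∈ (0, 500],
Q₁₀ ∈ [1, 4], a₃ ∈ [−50, 0], b₃ ∈ [0.3, 1.5] g·g⁻¹, R_max ∈ [0, 5]
mg·g⁻¹·d⁻¹, and variant-scaled rate magnitudes (day⁻¹ for the
intermediate variant, mg·g⁻¹·d⁻¹ for the simple variant and for the
complete variant's maximal velocities, with K_M ∈ [1, 2000] mg·g⁻¹).
All are user-overridable.

## Synthetic data

The generator replaces the undeposited orchard and cold-room datasets
with draws from known ground truth, so every downstream stage has a
recoverable target.

* **Weather**: seasonal cosine (annual mean 11 °C, amplitude 8.5 °C,
  warmest mid-July) plus stationary AR(1) noise (SD 3.5 °C, lag-1
  correlation 0.6) for a mid-France-like climate; tmin/tmax are the mean
  ∓ half an 8 °C diurnal range.
* **Ground-truth kinetics** (intermediate variant): optima μ = −0.1,
  17 and 13 °C — inside the published response-curve ranges — with width
  σ = 5 (thermal SD ≈ 4 °C, giving the observed two-peaks-with-a-trough
  response shape), stage differences that make cold hydrolysis dominate
  endodormancy, mild hydrolysis strongest in autumn and re-synthesis
  switch on during ecodormancy, and respiration R_max = 1.2 mg g⁻¹ d⁻¹,
  a₃ = −8, b₃ = 0.9, Q₁₀ = 2.64.
* **Field sampling**: initial pools GFS = 30, starch = 95 mg·g⁻¹ at the
  first autumn observation (45 days after day-of-year 244); destructive
  sampling every 30 days until budburst; independent Gaussian noise with
  SD 5 mg·g⁻¹ on both pools, 0.03 g·g⁻¹ on water content and 1 °C on
  measured frost hardiness. Water content follows a piecewise-linear
  seasonal profile (drying into midwinter, rewetting in spring), treated
  as an observed input, not modelled. FH observations come from the
  osmo-hydric relation with a = −5.32, b = 1.71 plus noise.
* **Cold room**: temperatures −3, +1, +5, +10, +15, +20, +25 °C for 7
  and 20 days (the "19–21 day" storage is fixed at 20), branches taken
  from the latent field trajectory at a chosen date.
* **Depleted scenario**: the defoliation manipulation is represented as
  a 60 % reduction of initial starch, all else equal.

Under these defaults the latent season reproduces the canonical winter
pattern — starch falls from 95 to ~10 mg·g⁻¹ into midwinter while GFS
rises from 30 to ~97, then the conversion reverses through ecodormancy —
which the test suite asserts. What the generator does *not* emulate:
tree-to-tree random effects (replicates are i.i.d. noise around one
latent trajectory), weather downscaling realism, carbon input before
leaf fall or export after budburst. Passing tests therefore demonstrate
the machinery is correct and self-consistent, not that the model is
adequate for any particular orchard.

## Test design choices worth knowing

* **Parameter identifiability.** The thermal optima μ are *practically
  non-identifiable* from monthly field sampling alone at a 5 mg·g⁻¹
  noise level: monthly pool levels constrain only the net flux along the
  one-dimensional seasonal (θ, PS) path, and μ trades off against the
  stage amplitudes along a nearly flat likelihood ridge. Empirically, a
  Nelder–Mead descent started *at the true parameters* walks several °C
  away from them while lowering the residual sum of squares below the
  pure-noise level, and the fitted optima settle near the mean
  temperatures realized during each channel's active season. The
  recovery test on three noisy seasons accordingly achieves model
  efficiency ≈ 0.99 against the noiseless truth but recovers μ only to
  3–7 °C, and the suite reports this honestly as a failing expectation.
  Pinning μ to a couple of degrees requires constant-temperature
  response data (the cold-room design exists for exactly this reason) or
  tight informative bounds.
* **Model discrimination** uses a held-out *depleted* season: with a
  normal held-out season the ranking of intermediate vs complete is a
  noise-level coin flip, because the complete variant nests the
  intermediate one (large-K_M limit) and even the simple variant mimics
  substrate limitation through flooring once starch is exhausted. Low
  initial pools break both escapes: zero-order fluxes calibrated on
  normal pools overshoot systematically, and the intermediate variant
  wins by a stable margin.
* **Scaled-down protocol.** The test suite and the acceptance script run
  the multistart protocol at 10–20 starts with 4 000–8 000 evaluations
  per start on one to three seasons; these sizes reproduce the protocol's
  behaviour at desk scale and every reported quantity states the problem
  size it used.
* The phenology implementation is checked bit-exactly against a naive
  daily re-accumulation for the chilling sum (pure arithmetic) and to
  10⁻⁹ for the forcing sum (scalar libm vs vectorised exp differ in the
  last ulp).

## Numerical notes and limitations

* Trajectories are deterministic and bit-reproducible for identical
  inputs; all stochastic stages are pure functions of their seed.
* The σ·2π width convention means fitted σ values are not comparable to
  Gaussian SDs without conversion (SD = √(σπ)).
* The window-correlation scan defines the w-day trailing mean as days
  t−w+1 … t inclusive (w = 0 is the sampling day); sampling dates with
  insufficient weather history are dropped per window, and a constant
  predictor yields a missing correlation.
* The three-Gaussian response decomposition is a *descriptive* fit of
  cold-room response curves (two positive components, one negative,
  classical 2σ² widths); it is multistart least squares and can land in
  local minima for pathological inputs, in which case it raises rather
  than returning silently.
* Frost hardiness is predicted from *observed* (interpolated) water
  content, not modelled water content, as in the source procedure.
* Chilling stops mattering beyond CU_crit (the PS cap is a design
  decision); sub-daily temperature data are not supported.
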