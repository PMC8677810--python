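# Methods

## Scope and model structure

`rasim` simulates the oxygen economy and growth of a single tilapia
tank in a recirculating aquaculture system. Two clocks run together: a
daily clock advances individual fish weight by the bioenergetic growth
rate, and an hourly clock evaluates the tank's oxygen budget using that
day's weight (no intra-day interpolation — the literature the budget
comes from gives none, and the within-day weight change is far below
the other model errors). A run is fully deterministic given its
configuration; randomness exists only in the synthetic-data generator,
always behind an explicit seed.

The oxygen budget has four terms (g O2 m-3 h-1): fish respiration
(quadratic surface in temperature and weight, times stocking density),
nitrification (4.57 g O2 per g TAN, TAN production proportional to the
feed offered, temperature dependence 0.1·1.08^(T−20)), biofilter demand
(2.3× the BOD5 excretion of the standing biomass) and pipe-flow
aeration. Supplemental generator demand closes the balance; it can be
negative near harvest size (aeration exceeding demand), which is
reported with a flag rather than clamped.

## Presets and deliberately preserved inconsistencies

The published figures this model family reproduces were evidently
computed under conventions that differ from the physically consistent
ones, so two presets ship and neither silently corrects the other:

* **reproduction** — stocking density fixed at 100 kg m-3 and the
  pipe-flow term on a per-cubic-metre basis (giving the 18.4 value whose
  subtraction from totals reproduces the published supplemental-demand
  pairs, e.g. 74.55 − 18.4 = 56.15). Only under SD = 100 does the
  respiration surface reproduce the published volumetric series
  (46.06 at 28 °C / 3 g; 12.01 at 28 °C / 226.25 g).
* **physical** — dynamic stocking density N·W/V and the pipe-flow term
  over the actual tank volume (150 m3). This is the preset for
  realistic engineering use.

Known issues carried visibly rather than patched:

* The published 26 °C fingerling respiration value (26.79) disagrees
  with the surface itself (36.79, which also restores monotonicity in
  temperature); the package computes 36.79 and documents the erratum.
* The published nitrification (0.13–4.56) and biofilter (0.43–21.91)
  series are not derivable from the stated equations under any single
  density/volume convention consistent with the respiration series; the
  package reports its equations' own values (the nitrification term is
  ~2 orders of magnitude smaller at fingerling size).
* The DO update in its printed form accumulates *unmet demand* (DO
  rises with consumption); it is available verbatim as
  `do_step(mode="as_printed")`. The `physical` mode integrates supply
  minus demand and floors at zero with a warning, and is what the
  simulator's DO trace uses, assuming a steady controller that supplies
  exactly the closing demand.
* The respiration surface is evaluated at 3–226 g although its
  regression support is 20–200 g and 24–32 °C; this emits a warning,
  not an error, because grow-out runs genuinely start below the
  support.

## Growth model, the catabolism knob and calibration

With the tabulated constants (K_min = 0.25, h = 0.81, m = 0.67,
n = 0.81) the catabolism term K·W^n exceeds anabolism for every weight
above ~0.2 g at any relative feeding level f ≤ 1, so the growth rate is
negative everywhere of interest. The time basis is taken as daily
throughout (the rate is defined in g day-1; the tabulated per-hour unit
of K_min is treated as a misprint — converting it would make growth 24×
more negative). Rather than editing a literature constant, the package
exposes `k_scale`, an explicit rescale of K_min, and calibrates it.

Two calibration routes are implemented:

* `calibrate_relative_feeding` — the procedure described for the model:
  f on a 0.01 grid over [0, 1], objective = sum of squared deviations
  between the model's interval-mean growth rate and a reference
  schedule (default: the hatchery feeding table's growth-rate column,
  reconstructed as rate ≈ interval width / growth period). With
  `refine=True`, k_scale is profiled out per grid point by its
  closed-form least-squares value; this is required for a meaningful
  fit under the tabulated K_min. On the default schedule it returns
  f = 0.83, k_scale = 0.196.
* `calibrate_to_final_weights` — joint (f, k_scale) fit to 150-day
  final weights by rearing temperature (f on the same grid, k_scale by
  bounded scalar minimization per grid point).

The **calibrated preset uses the second route**, anchored to the
reference grow-out endpoints (213.35 / 222.02 / 226.25 / 217.78 /
209.92 g at 24–32 °C). The reason is structural, found during
implementation: the catabolism temperature slope (s = 0.015 °C-1, ~3%
per 2 °C) dominates the nearly flat top of the intake bell τ (0.4%
between 26 and 28 °C), so any rate-schedule fit with appreciable
k_scale puts the growth optimum at 26 °C, not at the 28 °C intake
optimum the endpoint data show. Only endpoint data across temperatures
can pin down the anabolism/catabolism balance; the fit lands at
f = 0.40, k_scale = 0.0029 (catabolism nearly negligible), RMSE ≈ 6.8 g
over the five endpoints, and reproduces the endpoint ordering
28 > 26 > 30 > 24 > 32 °C. The below-optimum τ denominator defaults to
(T_opt − T_min), the standard symmetric form, which also fits the
endpoint asymmetry (24 °C above 32 °C) better than the printed variant
(T_opt − T_max); both are selectable via `tau_low_denominator`.

Other growth choices: factor boundary points take the permissive value
1 (continuity from the unconstrained side); integration halts with a
flag if weight would fall below 0.1 g (uncalibrated parameter sets fail
loudly instead of producing negative weights); negative growth rates
are reported, never clamped.

## Validation and synthetic data

The validation stage regresses predicted on measured (the response/
regressor order in which parity fits are conventionally printed),
reporting slope, intercept, R², the slope's standard error and the mean
absolute relative error in percent (the "error" of a parity comparison
is not otherwise standardized; MARE is unit-free and reproducible).
Four quantities are compared: mass-specific respiration (sensor rows
inverted through the inlet/outlet formula, daily means by default;
hourly by flag), biofilter demand, total volumetric consumption and
individual weight. The measured side of the biofilter/total terms is
built from the *measured* weights, so weighing noise propagates into
them; volumetric conversions use dynamic density biomass/V on both
sides regardless of preset, keeping the comparison in measurement
space.

The synthetic generator chooses an inlet DO (default 8 mg L-1, a
typical oxygenated supply) and solves the outlet DO so the inversion
recovers the model's respiration exactly, then adds Gaussian noise to
both channels (default sigma 0.12 mg L-1, an instrument class of ~1.5%
of reading); weighings every 10 days get multiplicative lognormal noise
(mean exactly 1, CV configurable). At the pump's rated 30 m3 h-1 the
demanded inlet-outlet drop exceeds the inlet DO once biomass has grown
enough, so the generator refuses (naming the limiting hour) unless
`flow="adaptive"`, which scales the flow to hold the drop near a target
(default 2 mg L-1) — the bookkeeping analogue of adjusting flow with
growth. What noise-free round trips prove is pipeline correctness
(slope 1, intercept 0, R² 1, 0% error for all four quantities), not
field accuracy: the generator emulates instrument error around a model
trajectory and none of sensor drift, fouling, diel cycles, individual
variation or mortality.

## Numerical choices and problem sizes

The feeding-table intervals are stored with their raw rate bands and
used at band midpoints in table mode. Calibration interval means use
25-point weight grids (insensitive beyond ~10 points). The budget
closure identity holds to 1e-9 row-wise by construction and is asserted
in tests. Test and example runs use 1–150-day horizons (hourly output
is 24 rows/day; a 150-day, 5-temperature sweep takes a few seconds);
the Monte-Carlo unbiasedness check uses 1000 regenerated weighing logs.
All stochastic tests are seeded; hypothesis runs derandomized.

## Limitations

Single tank, no mortality, no feedback control of the oxygen generator,
no gas-transfer physics (the oxygen transfer rate is a fixed
parameter), no multi-tank networks or economics. The calibrated preset
is a documented reconstruction: the endpoint data it is anchored to
cannot be reproduced from the tabulated constants as printed, and the
catabolism rescale it returns should be read as "effective catabolism
under these endpoints", not as a physiological measurement.
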