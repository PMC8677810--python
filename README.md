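# rasim — oxygen and growth simulation for recirculating tilapia culture

`rasim` is a Python library (with a thin CLI) for engineers and
researchers sizing the oxygenation of a recirculating aquaculture
system (RAS) for Nile tilapia. It couples two models over a grow-out
horizon:

**Hourly dissolved-oxygen mass balance.** The supplemental oxygen the
generator must add closes the tank budget

```
DO_FR + DO_B + DO_N = DO_sup + DO_PF        [g O2 m-3 h-1]
```

where fish respiration is a quadratic response surface in temperature
and individual weight scaled by stocking density,

```
FR(T, W) = 2014.45 + 2.75 W - 165.2 T + 0.007 W^2 + 3.93 T^2 - 0.21 W T
DO_FR    = FR * SD / 1000,
```

nitrification demand is `DO_N = 4.57 * K_NR * Nr / V` with
`K_NR = 0.1 * 1.08^(T-20)` and TAN production proportional to the
feeding ratio `Fr(W) = 17.02 * exp(-(ln W + 1.14)^2 / 19.52)`,
biofilter demand is 2.3x the BOD5 excretion of the standing biomass,
and pipe-flow aeration is `PC * f * E * OTR / V`.

**Daily bioenergetic growth.** Individual weight follows
`W_n = W_{n-1} + FGR` with

```
FGR = 0.2919 * tau * kappa * delta * phi * h * f * W^m  -  K(T) * W^n   [g day-1]
```

— anabolism throttled by temperature (`tau`), photoperiod (`kappa`),
dissolved oxygen (`delta`) and unionized ammonia (`phi`), minus
exponential-in-temperature catabolism `K = K_min exp[s(T - T_min)]`.
The relative feeding level `f` is calibrated by grid search (step 0.01
on [0, 1]); because the tabulated constants alone make catabolism
dominate at any ration, a catabolism rescale `k_scale` is fitted
jointly and reported explicitly (see `docs/methods.md`).

On top of the simulator sit a validation stage (ordinary-least-squares
parity fits of predicted on measured series, R², mean absolute relative
error) and a synthetic-data generator that inverts the sensor formula
`OC = (DO_in - DO_out) * Q / biomass * 1000` to produce measured-style
inlet/outlet DO logs and 10-day weighing logs with configurable
instrument noise — so the whole validation pipeline is testable without
farm data.

## Worked example

```python
import rasim

params = rasim.reproduction_preset()        # fixed SD = 100 kg m-3
budget = rasim.compute_budget(T=28.0, W=3.0, params=params)
print(budget.do_fr, budget.do_sup)

preset = rasim.calibrated_preset()          # fitted (f, k_scale)
summaries = rasim.temperature_sweep(preset, [24, 26, 28, 30, 32], days=150)
for s in summaries:
    print(s.temperature_c, round(s.final_weight_g, 2))
```

Running `python examples/03_temperature_sweep.py` prints:

```
T [C]   final W [g]   DO_FR start->end   DO_sup start->end  [g O2 m-3 h-1]
  24      207.77      0.12 ->   3.76      0.09 ->   9.33
  26      226.91      0.15 ->   3.57      0.11 ->   9.67
  28      228.02      0.18 ->   3.60      0.15 ->   9.73
  30      225.90      0.23 ->   4.51      0.20 ->  10.60
  32      199.57      0.30 ->   6.35      0.26 ->  11.74

maximum final weight 228.02 g at 28 C (the intake optimum)
```

Final weight peaks at the 28 °C intake optimum; the oxygen columns show
how respiration demand (here under dynamic stocking density, so it
*rises* with biomass) and the generator's supplemental duty grow over
the run. The other examples walk through the hourly budget
(`01_oxygen_budget.py`), the feeding-level calibration
(`02_growth_calibration.py`) and the parity-validation round trip
(`04_validation_roundtrip.py` — noise-free synthetic logs return slope
1, intercept 0, R² 1, 0% error for every compared quantity).

A thin CLI mirrors the library:
`rasim simulate --preset reproduction --days 150 --out-dir results/`,
then `rasim synth`, `rasim validate`, `rasim sweep`, `rasim calibrate`;
every run directory gets a `manifest.json` with the full configuration,
its hash, the seed and any warnings.

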