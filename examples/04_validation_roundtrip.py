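"""Model-vs-measurement parity on synthetic sensor campaigns.

Simulates 90 days, synthesizes an hourly inlet/outlet DO log and a
10-day weighing log from the trajectory, and parity-fits model against
"measurement".  Noise-free logs return the identity fit exactly (the
pipeline round-trips); instrument-class noise (~1.5% of an 8 mg/L
reading) degrades R^2 but leaves the slope statistically at 1.
"""

import rasim

traj = rasim.run_simulation(rasim.calibrated_preset(), days=90)


def report_line(name, fit):
    print(
        f"  {name:12s} slope={fit['slope']:.4f}  intercept={fit['intercept']:.4f}  "
        f"R2={fit['r_squared']:.4f}  error={fit['mare_pct']:.2f}%"
    )


for sigma, label in ((0.0, "noise-free"), (0.12, "instrument noise 0.12 mg/L")):
    noise = rasim.NoiseSpec(do_sigma=sigma, weight_cv=0.02 if sigma else 0.0, seed=42)
    sensors = rasim.generate_sensor_log(traj, noise, flow="adaptive")
    weights = rasim.generate_weighing_log(traj, interval_days=10, noise=noise)
    report = rasim.validation_report(traj, sensors, weights)
    print(f"{label}:")
    for key in ("respiration", "biofilter", "total", "fish_weight"):
        report_line(key, report[key])
    print()

print(
    "A perfect noise-free round trip is the pipeline's correctness check;\n"
    "with noise, slope ~1 within its standard error shows the parity fit\n"
    "recovers the model-measurement agreement it is designed to measure."
)
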