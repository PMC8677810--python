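"""Measured-style data generators for exercising the validation stage.

Sensor logs (hourly inlet/outlet DO pairs) are built by *inverting* the
consumption formula OC = (DO_in - DO_out) * Q / biomass * 1000: the
outlet DO is set so the formula recovers the model's mass-specific
respiration exactly, then Gaussian instrument noise is added to both
channels (a bench DO meter is good to roughly +-1.5% of reading, about
0.12 mg L-1 near 8 mg L-1).  Weighing logs sample the model weight every
few days with multiplicative lognormal noise.

These emulate instrument error around a model trajectory only -- not
sensor drift, fouling, diel cycles or real biological variation -- so
perfect parity on noise-free logs demonstrates pipeline correctness,
not field accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .simulate import Trajectory

SENSOR_COLUMNS = ["timestamp_h", "do_in_mg_l", "do_out_mg_l", "flow_m3_h", "biomass_kg"]
WEIGHING_COLUMNS = ["day", "weight_g"]


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument noise: additive sigma on DO channels [mg L-1],
    coefficient of variation on weighings, and the RNG seed."""

    do_sigma: float = 0.12
    weight_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.do_sigma < 0 or self.weight_cv < 0:
            raise ValueError("noise magnitudes must be >= 0")


def generate_sensor_log(
    trajectory: Trajectory,
    noise: Optional[NoiseSpec] = None,
    inlet_do: float = 8.0,
    flow: Union[float, str, None] = None,
    target_delta: float = 2.0,
) -> pd.DataFrame:
    """Hourly inlet/outlet DO log consistent with the model trajectory.

    ``flow`` is a constant [m3 h-1] (default: the tank's rated flow), or
    ``"adaptive"`` to scale the flow with biomass so the inlet-outlet
    drop stays near ``target_delta`` mg L-1 -- the bookkeeping analogue
    of adjusting the flow as the stock grows.  Raises if the demanded
    drop cannot be realized with a non-negative outlet DO, naming the
    limiting hour.
    """
    if not trajectory.hourly:
        raise ValueError("trajectory has no hourly records; rerun with hourly=True")
    noise = noise or NoiseSpec(do_sigma=0.0, weight_cv=0.0, seed=0)
    rng = np.random.default_rng(noise.seed)

    times, do_in, do_out, flows, biomasses = [], [], [], [], []
    for rec in trajectory.hourly:
        b = rec.budget
        # mass-specific consumption implied by the model [mg kg-1 h-1]
        oc = b.do_fr / b.stocking_density * 1000.0 if b.stocking_density > 0 else 0.0
        if flow is None:
            q = trajectory.params.tank.flow_rate
        elif flow == "adaptive":
            q = max(
                trajectory.params.tank.flow_rate,
                oc * b.biomass_kg / (1000.0 * target_delta),
            )
        else:
            q = float(flow)
        if q <= 0:
            raise ValueError(f"flow must be > 0, got {q}")
        delta = oc * b.biomass_kg / (1000.0 * q)
        outlet = inlet_do - delta
        if outlet < 0:
            raise ValueError(
                f"flow {q} m3 h-1 too small to realize the demanded DO drop "
                f"({delta:.2f} mg L-1) at hour {rec.time_h:.0f} with non-negative "
                "outlet DO; raise the flow or use flow='adaptive'"
            )
        times.append(rec.time_h)
        do_in.append(inlet_do)
        do_out.append(outlet)
        flows.append(q)
        biomasses.append(b.biomass_kg)

    do_in = np.asarray(do_in) + rng.normal(0.0, noise.do_sigma, len(times))
    do_out = np.asarray(do_out) + rng.normal(0.0, noise.do_sigma, len(times))
    return pd.DataFrame(
        {
            "timestamp_h": times,
            "do_in_mg_l": do_in,
            "do_out_mg_l": do_out,
            "flow_m3_h": flows,
            "biomass_kg": biomasses,
        }
    )


def generate_weighing_log(
    trajectory: Trajectory,
    interval_days: int = 10,
    noise: Optional[NoiseSpec] = None,
) -> pd.DataFrame:
    """Sample the model weight every ``interval_days`` (day 0 included)
    with multiplicative lognormal noise of the requested CV, mean 1."""
    if interval_days < 1:
        raise ValueError(f"interval_days must be >= 1, got {interval_days}")
    noise = noise or NoiseSpec(do_sigma=0.0, weight_cv=0.0, seed=0)
    rng = np.random.default_rng(noise.seed + 1)  # decouple from the DO stream
    days = [r.day for r in trajectory.daily if r.day % interval_days == 0]
    weights = np.array(
        [r.weight_g for r in trajectory.daily if r.day % interval_days == 0]
    )
    if noise.weight_cv > 0:
        sigma = np.sqrt(np.log1p(noise.weight_cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(days))
        weights = weights * factors
    return pd.DataFrame({"day": days, "weight_g": weights})
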