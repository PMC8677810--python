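"""Hourly dissolved-oxygen mass balance for a recirculating culture tank.

Four flux terms, all in g O2 m-3 h-1:

* ``do_fish_respiration`` -- mass-specific respiration of the stock,
  scaled by stocking density;
* ``do_nitrification`` -- oxygen bound by oxidizing the TAN excreted in
  response to feeding;
* ``do_biofilter`` -- heterotrophic demand of the biofilter, a fixed
  multiple of the BOD5 excretion of the biomass;
* ``do_pipe_flow`` -- oxygen added by the water-pumping cycle.

The supplemental demand the oxygen generator must meet closes the
balance: DO_sup = DO_FR + DO_N + DO_B - DO_PF.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from .params import (
    AerationParams,
    BiofilterParams,
    NitrificationParams,
    ParameterBundle,
    RespirationParams,
)


class ValidityRangeWarning(UserWarning):
    """Respiration surface evaluated outside its regression support."""


class NegativeConsumptionWarning(UserWarning):
    """Sensor pair implies oxygen gain across the tank (outlet > inlet)."""


class DOFloorWarning(UserWarning):
    """A DO update would have gone negative and was floored at zero."""


def respiration_rate(
    T: float, W: float, params: Optional[RespirationParams] = None
) -> float:
    """Mass-specific respiration FR(T, W) in mg O2 kg-1 fish h-1.

    Quadratic response surface in temperature [C] and individual weight
    [g].  Outside the regression support a :class:`ValidityRangeWarning`
    is emitted (not an error: grow-out runs start well below 20 g).
    """
    if not (math.isfinite(T) and math.isfinite(W)):
        raise ValueError(f"respiration_rate requires finite inputs, got T={T}, W={W}")
    p = params or RespirationParams()
    w_lo, w_hi = p.valid_weight_range
    t_lo, t_hi = p.valid_temp_range
    if not (w_lo <= W <= w_hi) or not (t_lo <= T <= t_hi):
        # message deliberately carries no state so default warning
        # filters collapse the per-hour repeats to one line
        warnings.warn(
            f"respiration surface evaluated outside its fitted support "
            f"(weight {w_lo}-{w_hi} g, {t_lo}-{t_hi} C)",
            ValidityRangeWarning,
            stacklevel=2,
        )
    c0, c1, c2, c3, c4, c5 = p.coefficients
    return c0 + c1 * W + c2 * T + c3 * W * W + c4 * T * T + c5 * W * T


def do_fish_respiration(
    T: float, W: float, sd: float, params: Optional[RespirationParams] = None
) -> float:
    """Volumetric respiration DO_FR = FR(T, W) * SD / 1000 [g O2 m-3 h-1]."""
    if sd < 0:
        raise ValueError(f"stocking density must be >= 0, got {sd}")
    if sd == 0:
        return 0.0
    return respiration_rate(T, W, params) * sd / 1000.0


def respiration_minimum_weight(
    T: float, params: Optional[RespirationParams] = None
) -> float:
    """Weight [g] minimizing FR(., W) at fixed temperature.

    Vertex of the quadratic in W: W* = -(c1 + c5*T) / (2*c3).  Explains
    why the predicted volumetric series bottoms out near harvest size.
    """
    p = params or RespirationParams()
    _, c1, _, c3, _, c5 = p.coefficients
    if c3 <= 0:
        raise ValueError("respiration surface is not convex in weight (c3 <= 0)")
    return max(0.0, -(c1 + c5 * T) / (2.0 * c3))


def nitrification_coefficient(
    T: float, params: Optional[NitrificationParams] = None
) -> float:
    """Temperature coefficient K_NR = k_base * theta**(T - t_ref)."""
    p = params or NitrificationParams()
    return p.k_base * p.theta ** (T - p.t_ref)


def nitrification_rate(
    fr_pct: float,
    W: float,
    n_fish: float,
    params: Optional[NitrificationParams] = None,
) -> float:
    """TAN production Nr = tan_fraction * Fr * W * N / (24 * 1000) [g TAN h-1].

    ``fr_pct`` is the feeding ratio in % body mass day-1.
    """
    if fr_pct < 0 or W < 0 or n_fish < 0:
        raise ValueError("nitrification_rate requires non-negative inputs")
    p = params or NitrificationParams()
    return p.tan_fraction * fr_pct * W * n_fish / (24.0 * 1000.0)


def do_nitrification(
    T: float,
    fr_pct: float,
    W: float,
    n_fish: float,
    volume: float,
    params: Optional[NitrificationParams] = None,
) -> float:
    """Nitrification demand DO_N = o2_per_tan * K_NR(T) * Nr / V [g O2 m-3 h-1]."""
    if volume <= 0:
        raise ValueError(f"tank volume must be > 0, got {volume}")
    p = params or NitrificationParams()
    return (
        p.o2_per_tan
        * nitrification_coefficient(T, p)
        * nitrification_rate(fr_pct, W, n_fish, p)
        / volume
    )


def do_biofilter(
    biomass_kg: float, volume: float, params: Optional[BiofilterParams] = None
) -> float:
    """Biofilter demand DO_B = demand_factor * BOD5 * biomass / (V*24*1000)."""
    if biomass_kg < 0:
        raise ValueError(f"biomass must be >= 0, got {biomass_kg}")
    if volume <= 0:
        raise ValueError(f"tank volume must be > 0, got {volume}")
    p = params or BiofilterParams()
    return p.demand_factor * p.bod5_excretion * biomass_kg / (volume * 24.0 * 1000.0)


def do_pipe_flow(aeration: Optional[AerationParams] = None) -> float:
    """Pipe-flow aeration DO_PF = PC * f * E * OTR / volume_basis."""
    a = aeration or AerationParams()
    return a.pump_cycle_h * a.pump_frequency_per_h * a.efficiency * a.otr / a.volume_basis


def supplemental_demand(do_fr: float, do_n: float, do_b: float, do_pf: float) -> float:
    """Oxygen the generator must add: DO_sup = DO_FR + DO_N + DO_B - DO_PF.

    May be negative when aeration exceeds demand; returned as-is (the
    :class:`OxygenBudget` carries an ``aeration_exceeds_demand`` flag).
    """
    for name, v in (("do_fr", do_fr), ("do_n", do_n), ("do_b", do_b), ("do_pf", do_pf)):
        if v < 0:
            raise ValueError(f"flux component {name} must be >= 0, got {v}")
    return do_fr + do_n + do_b - do_pf


@dataclass(frozen=True)
class OxygenBudget:
    """The four flux terms and the closing supplemental demand at one
    instant, with an echo of the state that produced them."""

    do_fr: float
    do_n: float
    do_b: float
    do_pf: float
    do_sup: float
    temperature_c: float
    weight_g: float
    stocking_density: float
    biomass_kg: float
    volume_m3: float

    @property
    def total_consumption(self) -> float:
        """DO_FR + DO_N + DO_B [g O2 m-3 h-1]."""
        return self.do_fr + self.do_n + self.do_b

    @property
    def aeration_exceeds_demand(self) -> bool:
        return self.do_sup < 0


def compute_budget(T: float, W: float, params: ParameterBundle) -> OxygenBudget:
    """Assemble the full oxygen budget for one hour at temperature ``T``
    and individual weight ``W`` under the bundle's tank and preset
    settings (feeding ratio from the growth side's feeding model)."""
    from .growth import feeding_ratio  # local import avoids a cycle

    tank = params.tank
    sd = tank.stocking_density(W)
    biomass = tank.biomass_kg(W)
    fr_pct = feeding_ratio(W, params.feeding)
    fr = do_fish_respiration(T, W, sd, params.respiration)
    n = do_nitrification(T, fr_pct, W, tank.n_fish, tank.volume, params.nitrification)
    b = do_biofilter(biomass, tank.volume, params.biofilter)
    pf = do_pipe_flow(params.aeration)
    sup = supplemental_demand(fr, n, b, pf)
    return OxygenBudget(
        do_fr=fr,
        do_n=n,
        do_b=b,
        do_pf=pf,
        do_sup=sup,
        temperature_c=T,
        weight_g=W,
        stocking_density=sd,
        biomass_kg=biomass,
        volume_m3=tank.volume,
    )


def do_step(
    do_prev: float,
    budget: OxygenBudget,
    dt: float = 1.0,
    mode: str = "physical",
    supplied: Optional[float] = None,
) -> float:
    """Advance the tank DO concentration by one time step [g m-3].

    ``mode='as_printed'`` integrates the unmet-demand rate
    (DO_FR + DO_B + DO_N - DO_PF) verbatim, under which the traced
    quantity *rises* with consumption -- it is the accumulated unmet
    demand, not a concentration.  ``mode='physical'`` integrates
    DO_PF + supplied - (DO_FR + DO_B + DO_N); ``supplied`` defaults to
    the budget's own DO_sup (a steady controller meeting demand exactly,
    net rate zero).  Results are floored at 0 with a warning.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if do_prev < 0:
        raise ValueError(f"do_prev must be >= 0, got {do_prev}")
    demand = budget.do_fr + budget.do_b + budget.do_n
    if mode == "as_printed":
        rate = demand - budget.do_pf
    elif mode == "physical":
        if supplied is None:
            supplied = budget.do_sup
        rate = budget.do_pf + supplied - demand
    else:
        raise ValueError(f"unknown do_step mode: {mode!r}")
    out = do_prev + rate * dt
    if out < 0:
        warnings.warn(
            f"DO update went negative ({out:.4f} g m-3); floored at 0",
            DOFloorWarning,
            stacklevel=2,
        )
        out = 0.0
    return out


def oxygen_consumption_from_sensors(
    do_in: float, do_out: float, flow: float, biomass_kg: float
) -> float:
    """Oxygen consumption from an inlet/outlet DO pair:
    OC = (DO_in - DO_out) * Q / biomass * 1000 [mg O2 kg-1 fish h-1].

    A negative result (outlet above inlet) is returned as-is with a
    warning -- it signals aeration inside the tank, not a model error.
    """
    if biomass_kg <= 0:
        raise ValueError(f"biomass must be > 0, got {biomass_kg}")
    if flow < 0:
        raise ValueError(f"flow must be >= 0, got {flow}")
    oc = (do_in - do_out) * flow / biomass_kg * 1000.0
    if oc < 0:
        warnings.warn(
            f"negative consumption ({oc:.3f} mg kg-1 h-1): outlet DO exceeds inlet",
            NegativeConsumptionWarning,
            stacklevel=2,
        )
    return oc
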