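"""Daily bioenergetic growth model for tank-reared Nile tilapia.

The growth rate of an individual fish is anabolism minus catabolism,

    FGR = a * tau * kappa * delta * phi * h * f * W**m  -  K(T) * W**n   [g day-1]

where the four dimensionless factors throttle food intake: tau
(temperature, bell-shaped around the optimum), kappa (photoperiod /
12 h), delta (dissolved oxygen, piecewise linear between a minimum and a
critical level) and phi (unionized ammonia, the mirror image).  The
catabolism coefficient K rises exponentially with temperature from its
fasting value at t_min.

The relative feeding level ``f`` is the model's free parameter; two
calibration routines recover it (optionally jointly with the catabolism
rescale ``k_scale``) from a reference growth schedule or from reference
final weights by temperature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .params import (
    EnvironmentSchedule,
    FeedingParams,
    GrowthParams,
    ParameterBundle,
    ScheduleMode,
    TauLowDenominator,
)

#: Integration halts (with a flag) if weight would drop below this [g],
#: so uncalibrated parameter sets fail loudly instead of going negative.
WEIGHT_FLOOR_G = 0.1


def temperature_factor(T: float, params: Optional[GrowthParams] = None) -> float:
    """Feed-intake temperature factor tau in [0, 1], equal to 1 at t_opt.

    exp(-4.6 * ((t_opt - T) / (t_opt - D))**4) below the optimum, with D
    chosen by ``tau_low_denominator`` (t_min by default); the symmetric
    expression with (t_max - t_opt) above it.
    """
    p = params or GrowthParams()
    if T >= p.t_opt:
        x = (T - p.t_opt) / (p.t_max - p.t_opt)
    else:
        denom = (
            p.t_opt - p.t_min
            if p.tau_low_denominator is TauLowDenominator.t_min
            else p.t_opt - p.t_max
        )
        x = (p.t_opt - T) / denom
    return math.exp(-4.6 * x**4)


def catabolism_coefficient(T: float, params: Optional[GrowthParams] = None) -> float:
    """K(T) = k_scale * k_min * exp(s * (T - t_min)) [g^(1-n) day-1].

    Below t_min the fasting value is returned with a warning (the
    exponential is an interpolation over the feeding range, not a
    cold-water model).
    """
    p = params or GrowthParams()
    if T < p.t_min:
        warnings.warn(
            f"catabolism evaluated below t_min ({T} < {p.t_min} C); "
            "returning the fasting value",
            UserWarning,
            stacklevel=2,
        )
        return p.k_scale * p.k_min
    return p.k_scale * p.k_min * math.exp(p.s_const * (T - p.t_min))


def do_factor(do_mg_l: float, params: Optional[GrowthParams] = None) -> float:
    """Dissolved-oxygen factor delta: 0 below do_min, 1 above do_crit,
    linear in between (boundary points take the permissive value 1)."""
    if do_mg_l < 0:
        raise ValueError(f"DO must be >= 0, got {do_mg_l}")
    p = params or GrowthParams()
    if do_mg_l >= p.do_crit:
        return 1.0
    if do_mg_l < p.do_min:
        return 0.0
    return (do_mg_l - p.do_min) / (p.do_crit - p.do_min)


def ammonia_factor(nh3_mg_l: float, params: Optional[GrowthParams] = None) -> float:
    """Unionized-ammonia factor phi: 1 below nh3_crit, 0 above nh3_max,
    linearly decreasing in between."""
    if nh3_mg_l < 0:
        raise ValueError(f"NH3 must be >= 0, got {nh3_mg_l}")
    p = params or GrowthParams()
    if nh3_mg_l <= p.nh3_crit:
        return 1.0
    if nh3_mg_l > p.nh3_max:
        return 0.0
    return (p.nh3_max - nh3_mg_l) / (p.nh3_max - p.nh3_crit)


def photoperiod_factor(photoperiod_h: float) -> float:
    """kappa = photoperiod / 12, the daylight fraction of a 12:12 cycle
    (diurnal feeders; can exceed 1 under extended light)."""
    if not 0.0 <= photoperiod_h <= 24.0:
        raise ValueError(f"photoperiod must lie in [0, 24] h, got {photoperiod_h}")
    return photoperiod_h / 12.0


def feeding_ratio(W: float, params: Optional[FeedingParams] = None) -> float:
    """Feeding ratio Fr(W) in % body mass day-1.

    Equation mode evaluates the lognormal bell
    fr_amp * exp(-(ln W + fr_shift)^2 / fr_width); table mode steps
    through the hatchery schedule (band midpoints), clamping to the
    nearest row outside the tabulated weight range.
    """
    if W <= 0:
        raise ValueError(f"weight must be > 0, got {W}")
    p = params or FeedingParams()
    if p.schedule_mode is ScheduleMode.equation:
        return p.fr_amp * math.exp(-((math.log(W) + p.fr_shift) ** 2) / p.fr_width)
    rows = sorted(p.table2_schedule, key=lambda r: r.w_lo)
    for row in rows:
        if row.w_lo <= W < row.w_hi:
            return row.feed_pct_mid
    return rows[0].feed_pct_mid if W < rows[0].w_lo else rows[-1].feed_pct_mid


@dataclass(frozen=True)
class GrowthFactors:
    """The four intake factors and the catabolism coefficient at one state."""

    tau: float
    kappa: float
    delta: float
    phi: float
    K: float


def growth_factors(
    T: float,
    do_mg_l: float,
    nh3_mg_l: float,
    photoperiod_h: float,
    params: Optional[GrowthParams] = None,
) -> GrowthFactors:
    p = params or GrowthParams()
    return GrowthFactors(
        tau=temperature_factor(T, p),
        kappa=photoperiod_factor(photoperiod_h),
        delta=do_factor(do_mg_l, p),
        phi=ammonia_factor(nh3_mg_l, p),
        K=catabolism_coefficient(T, p),
    )


def daily_growth_rate(
    W: float,
    T: float,
    do_mg_l: float,
    nh3_mg_l: float,
    photoperiod_h: float = 12.0,
    params: Optional[GrowthParams] = None,
) -> float:
    """FGR [g day-1] at one state; may be negative (not clamped)."""
    p = params or GrowthParams()
    if p.f_feed is None:
        raise ValueError("relative feeding level f_feed is not set on GrowthParams")
    if W <= 0:
        raise ValueError(f"weight must be > 0, got {W}")
    fac = growth_factors(T, do_mg_l, nh3_mg_l, photoperiod_h, p)
    anabolism = (
        p.anabolism_const
        * fac.tau
        * fac.kappa
        * fac.delta
        * fac.phi
        * p.h_food
        * p.f_feed
        * W**p.m_exp
    )
    return anabolism - fac.K * W**p.n_exp


@dataclass(frozen=True)
class GrowthRecord:
    """One day of the growth trajectory (weight at the start of the day)."""

    day: int
    weight_g: float
    fgr_g_day: float
    feeding_ratio_pct: float
    feed_kg_day: float
    factors: GrowthFactors


@dataclass(frozen=True)
class GrowthTrajectory:
    records: tuple[GrowthRecord, ...]
    halted: bool = False

    def __len__(self) -> int:
        return len(self.records)

    @property
    def final_weight(self) -> float:
        return self.records[-1].weight_g


def daily_feed_mass(fr_pct: float, W: float, n_fish: float) -> float:
    """Feed offered [kg day-1] = Fr * W * N / 100,000 (Fr in % day-1, W in g)."""
    if fr_pct < 0 or W < 0 or n_fish < 0:
        raise ValueError("daily_feed_mass requires non-negative inputs")
    return fr_pct * W * n_fish / 100_000.0


def integrate_growth(
    w0: float,
    days: int,
    env: EnvironmentSchedule,
    growth: GrowthParams,
    feeding: Optional[FeedingParams] = None,
    n_fish: float = 1.0,
) -> GrowthTrajectory:
    """Daily Euler accumulation W_n = W_{n-1} + FGR over the horizon.

    Returns ``days + 1`` records (day 0 carries ``w0``); integration
    halts with ``halted=True`` if weight would fall below the floor.
    """
    if w0 <= 0:
        raise ValueError(f"w0 must be > 0, got {w0}")
    if days < 0:
        raise ValueError(f"days must be >= 0, got {days}")
    env.check_covers(days)
    feeding = feeding or FeedingParams()

    def make_record(day: int, env_day: int, W: float) -> GrowthRecord:
        state = (
            env.temperature_on(env_day),
            env.do_on(env_day),
            env.nh3_on(env_day),
            env.photoperiod_on(env_day),
        )
        fgr = daily_growth_rate(W, *state, params=growth)
        fr = feeding_ratio(W, feeding)
        return GrowthRecord(
            day=day,
            weight_g=W,
            fgr_g_day=fgr,
            feeding_ratio_pct=fr,
            feed_kg_day=daily_feed_mass(fr, W, n_fish),
            factors=growth_factors(*state, params=growth),
        )

    records = []
    W = w0
    halted = False
    for day in range(days + 1):
        # the day-`days` record reports the final weight; its rate and
        # factors reuse the last covered environment day
        env_day = min(day, max(days - 1, 0))
        rec = make_record(day, env_day, W)
        records.append(rec)
        if day == days:
            break
        W = W + rec.fgr_g_day
        if W < WEIGHT_FLOOR_G:
            halted = True
            break
    return GrowthTrajectory(records=tuple(records), halted=halted)


# ---------------------------------------------------------------------------
# Calibration of the relative feeding level
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a grid calibration of the relative feeding level."""

    f_star: float
    k_scale_star: float
    objective: float
    grid: tuple[tuple[float, float], ...] = field(repr=False)


def _factor_product(env_point: tuple[float, float, float, float], p: GrowthParams) -> float:
    T, do, nh3, photo = env_point
    fac = growth_factors(T, do, nh3, photo, p)
    return fac.tau * fac.kappa * fac.delta * fac.phi


def interval_mean_rate_terms(
    reference: Sequence[tuple[float, float, float]],
    env_point: tuple[float, float, float, float],
    params: GrowthParams,
    n_points: int = 25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-interval mean anabolism (at f=1) and catabolism (at k_scale=1)
    terms plus the reference rates; FGR over an interval is then
    f * A - k_scale * B, linear in both calibration knobs."""
    fac = _factor_product(env_point, params)
    T = env_point[0]
    k_unit = params.k_min * math.exp(params.s_const * (T - params.t_min))
    A, B, G = [], [], []
    for w_lo, w_hi, rate in reference:
        grid = np.linspace(w_lo, w_hi, n_points)
        A.append(np.mean(params.anabolism_const * fac * params.h_food * grid**params.m_exp))
        B.append(np.mean(k_unit * grid**params.n_exp))
        G.append(rate)
    return np.asarray(A), np.asarray(B), np.asarray(G)


def default_rate_reference(feeding: Optional[FeedingParams] = None) -> list[tuple[float, float, float]]:
    """(w_lo, w_hi, growth rate) triples from the feeding table rows that
    carry an expected growth rate."""
    feeding = feeding or FeedingParams()
    return [
        (r.w_lo, r.w_hi, r.growth_g_day)
        for r in feeding.table2_schedule
        if r.growth_g_day is not None
    ]


def calibrate_relative_feeding(
    params: ParameterBundle,
    reference: Optional[Sequence[tuple[float, float, float]]] = None,
    env_point: tuple[float, float, float, float] = (28.0, 8.0, 0.0, 12.0),
    refine: bool = False,
    grid_step: float = 0.01,
) -> CalibrationResult:
    """Grid search of the relative feeding level against a growth schedule.

    ``f`` runs over {0, grid_step, ..., 1}; the objective is the sum of
    squared deviations between the model's interval-mean growth rate and
    the reference rate on each interval.  With ``refine=True`` the
    catabolism rescale ``k_scale`` is profiled out per grid point by its
    closed-form least-squares value (clamped to >= 0) -- needed whenever
    no ``f`` alone yields positive growth under the tabulated k_min.
    """
    if reference is None:
        reference = default_rate_reference(params.feeding)
    if len(reference) == 0:
        raise ValueError("calibration reference must be non-empty")
    A, B, G = interval_mean_rate_terms(reference, env_point, params.growth)
    n_grid = int(round(1.0 / grid_step)) + 1
    fs = np.round(np.linspace(0.0, 1.0, n_grid), 10)
    grid = []
    best = None
    for f in fs:
        if refine:
            ks = float(max(0.0, np.dot(B, A * f - G) / np.dot(B, B)))
        else:
            ks = params.growth.k_scale
        obj = float(np.sum((A * f - ks * B - G) ** 2))
        grid.append((float(f), obj))
        if best is None or obj < best[2]:
            best = (float(f), ks, obj)
    f_star, ks_star, objective = best
    return CalibrationResult(
        f_star=f_star, k_scale_star=ks_star, objective=objective, grid=tuple(grid)
    )


def _final_weight(
    T: float, f: float, ks: float, growth: GrowthParams, days: int, w0: float
) -> float:
    """Fast scalar Euler run with all non-temperature factors at 1."""
    tau = temperature_factor(T, growth)
    K = ks * growth.k_min * math.exp(growth.s_const * (T - growth.t_min))
    a = growth.anabolism_const * tau * growth.h_food * f
    W = w0
    for _ in range(days):
        W += a * W**growth.m_exp - K * W**growth.n_exp
        if W < WEIGHT_FLOOR_G:
            return WEIGHT_FLOOR_G
    return W


def calibrate_to_final_weights(
    params: ParameterBundle,
    reference: Mapping[float, float],
    days: int = 150,
    w0: float = 3.0,
    grid_step: float = 0.01,
) -> CalibrationResult:
    """Joint (f, k_scale) fit to reference final weights by temperature.

    For each grid value of ``f`` the catabolism rescale is optimized by
    bounded scalar minimization of the sum of squared final-weight
    errors over the reference temperatures; the grid argmin is returned.
    This anchors the shipped calibrated preset: grow-out endpoints pin
    down the anabolism/catabolism balance across temperatures, which a
    rate schedule at a single temperature cannot.
    """
    if len(reference) == 0:
        raise ValueError("calibration reference must be non-empty")
    temps = sorted(reference)
    targets = np.array([reference[t] for t in temps])

    def sse(f: float, ks: float) -> float:
        sim = np.array([_final_weight(t, f, ks, params.growth, days, w0) for t in temps])
        return float(np.sum((sim - targets) ** 2))

    n_grid = int(round(1.0 / grid_step)) + 1
    fs = np.round(np.linspace(0.0, 1.0, n_grid), 10)
    grid = []
    best = None
    for f in fs:
        res = minimize_scalar(
            lambda ks: sse(float(f), ks), bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-5},
        )
        obj = float(res.fun)
        grid.append((float(f), obj))
        if best is None or obj < best[2]:
            best = (float(f), float(res.x), obj)
    f_star, ks_star, objective = best
    return CalibrationResult(
        f_star=f_star, k_scale_star=ks_star, objective=objective, grid=tuple(grid)
    )
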