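"""Model constants and run settings for the RAS oxygen/growth simulator.

Every tunable quantity of the coupled dissolved-oxygen mass balance and
bioenergetic growth model lives here, grouped by the process it drives,
with literature defaults, invariant checking (via pydantic) and
round-trippable serialization to JSON/YAML mappings.

Units follow aquaculture convention throughout: oxygen fluxes in
g O2 m-3 h-1 (note mg L-1 == g m-3), weights in g per individual fish,
biomass in kg, stocking density in kg m-3, temperature in degrees C.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _StrictBase(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SdMode(str, Enum):
    """How stocking density enters the respiration flux.

    ``dynamic`` computes SD = N * W / V from the live biomass each day;
    ``fixed`` holds SD at :attr:`TankSpec.sd_fixed`, the preset used to
    reproduce the published volumetric respiration series.
    """

    dynamic = "dynamic"
    fixed = "fixed"


class ScheduleMode(str, Enum):
    """Feeding ratio source: the lognormal-bell equation or the stepped
    hatchery feeding table."""

    equation = "equation"
    table2 = "table2"


class TauLowDenominator(str, Enum):
    """Normalization of the temperature factor below the optimum.

    ``t_min`` uses (T_opt - T_min), the standard symmetric form;
    ``t_max`` uses (T_opt - T_max) as some sources print it.  Both are
    selectable; the difference only matters below T_opt.
    """

    t_min = "t_min"
    t_max = "t_max"


class RespirationParams(_StrictBase):
    """Quadratic response surface for mass-specific fish respiration.

    FR(T, W) = c0 + c1*W + c2*T + c3*W^2 + c4*T^2 + c5*W*T, in
    mg O2 kg-1 fish h-1.  The regression behind the defaults was built
    from 20-200 g fish at 24-32 C; use outside that window only warns,
    since grow-out runs legitimately start at ~3 g.
    """

    coefficients: tuple[float, float, float, float, float, float] = (
        2014.45,
        2.75,
        -165.2,
        0.007,
        3.93,
        -0.21,
    )
    valid_weight_range: tuple[float, float] = (20.0, 200.0)
    valid_temp_range: tuple[float, float] = (24.0, 32.0)

    @model_validator(mode="after")
    def _ranges_nonempty(self) -> "RespirationParams":
        if not self.valid_weight_range[0] < self.valid_weight_range[1]:
            raise ValueError("valid_weight_range must be a non-empty interval")
        if not self.valid_temp_range[0] < self.valid_temp_range[1]:
            raise ValueError("valid_temp_range must be a non-empty interval")
        return self


class NitrificationParams(_StrictBase):
    """Oxygen demand of nitrifying TAN: DO_N = o2_per_tan * K_NR * Nr / V
    with the Arrhenius-style coefficient K_NR = k_base * theta**(T - t_ref)
    and TAN production Nr = tan_fraction * Fr * W * N / (24*1000)."""

    o2_per_tan: float = Field(4.57, gt=0, description="g O2 per g TAN nitrified")
    k_base: float = Field(0.1, gt=0)
    theta: float = Field(1.08, gt=1)
    t_ref: float = 20.0
    tan_fraction: float = Field(0.03, gt=0, description="fraction of feed excreted as TAN")


class BiofilterParams(_StrictBase):
    """Heterotrophic oxygen demand of the biofilter, approximated as a
    multiple of the fish BOD5 excretion rate."""

    bod5_excretion: float = Field(2160.0, gt=0, description="mg O2 kg-1 fish day-1")
    demand_factor: float = Field(2.3, gt=0, description="biofilter demand / BOD5 production")


class AerationParams(_StrictBase):
    """Oxygen added by the water-pumping cycle.

    DO_PF = pump_cycle_h * pump_frequency_per_h * efficiency * otr / volume_basis.
    ``volume_basis`` defaults to 1 m3 (per-cubic-metre transfer), the
    convention under which the published supplemental-demand subtractions
    close exactly; set it to the tank volume for a physically scaled run.
    """

    pump_cycle_h: float = Field(1.0, gt=0)
    pump_frequency_per_h: float = Field(1.0, gt=0)
    efficiency: float = Field(0.5, ge=0, le=1)
    otr: float = Field(36.8, gt=0, description="g O2 h-1")
    volume_basis: float = Field(1.0, gt=0, description="m3 divisor in the pipe-flow flux")


class GrowthParams(_StrictBase):
    """Bioenergetic growth-rate parameters.

    FGR = anabolism_const * tau * kappa * delta * phi * h_food * f_feed * W**m_exp
          - K * W**n_exp            [g day-1]
    with K = k_scale * k_min * exp(s_const * (T - t_min)).

    ``k_scale`` rescales the fasting-catabolism coefficient without
    editing the literature value of ``k_min``: with the defaults as
    tabulated the catabolism term exceeds anabolism for all W above
    ~0.2 g at any f_feed <= 1, so growth is non-positive; calibration
    resolves this explicitly through k_scale (see the calibration
    routines) instead of silently changing k_min.

    ``c_unused`` (0.236) is carried from the source parameter table for
    completeness; it is referenced by no equation here (numerically it is
    close to anabolism_const * h_food).
    """

    anabolism_const: float = Field(0.2919, gt=0)
    h_food: float = Field(0.81, gt=0, description="food consumption coefficient, g^(1-m) day-1")
    m_exp: float = Field(0.67, gt=0)
    n_exp: float = Field(0.81, gt=0)
    k_min: float = Field(0.25, gt=0, description="fasting catabolism at t_min, g^(1-n) day-1")
    s_const: float = Field(0.015, gt=0, description="per degree C")
    t_min: float = 15.0
    t_max: float = 40.0
    t_opt: float = 28.0
    do_crit: float = Field(5.0, gt=0, description="mg L-1; DO above this has no feeding effect")
    do_min: float = Field(3.0, gt=0, description="mg L-1; feeding stops below this")
    nh3_max: float = Field(0.6, gt=0, description="mg L-1; feeding stops above this")
    nh3_crit: float = Field(0.025, gt=0, description="mg L-1; no effect below this")
    f_feed: Optional[float] = Field(None, description="relative feeding level in [0, 1]")
    k_scale: float = Field(1.0, ge=0, description="calibration rescale of k_min")
    tau_low_denominator: TauLowDenominator = TauLowDenominator.t_min
    c_unused: float = 0.236

    @model_validator(mode="after")
    def _orderings(self) -> "GrowthParams":
        if not self.t_min < self.t_opt < self.t_max:
            raise ValueError(
                f"temperature ordering violated: require t_min ({self.t_min}) < "
                f"t_opt ({self.t_opt}) < t_max ({self.t_max})"
            )
        if not self.do_min < self.do_crit:
            raise ValueError(
                f"oxygen thresholds violated: require do_min ({self.do_min}) < "
                f"do_crit ({self.do_crit})"
            )
        if not self.nh3_crit < self.nh3_max:
            raise ValueError(
                f"ammonia thresholds violated: require nh3_crit ({self.nh3_crit}) < "
                f"nh3_max ({self.nh3_max})"
            )
        if self.f_feed is not None and not 0.0 <= self.f_feed <= 1.0:
            raise ValueError(f"f_feed must lie in [0, 1], got {self.f_feed}")
        return self


class FeedingTableRow(_StrictBase):
    """One step of the hatchery feeding schedule: a weight interval [g],
    the recommended feeding rate band [% body mass day-1] and, where
    tabulated, the expected growth rate over that interval."""

    w_lo: float = Field(ge=0)
    w_hi: float = Field(gt=0)
    growth_g_day: Optional[float] = None
    feed_pct_lo: float = Field(gt=0)
    feed_pct_hi: float = Field(gt=0)

    @property
    def feed_pct_mid(self) -> float:
        """Midpoint of the recommended feeding-rate band (the value used
        in ``table2`` schedule mode; the raw band is retained)."""
        return 0.5 * (self.feed_pct_lo + self.feed_pct_hi)


#: Stepped feeding schedule for tank-reared Nile tilapia at 28 C, with the
#: growth rates expected on each weight interval where the source gives a
#: growth period (rate ~= interval width / period).
DEFAULT_FEEDING_TABLE: tuple[dict, ...] = (
    dict(w_lo=0.02, w_hi=0.5, growth_g_day=None, feed_pct_lo=15.0, feed_pct_hi=20.0),
    dict(w_lo=0.5, w_hi=5.0, growth_g_day=None, feed_pct_lo=10.0, feed_pct_hi=15.0),
    dict(w_lo=5.0, w_hi=20.0, growth_g_day=0.5, feed_pct_lo=7.0, feed_pct_hi=10.0),
    dict(w_lo=20.0, w_hi=50.0, growth_g_day=1.0, feed_pct_lo=4.0, feed_pct_hi=7.0),
    dict(w_lo=50.0, w_hi=100.0, growth_g_day=1.5, feed_pct_lo=3.5, feed_pct_hi=4.0),
    dict(w_lo=100.0, w_hi=250.0, growth_g_day=2.5, feed_pct_lo=1.5, feed_pct_hi=3.5),
    dict(w_lo=250.0, w_hi=450.0, growth_g_day=3.0, feed_pct_lo=1.0, feed_pct_hi=1.5),
)


class FeedingParams(_StrictBase):
    """Feeding-ratio model: Fr(W) = fr_amp * exp(-(ln W + fr_shift)^2 / fr_width)
    in % body mass day-1, or the stepped table in ``table2`` mode."""

    fr_amp: float = Field(17.02, gt=0)
    fr_shift: float = 1.14
    fr_width: float = Field(19.52, gt=0)
    schedule_mode: ScheduleMode = ScheduleMode.equation
    table2_schedule: tuple[FeedingTableRow, ...] = tuple(
        FeedingTableRow(**row) for row in DEFAULT_FEEDING_TABLE
    )

    @model_validator(mode="after")
    def _table_tiles(self) -> "FeedingParams":
        rows = sorted(self.table2_schedule, key=lambda r: r.w_lo)
        for r in rows:
            if not r.w_lo < r.w_hi:
                raise ValueError(f"feeding table interval empty: [{r.w_lo}, {r.w_hi}]")
        for a, b in zip(rows, rows[1:]):
            if b.w_lo < a.w_hi - 1e-12:
                raise ValueError(
                    f"feeding table intervals overlap: [{a.w_lo}, {a.w_hi}] and "
                    f"[{b.w_lo}, {b.w_hi}]"
                )
        if rows and (rows[0].w_lo > 0.02 + 1e-12 or rows[-1].w_hi < 450.0 - 1e-12):
            raise ValueError("feeding table must cover 0.02-450 g")
        return self


class TankSpec(_StrictBase):
    """Culture-tank geometry and stocking."""

    volume: float = Field(150.0, gt=0, description="m3 water volume")
    n_fish: int = Field(20000, gt=0)
    w0: float = Field(3.0, gt=0, description="initial individual weight, g")
    flow_rate: float = Field(30.0, gt=0, description="m3 h-1 recirculation flow")
    sd_mode: SdMode = SdMode.dynamic
    sd_fixed: float = Field(100.0, gt=0, description="kg m-3, used when sd_mode=fixed")

    def stocking_density(self, weight_g: float) -> float:
        """Stocking density [kg m-3] at the given individual weight."""
        if self.sd_mode is SdMode.fixed:
            return self.sd_fixed
        return self.n_fish * weight_g / 1000.0 / self.volume

    def biomass_kg(self, weight_g: float) -> float:
        return self.n_fish * weight_g / 1000.0


Series = Union[float, tuple[float, ...]]


def _value_on(series: Series, day: int) -> float:
    if isinstance(series, (int, float)):
        return float(series)
    return float(series[day])


class EnvironmentSchedule(_StrictBase):
    """Per-day environment driving the growth factors.

    Each of temperature, ambient DO and unionized ammonia may be a scalar
    (held constant) or a per-day sequence that must cover the simulated
    horizon.  Photoperiod defaults to a 12:12 light-dark cycle.
    """

    temperature: Series = 28.0
    do_ambient: Series = 6.0
    nh3: Series = 0.01
    photoperiod_h: Series = 12.0

    @model_validator(mode="after")
    def _photoperiod_range(self) -> "EnvironmentSchedule":
        vals = (
            (self.photoperiod_h,)
            if isinstance(self.photoperiod_h, (int, float))
            else self.photoperiod_h
        )
        for v in vals:
            if not 0.0 <= v <= 24.0:
                raise ValueError(f"photoperiod_h must lie in [0, 24], got {v}")
        return self

    def temperature_on(self, day: int) -> float:
        return _value_on(self.temperature, day)

    def do_on(self, day: int) -> float:
        return _value_on(self.do_ambient, day)

    def nh3_on(self, day: int) -> float:
        return _value_on(self.nh3, day)

    def photoperiod_on(self, day: int) -> float:
        return _value_on(self.photoperiod_h, day)

    def check_covers(self, days: int) -> None:
        """Raise if any per-day series is shorter than the horizon."""
        for name in ("temperature", "do_ambient", "nh3", "photoperiod_h"):
            series = getattr(self, name)
            if not isinstance(series, (int, float)) and len(series) < days:
                raise ValueError(
                    f"environment series '{name}' covers {len(series)} days "
                    f"but the horizon is {days} days"
                )


class ParameterBundle(_StrictBase):
    """The complete run configuration: one sub-model per process."""

    respiration: RespirationParams = RespirationParams()
    nitrification: NitrificationParams = NitrificationParams()
    biofilter: BiofilterParams = BiofilterParams()
    aeration: AerationParams = AerationParams()
    growth: GrowthParams = GrowthParams()
    feeding: FeedingParams = FeedingParams()
    tank: TankSpec = TankSpec()
    environment: EnvironmentSchedule = EnvironmentSchedule()
    preset: str = "default"

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def param_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_parameters() -> ParameterBundle:
    """The literature default configuration (all tabulated constants)."""
    return ParameterBundle()


def load_config(source: Union[str, Path, Mapping[str, Any]]) -> ParameterBundle:
    """Build a validated :class:`ParameterBundle` from a mapping or a
    JSON/YAML file.  Unspecified fields take the documented defaults;
    any invariant violation raises with the offending field named.
    """
    if isinstance(source, Mapping):
        data: Mapping[str, Any] = source
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"configuration file not found: {path}")
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"configuration root must be a mapping, got {type(data).__name__}")
    return ParameterBundle.model_validate(data)


def serialize(bundle: ParameterBundle, path: Optional[Union[str, Path]] = None) -> dict:
    """Dump a bundle to a plain mapping; optionally also write it to a
    JSON or YAML file (chosen by extension).  ``load_config`` of the
    result reproduces the bundle field-for-field."""
    data = bundle.to_dict()
    if path is not None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data))
    return data
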