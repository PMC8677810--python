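"""Model-vs-measurement parity validation.

For each compared quantity the predicted series is regressed on the
measured one (ordinary least squares, predicted as the response, the
form parity studies print as P = a*M + b), together with the coefficient
of determination of that fit and the mean absolute relative error in
percent.  Four quantities mirror the structure of a RAS validation
campaign: mass-specific respiration from inlet/outlet sensors, biofilter
demand, total volumetric consumption, and individual fish weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import oxygen
from .growth import feeding_ratio
from .params import ParameterBundle
from .simulate import Trajectory
from .synthetic import SENSOR_COLUMNS, WEIGHING_COLUMNS


@dataclass(frozen=True)
class ParityFit:
    """OLS parity fit of predicted on measured."""

    slope: float
    intercept: float
    r_squared: float
    mean_abs_rel_error_pct: float
    n_points: int
    slope_stderr: float
    pred_range: tuple[float, float]
    meas_range: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "mare_pct": self.mean_abs_rel_error_pct,
            "n": self.n_points,
            "slope_stderr": self.slope_stderr,
            "pred_range": list(self.pred_range),
            "meas_range": list(self.meas_range),
        }


def align_series(
    t_model: Sequence[float],
    v_model: Sequence[float],
    t_meas: Sequence[float],
    v_meas: Sequence[float],
    tol: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Nearest-time pairing of a model series with a measured one.

    Each measured point is matched to the nearest model time within
    ``tol``; unmatched measured points are dropped (their count is
    returned).  Raises when the time ranges do not overlap.
    """
    t_model = np.asarray(t_model, dtype=float)
    v_model = np.asarray(v_model, dtype=float)
    t_meas = np.asarray(t_meas, dtype=float)
    v_meas = np.asarray(v_meas, dtype=float)
    if len(t_model) == 0 or len(t_meas) == 0:
        raise ValueError("cannot align empty series")
    if t_meas.min() > t_model.max() or t_meas.max() < t_model.min():
        raise ValueError(
            f"model times [{t_model.min()}, {t_model.max()}] and measured times "
            f"[{t_meas.min()}, {t_meas.max()}] do not overlap"
        )
    order = np.argsort(t_model)
    t_sorted, v_sorted = t_model[order], v_model[order]
    idx = np.searchsorted(t_sorted, t_meas)
    pred, meas, dropped = [], [], 0
    for i, (tm, vm) in enumerate(zip(t_meas, v_meas)):
        cands = [j for j in (idx[i] - 1, idx[i]) if 0 <= j < len(t_sorted)]
        j = min(cands, key=lambda j: abs(t_sorted[j] - tm))
        if abs(t_sorted[j] - tm) <= tol:
            pred.append(v_sorted[j])
            meas.append(vm)
        else:
            dropped += 1
    if not pred:
        raise ValueError("no measured point lies within tolerance of the model grid")
    return np.asarray(pred), np.asarray(meas), dropped


def linear_parity_fit(predicted: Sequence[float], measured: Sequence[float]) -> ParityFit:
    """OLS of predicted on measured plus R^2 and mean |rel. error| in %."""
    pred = np.asarray(predicted, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if len(pred) != len(meas):
        raise ValueError("predicted and measured series differ in length")
    if len(pred) < 2:
        raise ValueError("parity fit needs at least 2 pairs")
    if np.allclose(meas, meas[0]):
        raise ValueError("measured series is degenerate (all values equal)")
    res = stats.linregress(meas, pred)
    nonzero = meas != 0
    mare = float(np.mean(np.abs(pred[nonzero] - meas[nonzero]) / np.abs(meas[nonzero])) * 100.0)
    return ParityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        mean_abs_rel_error_pct=mare,
        n_points=len(pred),
        slope_stderr=float(res.stderr),
        pred_range=(float(pred.min()), float(pred.max())),
        meas_range=(float(meas.min()), float(meas.max())),
    )


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {', '.join(missing)}")


def validation_report(
    trajectory: Trajectory,
    sensor_log: pd.DataFrame,
    weighing_log: pd.DataFrame,
    params: Optional[ParameterBundle] = None,
    frequency: str = "daily",
) -> dict:
    """Parity fits for respiration, biofilter, total consumption and
    fish weight, plus the ranges of each series.

    The respiration comparison inverts the inlet/outlet formula per log
    row and (by default) averages to daily means before pairing with the
    model's mass-specific rate.  Biofilter and total-consumption
    comparisons are evaluated at weighing days, building the measured
    side from measured weights so weighing noise propagates into them.
    Volumetric conversions use dynamic density biomass/V on both sides.
    """
    params = params or trajectory.params
    _require_columns(sensor_log, SENSOR_COLUMNS, "sensor log")
    _require_columns(weighing_log, WEIGHING_COLUMNS, "weighing log")
    if frequency not in ("daily", "hourly"):
        raise ValueError(f"frequency must be 'daily' or 'hourly', got {frequency!r}")

    tank = params.tank
    env = params.environment
    horizon_days = trajectory.daily[-1].day

    # --- measured mass-specific respiration from the sensors ------------
    # noisy logs legitimately produce occasional negative row differences;
    # they carry information for the fit, so the per-row warning is muted
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", oxygen.NegativeConsumptionWarning)
        oc_meas_rows = np.array(
            [
                oxygen.oxygen_consumption_from_sensors(
                    r.do_in_mg_l, r.do_out_mg_l, r.flow_m3_h, r.biomass_kg
                )
                for r in sensor_log.itertuples()
            ]
        )
    t_meas_h = sensor_log["timestamp_h"].to_numpy(dtype=float)

    # model mass-specific respiration per hour
    t_model_h = np.array([h.time_h for h in trajectory.hourly])
    oc_model_rows = np.array(
        [
            h.budget.do_fr / h.budget.stocking_density * 1000.0
            if h.budget.stocking_density > 0
            else 0.0
            for h in trajectory.hourly
        ]
    )

    if frequency == "daily":
        meas_day = (np.ceil(t_meas_h / 24.0) - 1).astype(int)
        model_day = (np.ceil(t_model_h / 24.0) - 1).astype(int)
        oc_meas_t, oc_meas_v = _daily_means(meas_day, oc_meas_rows)
        oc_model_t, oc_model_v = _daily_means(model_day, oc_model_rows)
        pred_oc, meas_oc, dropped_oc = align_series(
            oc_model_t, oc_model_v, oc_meas_t, oc_meas_v, tol=0.5
        )
    else:
        pred_oc, meas_oc, dropped_oc = align_series(
            t_model_h, oc_model_rows, t_meas_h, oc_meas_rows, tol=0.5
        )

    # --- weight, biofilter and total at weighing days --------------------
    model_days = np.array([r.day for r in trajectory.daily], dtype=float)
    model_w = np.array([r.weight_g for r in trajectory.daily])
    w_days = weighing_log["day"].to_numpy(dtype=float)
    w_meas = weighing_log["weight_g"].to_numpy(dtype=float)
    pred_w, meas_w, dropped_w = align_series(model_days, model_w, w_days, w_meas, tol=1.0)

    def volumetric_terms(day: float, w_g: float, oc_mass: float) -> tuple[float, float, float]:
        """(respiration, nitrification, biofilter) in g O2 m-3 h-1 for a
        weight and mass-specific respiration at the given day."""
        biomass = tank.n_fish * w_g / 1000.0
        sd = biomass / tank.volume
        resp = oc_mass * sd / 1000.0
        T = env.temperature_on(int(min(day, horizon_days - 1)))
        nitr = oxygen.do_nitrification(
            T, feeding_ratio(w_g, params.feeding), w_g, tank.n_fish, tank.volume,
            params.nitrification,
        )
        biof = oxygen.do_biofilter(biomass, tank.volume, params.biofilter)
        return resp, nitr, biof

    # daily-mean measured OC interpolated at weighing days
    if frequency == "daily":
        oc_meas_at = np.interp(w_days, oc_meas_t, oc_meas_v)
        oc_model_at = np.interp(w_days, oc_model_t, oc_model_v)
    else:
        oc_meas_at = np.interp(w_days, t_meas_h / 24.0, oc_meas_rows)
        oc_model_at = np.interp(w_days, t_model_h / 24.0, oc_model_rows)

    biof_pred, biof_meas, tot_pred, tot_meas = [], [], [], []
    for day, wp, wm, ocp, ocm in zip(w_days, pred_w, meas_w, oc_model_at, oc_meas_at):
        rp, np_, bp = volumetric_terms(day, wp, ocp)
        rm, nm, bm = volumetric_terms(day, wm, ocm)
        biof_pred.append(bp)
        biof_meas.append(bm)
        tot_pred.append(rp + np_ + bp)
        tot_meas.append(rm + nm + bm)

    report = {
        "respiration": linear_parity_fit(pred_oc, meas_oc).as_dict(),
        "biofilter": linear_parity_fit(biof_pred, biof_meas).as_dict(),
        "total": linear_parity_fit(tot_pred, tot_meas).as_dict(),
        "fish_weight": linear_parity_fit(pred_w, meas_w).as_dict(),
        "coverage": {
            "horizon_days": int(horizon_days),
            "weighing_last_day": float(w_days.max()),
            "weighing_truncated": bool(w_days.max() < horizon_days),
            "dropped_sensor_points": int(dropped_oc),
            "dropped_weighings": int(dropped_w),
        },
        "error_metric": "mean absolute relative error, percent",
    }
    report["respiration"]["units"] = "mg O2 kg-1 fish h-1"
    for key in ("biofilter", "total"):
        report[key]["units"] = "g O2 m-3 h-1"
    report["fish_weight"]["units"] = "g"
    return report


def _daily_means(day_index: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    days = np.unique(day_index)
    means = np.array([values[day_index == d].mean() for d in days])
    return days.astype(float), means
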