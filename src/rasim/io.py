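"""CSV/JSON readers and writers plus run provenance.

All outputs are plain text for inspectability: fluxes at 4 decimal
places, weights at 2.  Every run directory carries a ``manifest.json``
with the command, the full configuration, its hash, the seed and any
warnings emitted, so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .params import ParameterBundle, load_config
from .simulate import RunSummary, Trajectory
from .synthetic import SENSOR_COLUMNS, WEIGHING_COLUMNS

GROWTH_COLUMNS = [
    "day", "weight_g", "fgr_g_day", "feeding_ratio_pct", "feed_kg_day",
    "tau", "kappa", "delta", "phi",
]
HOURLY_COLUMNS = [
    "time_h", "do_fr", "do_n", "do_b", "do_pf", "do_sup", "do_mg_l",
    "weight_g", "biomass_kg", "temperature_c",
]
REFERENCE_COLUMNS = ["w_lo_g", "w_hi_g", "growth_g_day", "feed_pct_lo", "feed_pct_hi"]


def _read_csv_checked(path: Union[str, Path], columns: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} {path} is missing required column(s): {', '.join(missing)}")
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + 2  # 1-based, counting the header line
            raise ValueError(
                f"{what} {path}: non-numeric value {df.loc[bad[0], col]!r} "
                f"in column '{col}' at line {row}"
            )
        df[col] = coerced
    if df.empty:
        import warnings

        warnings.warn(f"{what} {path} contains a header but no rows", UserWarning)
    return df


def read_sensor_log(path: Union[str, Path]) -> pd.DataFrame:
    return _read_csv_checked(path, SENSOR_COLUMNS, "sensor log")


def read_weighing_log(path: Union[str, Path]) -> pd.DataFrame:
    return _read_csv_checked(path, WEIGHING_COLUMNS, "weighing log")


def read_reference_schedule(path: Union[str, Path]) -> list[tuple[float, float, float]]:
    """Growth-reference CSV (w_lo_g, w_hi_g, growth_g_day, feed bands) ->
    (w_lo, w_hi, rate) triples for calibration."""
    df = _read_csv_checked(path, REFERENCE_COLUMNS, "reference schedule")
    return [
        (float(r.w_lo_g), float(r.w_hi_g), float(r.growth_g_day))
        for r in df.itertuples()
        if pd.notna(r.growth_g_day)
    ]


def write_sensor_log(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def write_weighing_log(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def write_trajectory(trajectory: Trajectory, out_dir: Union[str, Path],
                     summary: Optional[RunSummary] = None) -> list[Path]:
    """Write growth.csv, oxygen_hourly.csv and summary.json; returns the
    file list (for the manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    growth_path = out / "growth.csv"
    df = trajectory.daily_frame()
    df["weight_g"] = df["weight_g"].round(2)
    df.to_csv(growth_path, index=False, float_format="%.4f")
    files.append(growth_path)
    hourly_path = out / "oxygen_hourly.csv"
    trajectory.hourly_frame().to_csv(hourly_path, index=False, float_format="%.4f")
    files.append(hourly_path)
    summary_path = out / "summary.json"
    from .simulate import summarize

    if summary is None and trajectory.hourly:
        summary = summarize(trajectory)
    payload = {
        "preset": trajectory.preset,
        "param_hash": trajectory.param_hash,
        "halted": trajectory.halted,
        "do_mode": trajectory.do_mode,
        "final_weight_g": trajectory.final_weight,
        "summary": summary.as_dict() if summary else None,
    }
    summary_path.write_text(json.dumps(payload, indent=2))
    files.append(summary_path)
    return files


def read_trajectory(run_dir: Union[str, Path]) -> Trajectory:
    """Rebuild a :class:`Trajectory` from a run directory written by
    :func:`write_trajectory` plus its manifest (for the configuration)."""
    from .growth import GrowthFactors, GrowthRecord
    from .oxygen import OxygenBudget
    from .simulate import HourlyRecord

    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    params = load_config(manifest["config"])
    growth = pd.read_csv(run_dir / "growth.csv")
    hourly = pd.read_csv(run_dir / "oxygen_hourly.csv")
    summary = json.loads((run_dir / "summary.json").read_text())
    daily = tuple(
        GrowthRecord(
            day=int(r.day),
            weight_g=r.weight_g,
            fgr_g_day=r.fgr_g_day,
            feeding_ratio_pct=r.feeding_ratio_pct,
            feed_kg_day=r.feed_kg_day,
            factors=GrowthFactors(tau=r.tau, kappa=r.kappa, delta=r.delta, phi=r.phi, K=0.0),
        )
        for r in growth.itertuples()
    )
    hourly_records = tuple(
        HourlyRecord(
            time_h=r.time_h,
            budget=OxygenBudget(
                do_fr=r.do_fr, do_n=r.do_n, do_b=r.do_b, do_pf=r.do_pf, do_sup=r.do_sup,
                temperature_c=r.temperature_c, weight_g=r.weight_g,
                stocking_density=params.tank.stocking_density(r.weight_g),
                biomass_kg=r.biomass_kg, volume_m3=params.tank.volume,
            ),
            do_mg_l=r.do_mg_l,
        )
        for r in hourly.itertuples()
    )
    return Trajectory(
        daily=daily,
        hourly=hourly_records,
        params=params,
        halted=bool(summary["halted"]),
        do_mode=summary["do_mode"],
    )


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output set."""

    command: str
    config: dict
    config_hash: str
    preset: str
    seed: Optional[int] = None
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def write(self, out_dir: Union[str, Path]) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        path.write_text(
            json.dumps(
                {
                    "command": self.command,
                    "config": self.config,
                    "config_hash": self.config_hash,
                    "preset": self.preset,
                    "seed": self.seed,
                    "warnings": self.warnings,
                    "outputs": self.outputs,
                },
                indent=2,
            )
        )
        return path


def make_manifest(command: str, params: ParameterBundle,
                  seed: Optional[int] = None) -> RunManifest:
    return RunManifest(
        command=command,
        config=params.to_dict(),
        config_hash=params.param_hash(),
        preset=params.preset,
        seed=seed,
    )
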