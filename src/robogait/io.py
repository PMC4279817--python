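"""Readers and writers for the pipeline's file formats.

All tabular artifacts are RFC-4180 UTF-8 CSV with fixed headers; objects
that carry scalar metadata (trajectory increment, passive-path start angle)
get a JSON sidecar next to the CSV.  Write-read round-trips preserve values
to full float precision (`repr`-exact via pandas' default float formatting at
17 significant digits is not guaranteed, so floats are written with %.17g).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .gait import GaitCurve
from .kinematics import PassivePath, RigidTransform
from .metrics import MetricsResult
from .robot import RobotTrace
from .trajectory import Trajectory

__all__ = [
    "write_gait_curve",
    "read_gait_curve",
    "write_passive_path",
    "read_passive_path",
    "write_trajectory",
    "read_trajectory",
    "write_trace",
    "read_trace",
    "write_metrics",
    "read_metrics",
]

GAIT_COLUMNS = ["gait_pct", "flexion_deg", "f_axial_bw", "f_pa_bw", "f_ml_bw"]
PATH_COLUMNS = (
    ["angle_deg"]
    + [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
    + ["tx_mm", "ty_mm", "tz_mm"]
)
TRAJ_COLUMNS = ["gait_pct", "angle_deg", "velocity_deg_s", "axial_force_bw"]
TRACE_COLUMNS = [
    "time_s",
    "cycle",
    "gait_pct",
    "angle_deg",
    "f_axial_n",
    "f_pa_n",
    "f_ml_n",
]


def _read_csv(path, expected_columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in expected_columns if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: line 1: missing column(s) {', '.join(missing)}"
        )
    bad = df[expected_columns].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.iloc[row].to_numpy().argmax()]
        raise ParseError(f"{path}: line {row + 2}: missing value in column {col}")
    return df


def _write_csv(path, columns: dict) -> None:
    pd.DataFrame(columns).to_csv(Path(path), index=False, float_format="%.17g")


def _sidecar(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_gait_curve(curve: GaitCurve, path) -> None:
    _write_csv(
        path,
        {
            "gait_pct": curve.grid,
            "flexion_deg": curve.flexion,
            "f_axial_bw": curve.f_axial,
            "f_pa_bw": curve.f_pa,
            "f_ml_bw": curve.f_ml,
        },
    )


def read_gait_curve(path) -> GaitCurve:
    df = _read_csv(path, GAIT_COLUMNS)
    return GaitCurve(
        grid=df["gait_pct"].to_numpy(),
        flexion=df["flexion_deg"].to_numpy(),
        f_axial=df["f_axial_bw"].to_numpy(),
        f_pa=df["f_pa_bw"].to_numpy(),
        f_ml=df["f_ml_bw"].to_numpy(),
    )


def write_passive_path(ppath: PassivePath, path) -> None:
    R = np.stack([p.rotation for p in ppath.poses]).reshape(ppath.n, 9)
    t = np.stack([p.translation for p in ppath.poses])
    cols = {"angle_deg": ppath.angles}
    for j, name in enumerate(PATH_COLUMNS[1:10]):
        cols[name] = R[:, j]
    for j, name in enumerate(("tx_mm", "ty_mm", "tz_mm")):
        cols[name] = t[:, j]
    _write_csv(path, cols)
    _sidecar(path).write_text(
        json.dumps(
            {
                "start_angle_deg": ppath.start_angle,
                "increment_deg": ppath.increment,
            }
        )
    )


def read_passive_path(path) -> PassivePath:
    df = _read_csv(path, PATH_COLUMNS)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ParseError(f"{sidecar}: missing passive-path sidecar")
    meta = json.loads(sidecar.read_text())
    R = df[PATH_COLUMNS[1:10]].to_numpy().reshape(-1, 3, 3)
    t = df[["tx_mm", "ty_mm", "tz_mm"]].to_numpy()
    poses = [RigidTransform(R[i], t[i]) for i in range(len(df))]
    return PassivePath(
        start_angle=float(meta["start_angle_deg"]),
        increment=float(meta["increment_deg"]),
        poses=poses,
    )


def write_trajectory(traj: Trajectory, path) -> None:
    _write_csv(
        path,
        {
            "gait_pct": traj.gait_pct,
            "angle_deg": traj.angle,
            "velocity_deg_s": traj.velocity,
            "axial_force_bw": traj.axial_force,
        },
    )
    _sidecar(path).write_text(
        json.dumps({"increment_deg": traj.increment, "v_max_deg_s": traj.v_max})
    )


def read_trajectory(path) -> Trajectory:
    df = _read_csv(path, TRAJ_COLUMNS)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ParseError(f"{sidecar}: missing trajectory sidecar")
    meta = json.loads(sidecar.read_text())
    return Trajectory(
        gait_pct=df["gait_pct"].to_numpy(),
        angle=df["angle_deg"].to_numpy(),
        velocity=df["velocity_deg_s"].to_numpy(),
        axial_force=df["axial_force_bw"].to_numpy(),
        increment=float(meta["increment_deg"]),
        v_max=float(meta["v_max_deg_s"]),
    )


def write_trace(trace: RobotTrace, path) -> None:
    _write_csv(
        path,
        {
            "time_s": trace.time,
            "cycle": trace.cycle,
            "gait_pct": trace.gait_pct,
            "angle_deg": trace.angle,
            "f_axial_n": trace.f_axial,
            "f_pa_n": trace.f_pa,
            "f_ml_n": trace.f_ml,
        },
    )
    _sidecar(path).write_text(
        json.dumps(
            {"sample_dt_s": trace.sample_dt, "cycle_period_s": trace.cycle_period}
        )
    )


def read_trace(path) -> RobotTrace:
    df = _read_csv(path, TRACE_COLUMNS)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ParseError(f"{sidecar}: missing trace sidecar")
    meta = json.loads(sidecar.read_text())
    return RobotTrace(
        time=df["time_s"].to_numpy(),
        cycle=df["cycle"].to_numpy(int),
        gait_pct=df["gait_pct"].to_numpy(),
        angle=df["angle_deg"].to_numpy(),
        f_axial=df["f_axial_n"].to_numpy(),
        f_pa=df["f_pa_n"].to_numpy(),
        f_ml=df["f_ml_n"].to_numpy(),
        sample_dt=float(meta["sample_dt_s"]),
        cycle_period=float(meta["cycle_period_s"]),
    )


def write_metrics(results: dict, path) -> None:
    """Write per-component metrics as JSON: totals plus per-bin curves."""
    payload = {
        comp: {
            "eps_total_bw": r.eps_total,
            "sd_total_bw": r.sd_total,
            "eps_curve": list(r.eps_curve),
            "sd_curve": list(r.sd_curve),
        }
        for comp, r in results.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_metrics(path) -> dict:
    raw = json.loads(Path(path).read_text())
    out = {}
    for comp, r in raw.items():
        out[comp] = MetricsResult(
            eps_curve=np.asarray(r["eps_curve"]),
            eps_total=float(r["eps_total_bw"]),
            sd_curve=np.asarray(r["sd_curve"]),
            sd_total=float(r["sd_total_bw"]),
        )
    return out
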