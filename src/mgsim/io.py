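"""File round-tripping: trajectory and direction-path CSV schemas, planner
configuration JSON, and run manifests.

Schemas (SI units, UTF-8, '.' decimal separator):

* trajectory CSV: ``t,alpha,beta,alpha_rate,beta_rate,alpha_acc,beta_acc``
* direction CSV:  ``t,ux,uy,uz``

Floats are written with Python's shortest round-trip representation, so a
written file re-reads into a bit-identical in-memory structure and a seeded
run rewrites byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinematics import DirectionPath, Trajectory
from .planners import MotionLimits, PlannerConfig

TRAJECTORY_COLUMNS = ["t", "alpha", "beta", "alpha_rate", "beta_rate",
                      "alpha_acc", "beta_acc"]
DIRECTION_COLUMNS = ["t", "ux", "uy", "uz"]


class SchemaError(ValueError):
    """A file does not match the documented CSV schema."""


def _validate_frame(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in columns]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    for c in columns:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = ~np.isfinite(col.to_numpy(dtype=float, na_value=np.nan))
        if bad.any():
            row = int(np.argmax(bad))
            raise SchemaError(
                f"{path}: non-numeric or missing value in column '{c}', "
                f"data row {row}")


def write_trajectory_csv(traj: Trajectory, path) -> None:
    df = pd.DataFrame({
        "t": traj.t, "alpha": traj.alpha, "beta": traj.beta,
        "alpha_rate": traj.alpha_rate, "beta_rate": traj.beta_rate,
        "alpha_acc": traj.alpha_acc, "beta_acc": traj.beta_acc,
    })
    df.to_csv(path, index=False)


def read_trajectory_csv(path) -> Trajectory:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed beyond repair
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    _validate_frame(df, TRAJECTORY_COLUMNS, path)
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError(f"{path}: need at least 2 rows")
    dt = float(t[1] - t[0])
    try:
        return Trajectory(
            t=t, alpha=df["alpha"].to_numpy(float),
            beta=df["beta"].to_numpy(float),
            alpha_rate=df["alpha_rate"].to_numpy(float),
            beta_rate=df["beta_rate"].to_numpy(float),
            alpha_acc=df["alpha_acc"].to_numpy(float),
            beta_acc=df["beta_acc"].to_numpy(float), dt=dt)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_direction_csv(dpath: DirectionPath, path) -> None:
    df = pd.DataFrame({"t": dpath.t, "ux": dpath.directions[:, 0],
                       "uy": dpath.directions[:, 1],
                       "uz": dpath.directions[:, 2]})
    df.to_csv(path, index=False)


def read_direction_csv(path) -> DirectionPath:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    _validate_frame(df, DIRECTION_COLUMNS, path)
    u = df[["ux", "uy", "uz"]].to_numpy(dtype=float)
    try:
        return DirectionPath(t=df["t"].to_numpy(dtype=float), directions=u)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# planner configuration JSON

_CONFIG_FIELDS = {"duration", "dt", "limits", "mode", "target_g", "seed",
                  "compensation"}
_LIMIT_FIELDS = {"rate_max", "acc_max", "jerk_max"}


def planner_config_to_dict(config: PlannerConfig) -> dict:
    d = dataclasses.asdict(config)
    d["limits"] = dataclasses.asdict(config.limits)
    return d


def planner_config_from_dict(d: dict) -> PlannerConfig:
    unknown = set(d) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = dict(d)
    if "limits" in kwargs:
        lim = kwargs["limits"]
        unknown = set(lim) - _LIMIT_FIELDS
        if unknown:
            raise ValueError(f"unknown limits key(s): {sorted(unknown)}")
        kwargs["limits"] = MotionLimits(**lim)
    return PlannerConfig(**kwargs)


def write_planner_config(config: PlannerConfig, path) -> None:
    Path(path).write_text(
        json.dumps(planner_config_to_dict(config), indent=2) + "\n")


def read_planner_config(path) -> PlannerConfig:
    return planner_config_from_dict(json.loads(Path(path).read_text()))


def write_manifest(path, command: str, seed: int, parameters: dict) -> None:
    """Provenance record written next to every simulation output."""
    manifest = {"software": "mgsim", "version": __version__,
                "command": command, "seed": seed, "parameters": parameters}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
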