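"""CSV/YAML readers and writers for the package's tabular artifacts.

All CSV files are comma-separated UTF-8 with a mandatory header row and '.'
decimals.  Readers validate headers exactly so that silently mislabeled
columns cannot flow into an analysis.

Schemas
-------
feeding experiment   group, day, intake, fat[, weight]  (fat may be blank on
                     unmeasured days; it is forward-filled only within a
                     phase when reading with ``fill_fat=True``)
leptin scatter       fat, leptin
trajectory           time, F, L, u
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from .dynamics import Trajectory
from .fitting import FeedingExperiment

__all__ = [
    "read_feeding_csv",
    "write_feeding_csv",
    "read_leptin_csv",
    "write_leptin_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_run_log",
]

_FEEDING_REQUIRED = ["group", "day", "intake"]
_TRAJ_COLUMNS = ["time", "F", "L", "u"]


def _check_header(path: str, actual: list[str], required: list[str],
                  optional: tuple[str, ...] = ()) -> None:
    missing = [c for c in required if c not in actual]
    extra = [c for c in actual if c not in required and c not in optional]
    problems = []
    if missing:
        problems.append(f"missing columns {missing}")
    if extra:
        problems.append(f"unexpected columns {extra}")
    if problems:
        raise ValueError(f"{path}: invalid header {actual}: " + "; ".join(problems))


def read_feeding_csv(path: str | os.PathLike, control_group: str,
                     controlled_window: tuple[float, float],
                     recovery_window: tuple[float, float],
                     fill_fat: bool = True) -> FeedingExperiment:
    """Read a feeding-experiment CSV into a :class:`FeedingExperiment`.

    ``fill_fat`` forward-fills missing fat values within each group and
    phase (never across the controlled/recovery boundary), matching how
    sparsely measured body composition is carried to a daily grid.
    """
    path = str(path)
    df = pd.read_csv(path)
    _check_header(path, list(df.columns), _FEEDING_REQUIRED, optional=("fat", "weight"))
    if fill_fat and "fat" in df.columns:
        c1 = controlled_window[1]
        parts = []
        for g, sub in df.groupby("group", sort=False):
            sub = sub.sort_values("day").copy()
            in_ctrl = sub["day"] <= c1
            sub.loc[in_ctrl, "fat"] = sub.loc[in_ctrl, "fat"].ffill()
            sub.loc[~in_ctrl, "fat"] = sub.loc[~in_ctrl, "fat"].ffill()
            parts.append(sub)
        df = pd.concat(parts, ignore_index=True)
    return FeedingExperiment(data=df, control_group=control_group,
                             controlled_window=controlled_window,
                             recovery_window=recovery_window)


def write_feeding_csv(exp: FeedingExperiment, path: str | os.PathLike) -> None:
    """Write a feeding experiment's data table as CSV."""
    cols = [c for c in ("group", "day", "intake", "fat", "weight") if c in exp.data.columns]
    exp.data[cols].to_csv(path, index=False)


def read_leptin_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a (fat, leptin) population scatter CSV."""
    path = str(path)
    df = pd.read_csv(path)
    _check_header(path, list(df.columns), ["fat", "leptin"])
    return df


def write_leptin_csv(scatter: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a (fat, leptin) population scatter as CSV."""
    scatter[["fat", "leptin"]].to_csv(path, index=False)


def read_trajectory_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a simulated trajectory CSV (columns time, F, L, u)."""
    path = str(path)
    df = pd.read_csv(path)
    _check_header(path, list(df.columns), _TRAJ_COLUMNS)
    return df


def write_trajectory_csv(traj: Trajectory | pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a trajectory (or its frame) as CSV with columns time, F, L, u."""
    frame = traj.to_frame() if isinstance(traj, Trajectory) else traj
    frame[_TRAJ_COLUMNS].to_csv(path, index=False)


def write_run_log(path: str | os.PathLike, command: str, params: dict,
                  seed: int | None = None, **extra) -> None:
    """Record a run's provenance (package version, command, parameters, seed)."""
    from . import __version__

    record = {"package": "adipoint", "version": __version__, "command": command,
              "parameters": params, "seed": seed}
    record.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(record, fh, sort_keys=False)
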