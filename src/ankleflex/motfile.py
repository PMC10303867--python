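"""Readers/writers for gait time series: OpenSim storage (.mot/.sto) and CSV.

The storage dialect is the tab-delimited text format of the musculoskeletal
modelling community: a free-form header terminated by ``endheader``, a line of
channel names starting with ``time``, then the numeric matrix.  Round trips
preserve values to full float precision and channel order.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GaitTrial, TrialLabel

__all__ = [
    "MotionFile",
    "read_motion",
    "write_motion",
    "trial_to_motion",
    "motion_to_trial",
]

# canonical channel names used when exchanging GaitTrial objects
TRIAL_CHANNELS = ("ankle_angle", "grf_z", "com_vel_dev", "ankle_moment")


@dataclass
class MotionFile:
    """A named table of uniformly sampled channels; first column is time."""

    name: str
    columns: list
    data: np.ndarray
    in_degrees: bool = False

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.columns):
            raise ValueError("data width does not match number of columns")
        if not self.columns or self.columns[0] != "time":
            raise ValueError("first column must be 'time'")

    @property
    def time(self) -> np.ndarray:
        return self.data[:, 0]

    def channel(self, name: str) -> np.ndarray:
        try:
            j = self.columns.index(name)
        except ValueError:
            raise KeyError(f"no channel {name!r} (have {self.columns})") from None
        return self.data[:, j]


def read_motion(path) -> MotionFile:
    """Parse a .mot/.sto storage file or a CSV with a ``time`` column."""
    path = Path(path)
    text = path.read_text()
    lower = text[:4096].lower()
    if "endheader" in lower:
        return _read_storage(text, path)
    # CSV dialect
    try:
        df = pd.read_csv(StringIO(text), float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as CSV ({exc})") from exc
    return _from_dataframe(df, path)


def _read_storage(text: str, path: Path) -> MotionFile:
    lines = text.splitlines()
    name = path.stem
    in_degrees = False
    i = 0
    for i, line in enumerate(lines):
        s = line.strip()
        if s.lower() == "endheader":
            break
        if "=" in s:
            key, _, val = s.partition("=")
            if key.strip().lower() == "indegrees":
                in_degrees = val.strip().lower() == "yes"
        elif i == 0 and s:
            name = s
    else:
        raise ValueError(f"{path}: no 'endheader' line")
    body = "\n".join(lines[i + 1 :])
    try:
        df = pd.read_csv(StringIO(body), sep=r"\s+", float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse data block ({exc})") from exc
    mf = _from_dataframe(df, path)
    mf.name = name
    mf.in_degrees = in_degrees
    return mf


def _from_dataframe(df: pd.DataFrame, path: Path) -> MotionFile:
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or non-numeric entries")
    cols = [str(c) for c in df.columns]
    if "time" not in cols:
        raise ValueError(f"{path}: missing 'time' column (have {cols})")
    if cols[0] != "time":
        cols = ["time"] + [c for c in cols if c != "time"]
        df = df[cols]
    return MotionFile(name=path.stem, columns=cols, data=df.to_numpy(dtype=float))


def write_motion(mf: MotionFile, path) -> None:
    """Write a storage file (.mot/.sto) or CSV, chosen by file extension."""
    path = Path(path)
    n_rows, n_cols = mf.data.shape
    fmt = lambda v: format(v, ".17g")  # noqa: E731
    if path.suffix.lower() == ".csv":
        with open(path, "w") as fh:
            fh.write(",".join(mf.columns) + "\n")
            for row in mf.data:
                fh.write(",".join(fmt(v) for v in row) + "\n")
        return
    with open(path, "w") as fh:
        fh.write(f"{mf.name}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={n_rows}\n")
        fh.write(f"nColumns={n_cols}\n")
        fh.write(f"inDegrees={'yes' if mf.in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("\t".join(mf.columns) + "\n")
        for row in mf.data:
            fh.write("\t".join(fmt(v) for v in row) + "\n")


def trial_to_motion(trial: GaitTrial, name: str = "trial") -> MotionFile:
    """Pack a gait trial's channels into a motion file."""
    cols = ["time", "ankle_angle", "grf_z", "com_vel_dev"]
    data = [trial.time, trial.q, trial.fz, trial.dcom]
    if trial.moment is not None:
        cols.append("ankle_moment")
        data.append(trial.moment)
    return MotionFile(name=name, columns=cols, data=np.column_stack(data))


def motion_to_trial(
    mf: MotionFile,
    mass: float,
    height: float,
    label: TrialLabel | None = None,
) -> GaitTrial:
    """Build a gait trial from a motion file's canonical channels."""
    moment = mf.channel("ankle_moment") if "ankle_moment" in mf.columns else None
    dcom = (
        mf.channel("com_vel_dev")
        if "com_vel_dev" in mf.columns
        else np.zeros_like(mf.time)
    )
    return GaitTrial(
        time=mf.time,
        q=mf.channel("ankle_angle"),
        fz=mf.channel("grf_z"),
        dcom=dcom,
        moment=moment,
        mass=mass,
        height=height,
        label=label or TrialLabel(),
    )
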