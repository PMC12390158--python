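"""Readers and writers for the delimited text formats used by the pipeline.

All artifacts are plain text: CSV tables for time series and JSON for
models/manifests, so that every intermediate is auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ActivityLabels, JointAngleSeries, SensorStream
from .errors import EmptyInputError, FormatError

log = logging.getLogger(__name__)

SENSOR_COLUMNS = [
    "time_s",
    "ax_g",
    "ay_g",
    "az_g",
    "gx_dps",
    "gy_dps",
    "gz_dps",
    "mx",
    "my",
    "mz",
]

LABEL_COLUMNS = ["time_s", "activity"]
MARKER_COLUMNS = ["task_id", "start_s", "end_s"]
FLAG_COLUMNS = ["event_time_s", "flag_type"]
JOINT_COLUMNS = ["time_s", "latflex_deg", "flexext_deg", "rot_deg"]


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None


def read_sensor_table(path, sensor_id: str | None = None, rate_hz: float = 20.0) -> SensorStream:
    """Read one sensor's delimited table into a validated stream.

    Rows containing non-finite values are dropped with a logged count.
    """
    path = Path(path)
    df = _read_csv(path)
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[SENSOR_COLUMNS].astype(float)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    finite = np.isfinite(df.to_numpy()).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        log.warning("%s: dropped %d rows with non-finite values", path, dropped)
        df = df[finite]
    if df.empty:
        raise EmptyInputError(f"{path}: no finite data rows")
    return SensorStream(
        sensor_id=sensor_id or path.stem,
        t=df["time_s"].to_numpy(),
        acc=df[["ax_g", "ay_g", "az_g"]].to_numpy(),
        gyr=df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(),
        mag=df[["mx", "my", "mz"]].to_numpy(),
        rate_hz=rate_hz,
    )


def write_sensor_table(stream: SensorStream, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.acc, stream.gyr, stream.mag]),
        columns=SENSOR_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def read_labels(path) -> ActivityLabels:
    path = Path(path)
    df = _read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return ActivityLabels(t=df["time_s"].to_numpy(float), labels=df["activity"].to_numpy(object))


def write_labels(labels: ActivityLabels, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": labels.t, "activity": labels.labels}).to_csv(
        path, index=False, float_format="%.8g"
    )
    return path


def read_markers(path) -> pd.DataFrame:
    """Marker table (task_id, start_s, end_s[, rep_index]) standing in for
    manual task review."""
    path = Path(path)
    df = _read_csv(path)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if "rep_index" not in df.columns:
        df["rep_index"] = np.nan
    return df


def read_flags(path) -> pd.DataFrame:
    path = Path(path)
    df = _read_csv(path)
    missing = [c for c in FLAG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_joint_angles(joint: JointAngleSeries, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(np.column_stack([joint.t, joint.angles]), columns=JOINT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def read_joint_angles(path) -> JointAngleSeries:
    path = Path(path)
    df = _read_csv(path)
    missing = [c for c in JOINT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return JointAngleSeries(
        t=df["time_s"].to_numpy(float),
        angles=df[["latflex_deg", "flexext_deg", "rot_deg"]].to_numpy(float),
    )


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
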