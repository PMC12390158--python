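"""Core data containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import ContractError

#: canonical activity labels (per-second track from the thigh-worn classifier)
ACTIVITIES = ("sitting", "standing", "stepping", "lying", "transport")
UNKNOWN_LABEL = "unknown"

#: joint-angle axis order used throughout: lateral flexion (x),
#: flexion-extension (y, forward positive), axial rotation (z)
ANGLE_AXES = ("latflex", "flexext", "rot")


def _as_2d(a, name: str, n: int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (n, 3):
        raise ContractError(f"{name} must have shape ({n}, 3), got {a.shape}")
    return a


@dataclass
class SensorStream:
    """One sensor's timestamped triaxial accelerometer / gyroscope /
    magnetometer series.

    Units: acceleration in g, angular rate in deg/s, magnetometer in
    normalized units (undisturbed Earth-field magnitude = 1).
    """

    sensor_id: str
    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    mag: np.ndarray
    rate_hz: float = 20.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1:
            raise ContractError("timestamps must be 1-D")
        n = self.t.size
        self.acc = _as_2d(self.acc, "acc", n)
        self.gyr = _as_2d(self.gyr, "gyr", n)
        self.mag = _as_2d(self.mag, "mag", n)
        if self.rate_hz <= 0:
            raise ContractError("nominal rate must be > 0")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ContractError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def acc_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.acc, axis=1)

    def gyr_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.gyr, axis=1)

    def mag_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.mag, axis=1)

    def copy(self) -> "SensorStream":
        return SensorStream(
            sensor_id=self.sensor_id,
            t=self.t.copy(),
            acc=self.acc.copy(),
            gyr=self.gyr.copy(),
            mag=self.mag.copy(),
            rate_hz=self.rate_hz,
        )

    def slice(self, i0: int, i1: int) -> "SensorStream":
        return SensorStream(
            sensor_id=self.sensor_id,
            t=self.t[i0:i1],
            acc=self.acc[i0:i1],
            gyr=self.gyr[i0:i1],
            mag=self.mag[i0:i1],
            rate_hz=self.rate_hz,
        )


@dataclass
class OrientationSeries:
    """Unit-quaternion trajectory of one sensor in the Earth frame."""

    t: np.ndarray
    q: np.ndarray  # (n, 4) scalar-first, sensor -> Earth
    sensor_id: str = ""
    gain: float = float("nan")
    rate_hz: float = 20.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (self.t.size, 4):
            raise ContractError(
                f"quaternion array must have shape ({self.t.size}, 4), got {self.q.shape}"
            )

    def __len__(self) -> int:
        return self.t.size


@dataclass
class JointAngleSeries:
    """Lumbar joint Euler angles in degrees over time.

    ``angles`` columns follow :data:`ANGLE_AXES`: lateral flexion (x),
    flexion-extension (y, forward flexion positive), axial rotation (z).
    """

    t: np.ndarray
    angles: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.angles = _as_2d(self.angles, "angles", self.t.size)

    def __len__(self) -> int:
        return self.t.size

    @property
    def latflex(self) -> np.ndarray:
        return self.angles[:, 0]

    @property
    def flexext(self) -> np.ndarray:
        return self.angles[:, 1]

    @property
    def rot(self) -> np.ndarray:
        return self.angles[:, 2]

    def axis(self, name: str) -> np.ndarray:
        try:
            return self.angles[:, ANGLE_AXES.index(name)]
        except ValueError:
            raise ContractError(f"unknown angle axis {name!r}") from None

    def shifted(self, offsets) -> "JointAngleSeries":
        offsets = np.asarray(offsets, dtype=float).reshape(1, 3)
        return JointAngleSeries(t=self.t, angles=self.angles - offsets)


@dataclass
class ActivityLabels:
    """Per-second activity labels (sitting/standing/stepping/lying/transport)."""

    t: np.ndarray  # second start times (s)
    labels: np.ndarray  # array of str

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.t.shape != self.labels.shape:
            raise ContractError("label track: t and labels must match in length")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class TaskWindow:
    """One standardized-task occurrence.

    ``condition`` is one of ``lab``, ``rw1``, ``rw2``; ``provenance``
    records how the window was obtained (``flag``, ``hop``, ``manual``).
    """

    task_id: str
    condition: str
    start_s: float
    end_s: float
    reps: list[tuple[float, float]] = field(default_factory=list)
    provenance: str = "manual"

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise ContractError(f"task window {self.task_id}: start must precede end")
        for s, e in self.reps:
            if not (self.start_s - 1e-9 <= s < e <= self.end_s + 1e-9):
                raise ContractError(f"task window {self.task_id}: rep sub-window not nested")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def window_mask(t: np.ndarray, start_s: float, end_s: float) -> np.ndarray:
    """Boolean mask of samples falling in ``[start_s, end_s)``."""
    return (t >= start_s) & (t < end_s)


def summarize(obj: Any) -> dict:
    """Small JSON-friendly summary used in run manifests."""
    if isinstance(obj, SensorStream):
        return {"sensor_id": obj.sensor_id, "n": len(obj), "duration_s": obj.duration_s}
    if isinstance(obj, JointAngleSeries):
        return {"n": len(obj)}
    return {"repr": repr(obj)}


__all__ = [
    "ACTIVITIES",
    "UNKNOWN_LABEL",
    "ANGLE_AXES",
    "SensorStream",
    "OrientationSeries",
    "JointAngleSeries",
    "ActivityLabels",
    "TaskWindow",
    "window_mask",
    "summarize",
    "replace",
]
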