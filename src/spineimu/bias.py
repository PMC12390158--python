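"""Gyroscope bias estimation and removal.

Stillness is detected by thresholding the gyroscope magnitude; each
continuous quiet period longer than a minimum duration contributes one
knot (its mean angular rate at its midpoint) to a piecewise-linear,
per-axis bias model that is subtracted before orientation fusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import SensorStream
from .errors import ContractError, NoStillnessError

log = logging.getLogger(__name__)


@dataclass
class StillnessInterval:
    start_s: float
    end_s: float
    gyro_mean: np.ndarray  # (3,) deg/s
    gyro_std: np.ndarray  # (3,) deg/s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BiasModel:
    """Per-axis piecewise-linear gyro bias vs time.

    Evaluation interpolates linearly between knots and extrapolates with
    the nearest knot value outside their range.
    """

    knot_t: np.ndarray  # (m,) strictly increasing
    knot_values: np.ndarray  # (m, 3) deg/s

    def __post_init__(self):
        self.knot_t = np.atleast_1d(np.asarray(self.knot_t, dtype=float))
        self.knot_values = np.atleast_2d(np.asarray(self.knot_values, dtype=float))
        if self.knot_values.shape != (self.knot_t.size, 3):
            raise ContractError("bias model: knot values must be (m, 3)")
        if self.knot_t.size > 1 and not np.all(np.diff(self.knot_t) > 0):
            raise ContractError("bias model: knot times must be strictly increasing")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.column_stack(
            [np.interp(t, self.knot_t, self.knot_values[:, j]) for j in range(3)]
        )

    def to_dict(self) -> dict:
        return {"knot_t": self.knot_t.tolist(), "knot_values": self.knot_values.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "BiasModel":
        return cls(knot_t=np.asarray(d["knot_t"]), knot_values=np.asarray(d["knot_values"]))

    @classmethod
    def zero(cls) -> "BiasModel":
        return cls(knot_t=np.array([0.0]), knot_values=np.zeros((1, 3)))


def detect_stillness(
    stream: SensorStream,
    gyro_thresh_dps: float = 3.0,
    min_duration_s: float = 5.0,
    max_duration_s: float | None = None,
) -> list[StillnessInterval]:
    """Maximal runs where the gyro magnitude stays below threshold for at
    least ``min_duration_s``.

    ``max_duration_s`` optionally splits very long runs into consecutive
    chunks so that a slowly drifting bias gets more than one knot through
    sustained stillness (e.g. sleep).
    """
    if gyro_thresh_dps <= 0:
        raise ContractError("gyro threshold must be > 0")
    below = stream.gyr_magnitude() < gyro_thresh_dps
    if not below.any():
        return []
    starts = list(np.flatnonzero(np.diff(np.r_[0, below.astype(np.int8)]) == 1))
    ends = list(np.flatnonzero(np.diff(np.r_[below.astype(np.int8), 0]) == -1))
    chunks: list[tuple[int, int]] = []
    for i0, i1 in zip(starts, ends):
        if stream.t[i1] - stream.t[i0] < min_duration_s:
            continue
        if max_duration_s is None:
            chunks.append((i0, i1))
        else:
            step = max(1, int(round(max_duration_s * stream.rate_hz)))
            j = i0
            while j <= i1:
                j2 = min(j + step - 1, i1)
                if stream.t[j2] - stream.t[j] >= min_duration_s or (j == i0 and j2 == i1):
                    chunks.append((j, j2))
                elif chunks and chunks[-1][1] >= i0:
                    chunks[-1] = (chunks[-1][0], j2)  # merge short tail
                j = j2 + 1
    out: list[StillnessInterval] = []
    for i0, i1 in chunks:
        g = stream.gyr[i0 : i1 + 1]
        out.append(
            StillnessInterval(
                start_s=float(stream.t[i0]),
                end_s=float(stream.t[i1]),
                gyro_mean=g.mean(axis=0),
                gyro_std=g.std(axis=0),
            )
        )
    return out


def fit_bias_model(intervals: list[StillnessInterval]) -> BiasModel:
    """One knot per stillness interval, at its midpoint, valued at the
    interval's mean gyro reading.  A single interval yields a constant
    model."""
    if not intervals:
        raise NoStillnessError("no stillness intervals: cannot fit bias model")
    intervals = sorted(intervals, key=lambda iv: iv.midpoint_s)
    return BiasModel(
        knot_t=np.array([iv.midpoint_s for iv in intervals]),
        knot_values=np.vstack([iv.gyro_mean for iv in intervals]),
    )


def remove_bias(stream: SensorStream, model: BiasModel) -> SensorStream:
    """Subtract the evaluated bias from the gyro channels only."""
    out = stream.copy()
    out.gyr = out.gyr - model(out.t)
    return out


def estimate_and_remove_bias(
    stream: SensorStream,
    gyro_thresh_dps: float = 3.0,
    min_duration_s: float = 5.0,
) -> tuple[SensorStream, BiasModel]:
    """Convenience wrapper: detect, fit, subtract.  Falls back to a zero
    model (with a warning) when the recording contains no stillness."""
    intervals = detect_stillness(stream, gyro_thresh_dps, min_duration_s)
    try:
        model = fit_bias_model(intervals)
    except NoStillnessError:
        log.warning("sensor %s: no stillness found, using zero bias", stream.sensor_id)
        model = BiasModel.zero()
    return remove_bias(stream, model), model
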