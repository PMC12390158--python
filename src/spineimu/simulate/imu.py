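"""Raw-sensor synthesis from ground-truth kinematics.

For each sensor: the accelerometer reads rotated gravity plus the shared
trunk linear acceleration, the gyroscope reads the true angular velocity
plus a slowly drifting bias, and the magnetometer reads the rotated Earth
field, scaled and/or tilted during scripted disturbance intervals.  A
per-sensor clock-speed offset makes the claimed timestamps drift linearly
against the master clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from ..core import SensorStream
from .. import quat
from .kinematics import GroundTruth

GRAVITY_UP = np.array([0.0, 0.0, 1.0])


@dataclass
class EarthField:
    """Earth magnetic field in normalized units (undisturbed magnitude 1).

    ``inclination_deg`` is the dip angle; negative values point the field
    above the horizon (southern-hemisphere-like default).
    """

    magnitude: float = 1.0
    inclination_deg: float = -60.0

    def vector(self) -> np.ndarray:
        inc = np.radians(self.inclination_deg)
        return self.magnitude * np.array([np.cos(inc), 0.0, -np.sin(inc)])


@dataclass
class Disturbance:
    """One scripted magnetic-disturbance interval.

    kinds: ``step`` (magnitude scaled by ``1 + magnitude`` throughout),
    ``ramp`` (scale rises linearly to ``1 + magnitude`` over the first
    10 s or 20% of the interval, whichever is shorter, then holds),
    ``tilt`` (field rotated by ``magnitude`` degrees about the west axis).
    """

    start_s: float
    end_s: float
    kind: str  # 'step' | 'ramp' | 'tilt'
    magnitude: float
    sensors: tuple[str, ...] | str = "all"

    def applies_to(self, sensor_id: str) -> bool:
        return self.sensors == "all" or sensor_id in self.sensors

    def to_dict(self) -> dict:
        return {
            "start_s": self.start_s,
            "end_s": self.end_s,
            "kind": self.kind,
            "magnitude": self.magnitude,
            "sensors": list(self.sensors) if self.sensors != "all" else "all",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Disturbance":
        sensors = d["sensors"]
        return cls(
            start_s=d["start_s"], end_s=d["end_s"], kind=d["kind"],
            magnitude=d["magnitude"],
            sensors="all" if sensors == "all" else tuple(sensors),
        )


@dataclass
class BiasSpec:
    """Piecewise-linear true gyro bias (deg/s) vs time."""

    knot_t: np.ndarray
    knot_values: np.ndarray  # (m, 3)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        kt = np.atleast_1d(self.knot_t)
        kv = np.atleast_2d(self.knot_values)
        return np.column_stack([np.interp(t, kt, kv[:, j]) for j in range(3)])

    def to_dict(self) -> dict:
        return {
            "knot_t": np.atleast_1d(self.knot_t).tolist(),
            "knot_values": np.atleast_2d(self.knot_values).tolist(),
        }

    @classmethod
    def zero(cls) -> "BiasSpec":
        return cls(knot_t=np.array([0.0]), knot_values=np.zeros((1, 3)))


@dataclass
class SensorParams:
    sensor_id: str = "lower"
    noise_acc_g: float = 0.0
    noise_gyr_dps: float = 0.0
    noise_mag: float = 0.0
    clock_skew_samples_per_s: float = 0.0
    mounting_quat: np.ndarray = field(default_factory=quat.identity)
    bias: BiasSpec = field(default_factory=BiasSpec.zero)

    def __post_init__(self):
        self.mounting_quat = np.asarray(self.mounting_quat, dtype=float).reshape(4)
        if abs(np.linalg.norm(self.mounting_quat) - 1.0) > 1e-6:
            raise ValueError("mounting rotation must be a unit quaternion")


def angular_velocity_dps(q: np.ndarray, rate_hz: float) -> np.ndarray:
    """Sensor-frame angular velocity from a quaternion trajectory via
    forward differences (deg/s)."""
    n = q.shape[0]
    if n < 2:
        return np.zeros((n, 3))
    q_rel = quat.qmul(quat.qconj(q[:-1]), q[1:])
    rv = Rotation.from_quat(quat.to_scipy(q_rel)).as_rotvec()
    w = np.degrees(rv) * rate_hz
    return np.vstack([w, w[-1:]])


def field_trace(
    t: np.ndarray,
    sensor_id: str,
    earth: EarthField,
    disturbances: list[Disturbance] | None,
) -> np.ndarray:
    """Earth-frame field vector per sample after scripted disturbances."""
    base = earth.vector()
    e = np.tile(base, (t.size, 1))
    for d in disturbances or []:
        if not d.applies_to(sensor_id):
            continue
        sel = (t >= d.start_s) & (t < d.end_s)
        if not sel.any():
            continue
        if d.kind == "step":
            e[sel] *= 1.0 + d.magnitude
        elif d.kind == "ramp":
            onset = min(10.0, 0.2 * (d.end_s - d.start_s))
            u = np.clip((t[sel] - d.start_s) / max(1e-9, onset), 0.0, 1.0)
            e[sel] *= (1.0 + d.magnitude * u)[:, None]
        elif d.kind == "tilt":
            rot = quat.from_axis_angle([0.0, 1.0, 0.0], np.radians(d.magnitude))
            e[sel] = quat.qrot(rot, e[sel])
        else:
            raise ValueError(f"unknown disturbance kind {d.kind!r}")
    return e


def synthesize_imu(
    truth: GroundTruth,
    params: SensorParams,
    earth: EarthField | None = None,
    disturbances: list[Disturbance] | None = None,
    seed: int = 0,
) -> SensorStream:
    """Render one sensor's raw stream from the ground truth.

    The sensor orientation is the segment orientation composed with the
    session's mounting offset.  Clock skew ``s`` (samples/s) makes claimed
    timestamps advance at ``1 + s/rate`` relative to the master clock, so
    the lag against a skew-free sensor grows as ``s x t`` samples.
    """
    earth = earth or EarthField()
    rng = np.random.default_rng(seed)
    rate = truth.rate_hz
    seg_q = {
        "upper": truth.q_upper,
        "lower": truth.q_lower,
        "thigh": truth.q_thigh if truth.q_thigh is not None else truth.q_lower,
    }[params.sensor_id if params.sensor_id in ("upper", "lower", "thigh") else "lower"]
    q_s = quat.qmul(seg_q, params.mounting_quat)

    gyr = angular_velocity_dps(q_s, rate)
    gyr = gyr + params.bias(truth.t - truth.t[0])
    q_inv = quat.qconj(q_s)
    acc = quat.qrot(q_inv, truth.lin_acc_earth + GRAVITY_UP)
    e = field_trace(truth.t, params.sensor_id, earth, disturbances)
    mag = quat.qrot(q_inv, e)

    if params.noise_gyr_dps:
        gyr = gyr + rng.normal(0.0, params.noise_gyr_dps, gyr.shape)
    if params.noise_acc_g:
        acc = acc + rng.normal(0.0, params.noise_acc_g, acc.shape)
    if params.noise_mag:
        mag = mag + rng.normal(0.0, params.noise_mag, mag.shape)

    skew = params.clock_skew_samples_per_s
    if skew == 0.0:
        t_claim = truth.t - truth.t[0]
        return SensorStream(
            sensor_id=params.sensor_id, t=t_claim, acc=acc, gyr=gyr, mag=mag, rate_hz=rate
        )
    dt = 1.0 / rate
    t_rel = truth.t - truth.t[0]
    span = t_rel[-1]
    n_out = int(np.floor(span * (rate + skew) / rate / dt)) + 1
    tau = np.arange(n_out) * dt * rate / (rate + skew)  # master time of each sample
    out = {}
    for name, arr in (("acc", acc), ("gyr", gyr), ("mag", mag)):
        out[name] = np.column_stack([np.interp(tau, t_rel, arr[:, j]) for j in range(3)])
    return SensorStream(
        sensor_id=params.sensor_id,
        t=np.arange(n_out) * dt,
        acc=out["acc"],
        gyr=out["gyr"],
        mag=out["mag"],
        rate_hz=rate,
    )


def disturbed_sample_mask(
    t: np.ndarray, sensor_id: str, disturbances: list[Disturbance]
) -> np.ndarray:
    """Master-grid samples whose field was modified (simulation manifest
    oracle)."""
    sel = np.zeros(t.size, dtype=bool)
    for d in disturbances:
        if d.applies_to(sensor_id):
            sel |= (t >= d.start_s) & (t < d.end_s)
    return sel
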