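"""Gradient-descent MARG orientation filter and lumbar joint angles.

The filter is a predictor-corrector complementary filter: the quaternion
derivative from the gyroscope is corrected by descending the gradient of a
gravity-plus-magnetic-field alignment objective, with the step size set by
a single gain.  The magnetic reference is re-derived from the current
estimate each step (horizontal + vertical field components), so only the
dip angle -- not the absolute heading -- is constrained by the reference.

Quaternions are scalar-first Hamilton, sensor -> Earth, Earth frame
north-west-up (see :mod:`spineimu.quat`).
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .core import JointAngleSeries, OrientationSeries, SensorStream
from .errors import ContractError
from . import quat

log = logging.getLogger(__name__)

DEG = math.pi / 180.0


def initial_orientation(acc: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Analytic accelerometer+magnetometer alignment (TRIAD-style).

    ``acc`` gives the up direction in the sensor frame; the magnetometer
    fixes heading.  Returns a unit quaternion (sensor -> Earth).
    """
    up = np.asarray(acc, dtype=float)
    m = np.asarray(mag, dtype=float)
    nu = np.linalg.norm(up)
    nm = np.linalg.norm(m)
    if nu == 0:
        return quat.identity()
    up = up / nu
    if nm == 0:
        # gravity only: pick any heading
        m = np.array([1.0, 0.0, 0.0])
        if abs(up[0]) > 0.9:
            m = np.array([0.0, 1.0, 0.0])
    else:
        m = m / nm
    west = np.cross(up, m)
    nw = np.linalg.norm(west)
    if nw < 1e-12:  # field parallel to gravity: heading unobservable
        west = np.cross(up, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(west) < 1e-12:
            west = np.cross(up, np.array([0.0, 1.0, 0.0]))
        nw = np.linalg.norm(west)
    west = west / nw
    north = np.cross(west, up)
    rot = np.vstack([north, west, up])  # rows: Earth axes in sensor coords
    from scipy.spatial.transform import Rotation

    return quat.from_scipy(Rotation.from_matrix(rot).as_quat())


def _fusion_step_scalar(
    qw, qx, qy, qz, ax, ay, az, gx, gy, gz, mx, my, mz, beta, dt
):
    """One filter update with plain floats (hot loop).

    Gyro rates in rad/s.  Returns the renormalized quaternion components
    and a flag telling whether the corrector ran (False = gyro-only step).

    The gyro prediction uses exact exponential integration
    (``q (x) exp(w dt / 2)``), which is error-free for piecewise-constant
    rates; the field/gravity correction is the usual normalized-gradient
    descent step scaled by the gain.
    """
    wn = math.sqrt(gx * gx + gy * gy + gz * gz)
    if wn > 0.0:
        half = 0.5 * wn * dt
        c = math.cos(half)
        s = math.sin(half) / wn
        rw, rx, ry, rz = c, gx * s, gy * s, gz * s
        qw, qx, qy, qz = (
            qw * rw - qx * rx - qy * ry - qz * rz,
            qw * rx + qx * rw + qy * rz - qz * ry,
            qw * ry - qx * rz + qy * rw + qz * rx,
            qw * rz + qx * ry - qy * rx + qz * rw,
        )
    dqw = dqx = dqy = dqz = 0.0

    corrected = False
    an = math.sqrt(ax * ax + ay * ay + az * az)
    mn = math.sqrt(mx * mx + my * my + mz * mz)
    if beta > 0.0 and an > 0.0 and mn > 0.0:
        corrected = True
        ax, ay, az = ax / an, ay / an, az / an
        mx, my, mz = mx / mn, my / mn, mz / mn

        # field reference from current estimate: h = q (x) m (x) q*
        # (rotate measurement into Earth frame, keep horizontal magnitude + vertical)
        hx = (
            (1 - 2 * (qy * qy + qz * qz)) * mx
            + 2 * (qx * qy - qw * qz) * my
            + 2 * (qx * qz + qw * qy) * mz
        )
        hy = (
            2 * (qx * qy + qw * qz) * mx
            + (1 - 2 * (qx * qx + qz * qz)) * my
            + 2 * (qy * qz - qw * qx) * mz
        )
        hz = (
            2 * (qx * qz - qw * qy) * mx
            + 2 * (qy * qz + qw * qx) * my
            + (1 - 2 * (qx * qx + qy * qy)) * mz
        )
        bx = math.sqrt(hx * hx + hy * hy)
        bz = hz

        # objective: predicted gravity / field in sensor frame minus measurement
        f1 = 2 * (qx * qz - qw * qy) - ax
        f2 = 2 * (qw * qx + qy * qz) - ay
        f3 = 1 - 2 * (qx * qx + qy * qy) - az
        f4 = bx * (1 - 2 * (qy * qy + qz * qz)) + bz * 2 * (qx * qz - qw * qy) - mx
        f5 = bx * 2 * (qx * qy - qw * qz) + bz * 2 * (qw * qx + qy * qz) - my
        f6 = bx * 2 * (qx * qz + qw * qy) + bz * (1 - 2 * (qx * qx + qy * qy)) - mz

        # gradient = J^T f
        gw = (
            -2 * qy * f1
            + 2 * qx * f2
            + (-2 * bz * qy) * f4
            + (-2 * bx * qz + 2 * bz * qx) * f5
            + (2 * bx * qy) * f6
        )
        gxq = (
            2 * qz * f1
            + 2 * qw * f2
            - 4 * qx * f3
            + (2 * bz * qz) * f4
            + (2 * bx * qy + 2 * bz * qw) * f5
            + (2 * bx * qz - 4 * bz * qx) * f6
        )
        gyq = (
            -2 * qw * f1
            + 2 * qz * f2
            - 4 * qy * f3
            + (-4 * bx * qy - 2 * bz * qw) * f4
            + (2 * bx * qx + 2 * bz * qz) * f5
            + (2 * bx * qw - 4 * bz * qy) * f6
        )
        gzq = (
            2 * qx * f1
            + 2 * qy * f2
            + (-4 * bx * qz + 2 * bz * qx) * f4
            + (-2 * bx * qw + 2 * bz * qy) * f5
            + (2 * bx * qx) * f6
        )
        gn = math.sqrt(gw * gw + gxq * gxq + gyq * gyq + gzq * gzq)
        if gn > 0.0:
            dqw -= beta * gw / gn
            dqx -= beta * gxq / gn
            dqy -= beta * gyq / gn
            dqz -= beta * gzq / gn

    qw += dqw * dt
    qx += dqx * dt
    qy += dqy * dt
    qz += dqz * dt
    n = math.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
    return qw / n, qx / n, qy / n, qz / n, corrected


def fusion_step(q, accel, gyro_dps, mag, gain: float, dt: float) -> np.ndarray:
    """Single predictor-corrector update (array interface).

    ``gyro_dps`` in deg/s; ``accel``/``mag`` are normalized internally.  A
    zero-norm accelerometer or magnetometer sample degrades to a gyro-only
    update for that step.
    """
    if dt <= 0:
        raise ContractError("dt must be > 0")
    q = np.asarray(q, dtype=float)
    a = np.asarray(accel, dtype=float)
    g = np.asarray(gyro_dps, dtype=float) * DEG
    m = np.asarray(mag, dtype=float)
    qw, qx, qy, qz, _ = _fusion_step_scalar(
        q[0], q[1], q[2], q[3], a[0], a[1], a[2], g[0], g[1], g[2], m[0], m[1], m[2], gain, dt
    )
    return np.array([qw, qx, qy, qz])


def estimate_orientation(
    stream: SensorStream,
    gain: float = 0.1,
    q0: np.ndarray | None = None,
) -> OrientationSeries:
    """Run the filter over a (synchronized, bias-corrected) stream.

    The initial orientation defaults to the analytic accel+mag alignment at
    the first sample.
    """
    n = len(stream)
    if n == 0:
        return OrientationSeries(
            t=np.empty(0), q=np.empty((0, 4)), sensor_id=stream.sensor_id, gain=gain,
            rate_hz=stream.rate_hz,
        )
    if q0 is None:
        q0 = initial_orientation(stream.acc[0], stream.mag[0])
    qw, qx, qy, qz = (float(x) for x in quat.qnormalize(np.asarray(q0, dtype=float)))

    t = stream.t
    acc = stream.acc.tolist()
    gyr = (stream.gyr * DEG).tolist()
    mag = stream.mag.tolist()
    dts = np.diff(t).tolist()

    out = np.empty((n, 4))
    out[0] = (qw, qx, qy, qz)
    skipped = 0
    step = _fusion_step_scalar
    # the step from sample i-1 to i integrates the rate measured over that
    # interval (previous gyro sample) and corrects against the arrival
    # accelerometer/magnetometer samples
    for i in range(1, n):
        a = acc[i]
        g = gyr[i - 1]
        m = mag[i]
        qw, qx, qy, qz, corrected = step(
            qw, qx, qy, qz, a[0], a[1], a[2], g[0], g[1], g[2], m[0], m[1], m[2], gain, dts[i - 1]
        )
        if not corrected and gain > 0.0:
            skipped += 1
        out[i, 0] = qw
        out[i, 1] = qx
        out[i, 2] = qy
        out[i, 3] = qz
    if skipped:
        log.warning(
            "sensor %s: %d gyro-only steps (zero-norm accel or mag)", stream.sensor_id, skipped
        )
    return OrientationSeries(
        t=t.copy(), q=out, sensor_id=stream.sensor_id, gain=gain, rate_hz=stream.rate_hz
    )


def joint_angles(upper: OrientationSeries, lower: OrientationSeries) -> JointAngleSeries:
    """Lumbar joint Euler angles from the two spine-sensor orientations.

    ``q_joint = conj(q_lower) (x) q_upper`` (upper expressed in the lower
    frame), decomposed intrinsically z-y'-x'' and reported in degrees as
    (lateral flexion x, flexion-extension y, axial rotation z).
    """
    if len(upper) != len(lower):
        raise ContractError(
            f"orientation series length mismatch: {len(upper)} vs {len(lower)}"
        )
    if len(upper) and not np.allclose(upper.t, lower.t, atol=1e-6):
        raise ContractError("orientation series must share one clock grid")
    qj = quat.qmul(quat.qconj(lower.q), upper.q)
    if len(upper) == 0:
        return JointAngleSeries(t=upper.t.copy(), angles=np.empty((0, 3)))
    e = quat.to_euler_zyx(qj)  # columns (z, y, x)
    angles = np.column_stack([e[:, 2], e[:, 1], e[:, 0]])
    return JointAngleSeries(t=upper.t.copy(), angles=angles)


def angular_error_deg(q_est: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Total rotation angle between estimated and true quaternions (deg)."""
    q_rel = quat.qmul(quat.qconj(q_true), q_est)
    w = np.clip(np.abs(q_rel[..., 0]), -1.0, 1.0)
    return 2.0 * np.degrees(np.arccos(w))
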