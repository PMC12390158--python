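"""Quaternion utilities (Hamilton convention, scalar-first).

Quaternions are stored as ``(..., 4)`` arrays ``[w, x, y, z]`` and
represent rotations from the sensor (or segment) frame to the Earth frame.
The Earth frame is right-handed north-west-up (x north, y west, z up), so
gravity measured by a resting accelerometer is ``+1 g`` along the sensor
axis that points up.

scipy's :class:`~scipy.spatial.transform.Rotation` (scalar-last) is used at
the boundary for Euler conversions; everything else is explicit so the
algebra stays transparent in the fusion filter.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "qmul",
    "qconj",
    "qnormalize",
    "qrot",
    "from_axis_angle",
    "from_rotvec",
    "to_rotvec",
    "from_euler_zyx",
    "to_euler_zyx",
    "to_scipy",
    "from_scipy",
    "identity",
]


def identity(n: int | None = None) -> np.ndarray:
    """Identity quaternion, or ``(n, 4)`` stack of identities."""
    if n is None:
        return np.array([1.0, 0.0, 0.0, 0.0])
    q = np.zeros((n, 4))
    q[:, 0] = 1.0
    return q


def qmul(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product ``p ⊗ q`` (broadcasts over leading axes)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pw, px, py, pz = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    qw, qx, qy, qz = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    return np.stack(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    return q / n


def qrot(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by quaternion(s) ``q`` (sensor -> Earth)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # v + 2 w (u x v) + 2 u x (u x v), valid for unit quaternions
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def from_axis_angle(axis, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = 0.5 * angle_rad
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def from_rotvec(rotvec: np.ndarray) -> np.ndarray:
    """Quaternion(s) from rotation vector(s) in radians."""
    r = Rotation.from_rotvec(np.atleast_2d(rotvec))
    q = from_scipy(r.as_quat())
    return q[0] if np.ndim(rotvec) == 1 else q


def to_rotvec(q: np.ndarray) -> np.ndarray:
    r = Rotation.from_quat(to_scipy(np.atleast_2d(q)))
    rv = r.as_rotvec()
    return rv[0] if np.ndim(q) == 1 else rv


def from_scipy(q_xyzw: np.ndarray) -> np.ndarray:
    q_xyzw = np.asarray(q_xyzw, dtype=float)
    return np.concatenate([q_xyzw[..., 3:4], q_xyzw[..., :3]], axis=-1)


def to_scipy(q_wxyz: np.ndarray) -> np.ndarray:
    q_wxyz = np.asarray(q_wxyz, dtype=float)
    return np.concatenate([q_wxyz[..., 1:4], q_wxyz[..., 0:1]], axis=-1)


def from_euler_zyx(z_deg, y_deg, x_deg) -> np.ndarray:
    """Quaternion from intrinsic z-y'-x'' Euler angles in degrees.

    ``z`` is axial rotation, ``y`` flexion-extension (forward positive),
    ``x`` lateral flexion.
    """
    ang = np.stack(
        [np.asarray(z_deg, dtype=float), np.asarray(y_deg, dtype=float), np.asarray(x_deg, dtype=float)],
        axis=-1,
    )
    scalar = ang.ndim == 1
    r = Rotation.from_euler("ZYX", np.atleast_2d(ang), degrees=True)
    q = from_scipy(r.as_quat())
    return q[0] if scalar else q


def to_euler_zyx(q: np.ndarray) -> np.ndarray:
    """Intrinsic z-y'-x'' Euler angles in degrees, columns ``(z, y, x)``."""
    scalar = np.ndim(q) == 1
    r = Rotation.from_quat(to_scipy(np.atleast_2d(q)))
    e = r.as_euler("ZYX", degrees=True)
    return e[0] if scalar else e
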