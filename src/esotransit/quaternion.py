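"""Unit-quaternion algebra (Hamilton convention, scalar-first).

Quaternions here map the *sensor* frame to the *earth* frame (ENU:
x = east, y = north, z = up): ``v_earth = q ⊗ v_sensor ⊗ q*``.  Arrays are
``(..., 4)`` with components ordered ``(w, x, y, z)``; all functions
broadcast over leading axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quat_normalize",
    "quat_multiply",
    "quat_conjugate",
    "rotate_vector",
    "quat_from_axis_angle",
    "quat_to_euler_zyx",
    "quat_angle_between",
]

_EPS = 1e-12


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Return q scaled to unit norm. Raises on (near-)zero quaternions."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < _EPS):
        raise ValueError("cannot normalize a zero-norm quaternion")
    return q / n


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v from the sensor frame to the earth frame by q.

    Uses ``v' = v + 2 q_v × (q_v × v + w v)``, which is the expanded form of
    ``q ⊗ v ⊗ q*`` for unit q.  Pass ``quat_conjugate(q)`` to rotate
    earth → sensor.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(q, axis=-1)
    if np.any(n < _EPS):
        raise ValueError("rotation by a zero-norm quaternion is undefined")
    w = q[..., :1]
    qv = q[..., 1:]
    t = np.cross(qv, np.cross(qv, v) + w * v)
    return v + 2.0 * t


def quat_from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle_rad`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < _EPS:
        raise ValueError("rotation axis must be non-zero")
    half = 0.5 * float(angle_rad)
    return np.concatenate([[np.cos(half)], np.sin(half) * axis / n])


def quat_to_euler_zyx(q: np.ndarray) -> np.ndarray:
    """Intrinsic Z-Y-X (yaw-pitch-roll) Euler angles, degrees.

    Returns ``(..., 3)`` ordered (roll, pitch, yaw).  Reporting convention
    only; all computation stays in quaternions.
    """
    q = quat_normalize(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    roll = np.arctan2(2.0 * (w * x + y * z), 1.0 - 2.0 * (x * x + y * y))
    pitch = np.arcsin(np.clip(2.0 * (w * y - z * x), -1.0, 1.0))
    yaw = np.arctan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z))
    return np.degrees(np.stack([roll, pitch, yaw], axis=-1))


def quat_angle_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Geodesic angle (radians) between two rotations, sign-insensitive."""
    a = quat_normalize(a)
    b = quat_normalize(b)
    dot = np.abs(np.sum(a * b, axis=-1))
    return 2.0 * np.arccos(np.clip(dot, -1.0, 1.0))
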