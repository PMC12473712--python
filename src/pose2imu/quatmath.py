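"""Quaternion algebra for rigid-body orientation streams.

Conventions used throughout the package:

* Quaternions are stored **w-first**: ``(w, x, y, z)``, Hamilton convention.
* Unit quaternions represent **body-to-world** rotations, i.e. ``q ⊗ (0,v_b) ⊗ q*``
  maps a body-frame vector into the world frame.  Consequently the world→body
  map used by the kinematic transforms is the conjugated sandwich
  ``q* ⊗ (0,v_w) ⊗ q``.
* Euler angles are intrinsic Z-Y-X (yaw, pitch, roll), in radians.

All functions are vectorised: a "quaternion" argument is an ndarray whose last
axis has length 4, a "vector" an ndarray whose last axis has length 3.  Scalars
broadcast in the usual numpy way.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "hamilton_product",
    "conjugate",
    "norm",
    "normalize",
    "rotate_world_to_body",
    "rotate_body_to_world",
    "quat_to_euler",
    "euler_to_quat",
    "from_axis_angle",
    "random_unit_quaternions",
]

#: identity rotation, w-first
IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def _check_finite(q: np.ndarray, name: str) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError(f"{name} contains non-finite components")
    return q


def hamilton_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b`` of two (arrays of) quaternions.

    Inputs need not be unit quaternions; the product norm is the product of
    the input norms.  Raises ``ValueError`` on non-finite components.
    """
    a = _check_finite(a, "a")
    b = _check_finite(b, "b")
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


def conjugate(q: np.ndarray) -> np.ndarray:
    """Quaternion conjugate ``q* = (w, -x, -y, -z)`` (inverse for unit q)."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def norm(q: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(q, dtype=float), axis=-1)


def normalize(q: np.ndarray) -> np.ndarray:
    """Scale to unit norm.  Raises on (numerically) zero quaternions."""
    q = _check_finite(q, "q")
    n = norm(q)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n[..., None]


def _require_unit(q: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    q = _check_finite(q, "q")
    err = np.abs(norm(q) - 1.0)
    if np.any(err > tol):
        raise ValueError(
            f"quaternion norm deviates from 1 by {float(np.max(err)):.3g} "
            f"(tolerance {tol:g})"
        )
    return q


def _sandwich(q: np.ndarray, v: np.ndarray, conj_first: bool) -> np.ndarray:
    v = _check_finite(v, "v")
    pure = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    if conj_first:
        out = hamilton_product(hamilton_product(conjugate(q), pure), q)
    else:
        out = hamilton_product(hamilton_product(q, pure), conjugate(q))
    return out[..., 1:]


def rotate_world_to_body(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate world-frame vector(s) into the body frame: ``vec(q* ⊗ (0,v) ⊗ q)``.

    ``q`` must be unit within 1e-6.  Norm of ``v`` is preserved.
    """
    return _sandwich(_require_unit(q), v, conj_first=True)


def rotate_body_to_world(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rotate_world_to_body`: ``vec(q ⊗ (0,v) ⊗ q*)``."""
    return _sandwich(_require_unit(q), v, conj_first=False)


def quat_to_euler(q: np.ndarray) -> np.ndarray:
    """Unit quaternion(s) → intrinsic Z-Y-X Euler angles (yaw, pitch, roll).

    Angles are in radians, yaw/roll in (-pi, pi], pitch in [-pi/2, pi/2].
    In the gimbal-lock neighbourhood (|pitch| within ~1e-6 of pi/2) the
    yaw/roll split is resolved by fixing roll = 0.
    """
    q = _require_unit(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    sinp = np.clip(2.0 * (w * y - z * x), -1.0, 1.0)
    pitch = np.arcsin(sinp)

    yaw = np.arctan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z))
    roll = np.arctan2(2.0 * (w * x + y * z), 1.0 - 2.0 * (x * x + y * y))

    locked = np.abs(np.abs(sinp) - 1.0) < 1e-9
    if np.any(locked):
        # at the singularity only yaw±roll is observable; put it all in yaw
        yaw_lock = 2.0 * np.arctan2(z, w) * np.sign(sinp)
        yaw = np.where(locked, yaw_lock, yaw)
        roll = np.where(locked, 0.0, roll)
    return np.stack([yaw, pitch, roll], axis=-1)


def euler_to_quat(e: np.ndarray) -> np.ndarray:
    """Intrinsic Z-Y-X Euler angles (yaw, pitch, roll) → unit quaternion."""
    e = _check_finite(e, "euler angles")
    yaw, pitch, roll = np.moveaxis(e, -1, 0)
    cy, sy = np.cos(yaw / 2), np.sin(yaw / 2)
    cp, sp = np.cos(pitch / 2), np.sin(pitch / 2)
    cr, sr = np.cos(roll / 2), np.sin(roll / 2)
    return np.stack(
        [
            cy * cp * cr + sy * sp * sr,
            cy * cp * sr - sy * sp * cr,
            cy * sp * cr + sy * cp * sr,
            sy * cp * cr - cy * sp * sr,
        ],
        axis=-1,
    )


def from_axis_angle(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle`` radians about ``axis``.

    ``axis`` is normalised internally; ``angle`` broadcasts against it.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    angle = np.asarray(angle, dtype=float)
    half = angle / 2.0
    return np.concatenate(
        [np.cos(half)[..., None], np.sin(half)[..., None] * axis], axis=-1
    )


def random_unit_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` quaternions uniformly on S^3 (uniform random rotations)."""
    q = rng.standard_normal((n, 4))
    return q / np.linalg.norm(q, axis=-1, keepdims=True)
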