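"""Pose-to-IMU modality transformation.

Given a uniformly sampled 6-DoF pose recording — positions ``p(t)`` in the
world frame and body-to-world unit quaternions ``o(t)`` — this module produces
the signals an inertial measurement unit rigidly attached to the tracked body
would report:

* body-frame velocity      ``v(t) = vec( o*(t) ⊗ p'(t)  ⊗ o(t) )``
* body-frame acceleration  ``a(t) = vec( o*(t) ⊗ p''(t) ⊗ o(t) )``
* body-frame angular rate  ``ω(t) = 2 M(o(t)) o'(t)  ==  2 vec( o*(t) ⊗ o'(t) )``

where ``'`` is the forward difference over the sample period ΔT and ``M(o)``
is the 3x4 quaternion-rate matrix.  No gravity term enters the acceleration
by default (the transform models kinematic acceleration, not specific force);
an opt-in flag subtracts gravity rotated into the body frame for users who
want accelerometer semantics.

Quaternion streams are sign-continuity corrected before differencing: ``q``
and ``-q`` encode the same rotation, and a raw recording may flip sign between
samples, which would corrupt the finite difference.

Optional conditioning applies a zero-phase 4th-order Butterworth low-pass
(typical cutoffs 3 or 6 Hz) to the acceleration and angular-velocity channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import quatmath as qm

__all__ = [
    "PoseRecording",
    "KinematicSeries",
    "GRAVITY",
    "enforce_continuity",
    "quat_derivative",
    "body_velocity",
    "body_acceleration",
    "angular_velocity",
    "lowpass",
    "transform_recording",
]

#: world-frame gravitational acceleration, m/s^2 (world Z up)
GRAVITY = np.array([0.0, 0.0, -9.81])


@dataclass
class PoseRecording:
    """One trial of uniformly sampled 6-DoF pose.

    Parameters
    ----------
    positions : (N, 3) array, metres, world frame.
    orientations : (N, 4) array, unit quaternions (w, x, y, z), body-to-world.
    sample_rate : sampling frequency in Hz.
    """

    positions: np.ndarray
    orientations: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if self.orientations.ndim != 2 or self.orientations.shape[1] != 4:
            raise ValueError("orientations must be an (N, 4) array")
        if len(self.positions) != len(self.orientations):
            raise ValueError("positions and orientations must share length")
        if len(self.positions) < 3:
            raise ValueError("a recording needs at least 3 samples")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")
        if not (self.sample_rate > 0):
            raise ValueError("sample_rate must be positive")
        err = np.abs(qm.norm(self.orientations) - 1.0)
        if np.any(err > 1e-6):
            raise ValueError(
                f"orientations deviate from unit norm by up to {err.max():.3g}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.positions)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        """Span (N-1)·ΔT of the recording, seconds."""
        return (self.n_samples - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass
class KinematicSeries:
    """Body-frame kinematics derived from one :class:`PoseRecording`.

    All three channels share the source recording's length and rate.
    Units: velocity m/s, acceleration m/s^2, angular velocity rad/s.
    """

    velocity: np.ndarray
    acceleration: np.ndarray
    angular_velocity: np.ndarray
    sample_rate: float
    lowpass_cutoff: float | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.velocity)
        if not (len(self.acceleration) == n == len(self.angular_velocity)):
            raise ValueError("kinematic channels must share length")
        for name in ("velocity", "acceleration", "angular_velocity"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} contains non-finite values")


def enforce_continuity(orientations: np.ndarray) -> np.ndarray:
    """Resolve the q/-q sign ambiguity so consecutive quaternions have
    non-negative dot product.

    The first sample is kept as-is; each later sample is flipped whenever that
    brings it onto the same hemisphere as its (already corrected) predecessor.
    """
    q = np.asarray(orientations, dtype=float)
    if q.ndim != 2 or q.shape[1] != 4 or len(q) == 0:
        raise ValueError("expected a non-empty (N, 4) quaternion array")
    dots = np.sum(q[1:] * q[:-1], axis=1)
    # a flip at t toggles the sign of every later comparison
    flips = np.concatenate([[1.0], np.cumprod(np.sign(np.where(dots < 0, -1.0, 1.0)))])
    return q * flips[:, None]


def _forward_diff(x: np.ndarray, dt: float) -> np.ndarray:
    """Forward difference with last-element duplication (keeps length)."""
    d = np.diff(x, axis=0) / dt
    return np.concatenate([d, d[-1:]], axis=0)


def quat_derivative(orientations: np.ndarray, dt: float) -> np.ndarray:
    """Forward-difference quaternion derivative o'(t) = (o(t+1) - o(t)) / ΔT.

    The input should be sign-continuity corrected.  The final element
    duplicates index N-2 so the output length equals the input length.
    """
    q = np.asarray(orientations, dtype=float)
    if len(q) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    if not dt > 0:
        raise ValueError("dt must be positive")
    return _forward_diff(q, dt)


def body_velocity(rec: PoseRecording) -> np.ndarray:
    """Body-frame velocity v(t) = vec( o* ⊗ p' ⊗ o ), shape (N, 3), m/s."""
    o = enforce_continuity(rec.orientations)
    p_dot = _forward_diff(rec.positions, rec.dt)
    return qm.rotate_world_to_body(o, p_dot)


def body_acceleration(rec: PoseRecording, add_gravity: bool = False) -> np.ndarray:
    """Body-frame acceleration a(t) = vec( o* ⊗ p'' ⊗ o ), shape (N, 3), m/s^2.

    ``p''`` is the forward difference applied twice.  With ``add_gravity``
    the world gravity vector is subtracted (rotated into the body frame),
    yielding specific force as an accelerometer would measure it.
    """
    o = enforce_continuity(rec.orientations)
    p_ddot = _forward_diff(_forward_diff(rec.positions, rec.dt), rec.dt)
    a = qm.rotate_world_to_body(o, p_ddot)
    if add_gravity:
        a = a - qm.rotate_world_to_body(o, np.broadcast_to(GRAVITY, a.shape))
    return a


def _rate_matrix_apply(o: np.ndarray, o_dot: np.ndarray) -> np.ndarray:
    """Apply the 3x4 body-rate matrix M(o) to quaternion derivatives.

        M(o) = [[-x,  w,  z, -y],
                [-y, -z,  w,  x],
                [-z,  y, -x,  w]]

    so that ω = 2 M(o) o', algebraically identical to 2 vec(o* ⊗ o').
    """
    w, x, y, z = np.moveaxis(o, -1, 0)
    dw, dx, dy, dz = np.moveaxis(o_dot, -1, 0)
    return np.stack(
        [
            -x * dw + w * dx + z * dy - y * dz,
            -y * dw - z * dx + w * dy + x * dz,
            -z * dw + y * dx - x * dy + w * dz,
        ],
        axis=-1,
    )


def angular_velocity(
    orientations: np.ndarray, dt: float, *, method: str = "matrix"
) -> np.ndarray:
    """Body-frame angular velocity ω(t) = 2 M(o(t)) o'(t), shape (N, 3), rad/s.

    ``method`` selects the algebraic route: ``"matrix"`` applies the 3x4 rate
    matrix, ``"conjugate"`` computes 2 vec(o* ⊗ o').  The two agree to
    machine precision; both are kept so the equivalence is testable.
    Orientations must be unit within 1e-6 (they are continuity-corrected here).
    """
    o = enforce_continuity(orientations)
    err = np.abs(qm.norm(o) - 1.0)
    if np.any(err > 1e-6):
        raise ValueError("orientations must be unit quaternions (tol 1e-6)")
    o_dot = quat_derivative(o, dt)
    if method == "matrix":
        return 2.0 * _rate_matrix_apply(o, o_dot)
    if method == "conjugate":
        return 2.0 * qm.hamilton_product(qm.conjugate(o), o_dot)[..., 1:]
    raise ValueError(f"unknown method {method!r}")


def lowpass(
    series: np.ndarray, cutoff: float, sample_rate: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass, applied independently per channel.

    Forward-backward filtering (``filtfilt``) doubles the effective order's
    attenuation and cancels phase delay, so filtered features stay aligned in
    time with the raw signal.  ``cutoff`` must lie below the Nyquist rate.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < cutoff < sample_rate / 2:
        raise ValueError(
            f"cutoff must be in (0, Nyquist={sample_rate / 2:g} Hz), got {cutoff:g}"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, series, axis=0)


def transform_recording(
    rec: PoseRecording,
    cutoff: float | None = None,
    *,
    order: int = 4,
    add_gravity: bool = False,
) -> KinematicSeries:
    """Full pose→IMU pipeline for one recording.

    Continuity correction → forward-difference derivatives → body-frame
    velocity / acceleration / angular velocity → optional zero-phase low-pass
    on the acceleration and angular-velocity channels.
    """
    v = body_velocity(rec)
    a = body_acceleration(rec, add_gravity=add_gravity)
    w = angular_velocity(rec.orientations, rec.dt)
    if cutoff is not None:
        a = lowpass(a, cutoff, rec.sample_rate, order=order)
        w = lowpass(w, cutoff, rec.sample_rate, order=order)
    return KinematicSeries(
        velocity=v,
        acceleration=a,
        angular_velocity=w,
        sample_rate=rec.sample_rate,
        lowpass_cutoff=cutoff,
    )
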