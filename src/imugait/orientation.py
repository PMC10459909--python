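"""Orientation estimation and heading-frame transformation.

Sensor attitude is tracked as unit quaternions mapping the sensor frame to
a gravity-referenced global frame (global Z up).  When the acquisition
software recorded quaternions they are used directly; otherwise a
gradient-descent complementary filter fuses gyroscope integration with an
accelerometer gravity correction.  Magnetometers are never used for
orientation (they only carry the sync pulse; indoor environments with
ferrous objects make magnetic yaw unreliable), so absolute yaw is
arbitrary: every yaw-dependent quantity is defined relative to the
quiet-stance reference attitude via the heading correction, which yaw-aligns
the horizontal projection of the sensor's local Z axis (mounted to point
along the travel direction) with global +Y.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError, ValidationError
from .types import GRAVITY, HeadingFrameAcceleration, OrientationTrack

__all__ = [
    "fuse_orientation",
    "track_from_quats",
    "quiet_stance_orientation",
    "heading_correction",
    "to_heading_frame",
    "global_yaw_rate",
]


def _tilt_quat_from_acc(acc: np.ndarray) -> Tuple[float, float, float, float]:
    """Scalar-first quaternion rotating the measured gravity onto global Z."""
    a = np.asarray(acc, dtype=float)
    norm = np.linalg.norm(a)
    if norm < 1e-9:
        raise DegenerateInputError("accelerometer sample is all zero")
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [a / norm])
    x, y, z, w = rot.as_quat()
    return (w, x, y, z)


def fuse_orientation(
    time: np.ndarray,
    acc: np.ndarray,
    gyro: np.ndarray,
    gain: float = 0.1,
    q0: Optional[np.ndarray] = None,
    g: float = GRAVITY,
    gate: Tuple[float, float] = (0.3, 0.8),
    gate_window_s: float = 0.4,
) -> OrientationTrack:
    """Gradient-descent (Madgwick-style) accelerometer/gyroscope fusion.

    Gyroscope rates are integrated for the quaternion derivative and a
    normalized gradient step pulls the predicted gravity direction toward
    the measured accelerometer direction.  The correction is gated to
    quasi-static segments: a sample counts as quasi-static when the
    accelerometer magnitude stays close to g over a ``gate_window_s``
    neighbourhood (windowed maximum deviation below ``gate[0]`` m/s^2 for
    full weight, fading linearly to zero at ``gate[1]``).  During gait the
    accelerometer does not point along gravity — its magnitude swings by
    several m/s^2 each step — so between quasi-static moments the filter
    trusts the gyroscope alone; the windowed gate keeps brief in-swing
    crossings of |a| = g from dragging the tilt estimate.  Yaw is
    unobservable from these two sensors: the estimate keeps whatever yaw
    it was initialized with (tilt of the first accelerometer sample, zero
    yaw, unless ``q0`` is given), drifting only with gyro bias.
    Downstream heading correction removes this arbitrariness.

    Parameters
    ----------
    time : (n,) seconds, uniformly sampled.
    acc : (n, 3) m/s^2 in the sensor frame, gravity included.
    gyro : (n, 3) rad/s in the sensor frame.
    gain : dimensionless gradient step size per second.
    q0 : optional initial quaternion, scalar-last.
    g : gravity magnitude used by the quasi-static gate.
    gate : (full-weight, zero-weight) windowed deviations of |acc| from g.
    gate_window_s : length of the quasi-static assessment window, seconds.
    """
    time = np.asarray(time, dtype=float)
    acc = np.asarray(acc, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    n = len(time)
    if acc.shape != (n, 3) or gyro.shape != (n, 3):
        raise ValidationError("acc and gyro must both have shape (n, 3)")
    if n < 2:
        raise ValidationError("need at least two samples")
    dts = np.diff(time)
    dt = float(np.median(dts))
    if np.any(np.abs(dts - dt) > 0.01 * dt):
        raise ValidationError("fuse_orientation requires uniform sampling")
    if not np.any(np.linalg.norm(acc, axis=1) > 1e-9):
        raise DegenerateInputError("accelerometer signal is all zero")

    if q0 is not None:
        x, y, z, w = np.asarray(q0, dtype=float)
        q = (w, x, y, z)
    else:
        i0 = int(np.argmax(np.linalg.norm(acc, axis=1) > 1e-9))
        q = _tilt_quat_from_acc(acc[i0])

    half = max(int(round(gate_window_s * 0.5 / dt)), 1)
    size = 2 * half + 1
    dev_mag = maximum_filter1d(
        np.abs(np.linalg.norm(acc, axis=1) - g), size=size, mode="nearest"
    )
    ptp = np.linalg.norm(
        maximum_filter1d(acc, size=size, axis=0, mode="nearest")
        - minimum_filter1d(acc, size=size, axis=0, mode="nearest"),
        axis=1,
    )
    dev = np.maximum(dev_mag, 0.5 * ptp)
    weights = np.clip((gate[1] - dev) / max(gate[1] - gate[0], 1e-12), 0.0, 1.0)

    out = np.empty((n, 4))
    q0_, q1, q2, q3 = q
    out[0] = (q1, q2, q3, q0_)
    for i in range(1, n):
        gx, gy, gz = gyro[i]
        # quaternion derivative from angular rate: 0.5 * q (x) (0, omega)
        dq0 = 0.5 * (-q1 * gx - q2 * gy - q3 * gz)
        dq1 = 0.5 * (q0_ * gx + q2 * gz - q3 * gy)
        dq2 = 0.5 * (q0_ * gy - q1 * gz + q3 * gx)
        dq3 = 0.5 * (q0_ * gz + q1 * gy - q2 * gx)

        ax, ay, az = acc[i]
        norm = math.sqrt(ax * ax + ay * ay + az * az)
        weight = weights[i]
        if norm > 1e-9 and weight > 0.0:
            ax, ay, az = ax / norm, ay / norm, az / norm
            # objective: predicted sensor-frame gravity minus measurement
            f1 = 2.0 * (q1 * q3 - q0_ * q2) - ax
            f2 = 2.0 * (q0_ * q1 + q2 * q3) - ay
            f3 = 2.0 * (0.5 - q1 * q1 - q2 * q2) - az
            s0 = -2.0 * q2 * f1 + 2.0 * q1 * f2
            s1 = 2.0 * q3 * f1 + 2.0 * q0_ * f2 - 4.0 * q1 * f3
            s2 = -2.0 * q0_ * f1 + 2.0 * q3 * f2 - 4.0 * q2 * f3
            s3 = 2.0 * q1 * f1 + 2.0 * q2 * f2
            snorm = math.sqrt(s0 * s0 + s1 * s1 + s2 * s2 + s3 * s3)
            if snorm > 1e-12:
                # normalized step far from the optimum (constant angular
                # rate, as in the classic gradient filter) but proportional
                # inside a small error zone, so the estimate converges to
                # the fixed point instead of chattering around it with
                # amplitude gain*dt
                fnorm = math.sqrt(f1 * f1 + f2 * f2 + f3 * f3)
                step = gain * weight * min(1.0, fnorm / 0.02) / snorm
                dq0 -= step * s0
                dq1 -= step * s1
                dq2 -= step * s2
                dq3 -= step * s3

        q0_ += dq0 * dt
        q1 += dq1 * dt
        q2 += dq2 * dt
        q3 += dq3 * dt
        inv = 1.0 / math.sqrt(q0_ * q0_ + q1 * q1 + q2 * q2 + q3 * q3)
        q0_, q1, q2, q3 = q0_ * inv, q1 * inv, q2 * inv, q3 * inv
        out[i] = (q1, q2, q3, q0_)
    return track_from_quats(time, out)


def track_from_quats(time: np.ndarray, quat: np.ndarray) -> OrientationTrack:
    """Build a sign-continuous track from recorded scalar-last quaternions."""
    q = np.array(quat, dtype=float)
    norms = np.linalg.norm(q, axis=1)
    if np.any(norms < 1e-9):
        raise ValidationError("zero-norm quaternion in track")
    q /= norms[:, None]
    flips = np.cumsum(np.sum(q[1:] * q[:-1], axis=1) < 0) % 2
    q[1:][flips == 1] *= -1.0
    return OrientationTrack(np.asarray(time, dtype=float), q)


def quiet_stance_orientation(
    track: OrientationTrack,
    window: Tuple[float, float],
    min_duration_s: float = 1.0,
) -> np.ndarray:
    """Reference attitude: chordal mean of quaternions over a quiet window.

    Quaternions are sign-aligned to the first in-window sample before
    averaging, then the mean is renormalized (the chordal mean, adequate
    for the sub-degree scatter of a quiet stance).
    """
    t0, t1 = window
    if t1 - t0 < min_duration_s:
        raise ValidationError(
            f"quiet window {t1 - t0:.2f}s shorter than minimum {min_duration_s}s"
        )
    sel = (track.time >= t0) & (track.time <= t1)
    if not np.any(sel):
        raise ValidationError("quiet window contains no orientation samples")
    q = track.quat[sel]
    signs = np.where(q @ q[0] < 0, -1.0, 1.0)
    mean = (q * signs[:, None]).mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-9:
        raise DegenerateInputError("quaternion mean degenerate (antipodal inputs)")
    return mean / norm


def heading_correction(q_ref: np.ndarray, min_horizontal: float = 1e-3) -> float:
    """Yaw (radians) aligning the sensor's local Z axis with global +Y.

    The returned angle is the frame yaw about the gravity axis such that,
    after applying it (see :func:`to_heading_frame`), the horizontal
    projection of the reference attitude's local Z axis coincides with
    global +Y, i.e. the assumed heading direction.  Raises when local Z is
    (near-)parallel to gravity, where the horizontal projection vanishes.
    """
    z_global = Rotation.from_quat(np.asarray(q_ref, dtype=float)).apply([0.0, 0.0, 1.0])
    px, py = z_global[0], z_global[1]
    if math.hypot(px, py) < min_horizontal:
        raise DegenerateInputError(
            "local Z is parallel to gravity; heading is undefined"
        )
    return -math.atan2(px, py)


def _yaw_matrix(psi: float) -> np.ndarray:
    c, s = math.cos(psi), math.sin(psi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def to_heading_frame(
    time: np.ndarray,
    acc_local: np.ndarray,
    track: OrientationTrack,
    yaw_correction: float = 0.0,
    g: float = GRAVITY,
) -> HeadingFrameAcceleration:
    """Rotate local accelerations into the heading frame and remove gravity.

    Local samples are rotated to the global frame with the orientation
    track, expressed in the yaw-corrected heading frame, and gravity is
    subtracted from the vertical (global Z) component.
    """
    time = np.asarray(time, dtype=float)
    acc_local = np.asarray(acc_local, dtype=float)
    if len(track.time) != len(time) or not np.allclose(track.time, time, atol=1e-9):
        raise ValidationError("orientation track and acceleration time bases differ")
    a_global = Rotation.from_quat(track.quat).apply(acc_local)
    # passive yaw: coordinates in the heading frame
    a_h = a_global @ _yaw_matrix(-yaw_correction).T
    return HeadingFrameAcceleration(
        time=time, ap=a_h[:, 1], ml=a_h[:, 0], v=a_h[:, 2] - g
    )


def global_yaw_rate(track: OrientationTrack, gyro_local: np.ndarray) -> np.ndarray:
    """Angular rate about the gravity axis, rad/s (sign per right-hand rule)."""
    omega_global = Rotation.from_quat(track.quat).apply(np.asarray(gyro_local, float))
    return omega_global[:, 2]
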