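"""Core in-memory containers shared across the pipeline.

All time axes are in seconds on whatever clock the producing stage used
(sensor clock before alignment, session clock after).  Accelerations are in
m/s^2, angular rates in rad/s, magnetometer channels in arbitrary units
normalized so the quiet baseline magnitude is O(1).  Quaternions are stored
scalar-last ``(x, y, z, w)`` to interoperate with
:class:`scipy.spatial.transform.Rotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ValidationError

SITES = ("head", "trunk", "ankle")

#: Standard gravity used throughout the package, m/s^2.
GRAVITY = 9.80665


def _as_float_array(x, name: str, ncol: Optional[int] = None) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if ncol is not None:
        if a.ndim != 2 or a.shape[1] != ncol:
            raise ValidationError(f"{name} must have shape (n, {ncol}), got {a.shape}")
    return a


@dataclass
class ImuRecording:
    """One sensor's raw (or repaired) streams.

    Parameters
    ----------
    site : str
        Body site, one of ``head``, ``trunk``, ``ankle``.
    time : ndarray, shape (n,)
        Sample timestamps, seconds, strictly increasing.  Gaps (dropped
        wireless packets) appear as spacings larger than the nominal period.
    acc, gyro, mag : ndarray, shape (n, 3)
        Tri-axial accelerometer (m/s^2, gravity included), gyroscope (rad/s)
        and magnetometer (arbitrary units) in the sensor's local frame.
    quat : ndarray, shape (n, 4), optional
        Unit orientation quaternions (sensor -> global, scalar-last) when the
        acquisition software recorded them.
    nominal_rate : float
        Nominal sampling rate, Hz.
    interpolated_fraction : float
        Fraction of samples that were inserted by gap repair (0 for raw data).
    """

    site: str
    time: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    quat: Optional[np.ndarray] = None
    nominal_rate: float = 50.0
    interpolated_fraction: float = 0.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.acc = _as_float_array(self.acc, "acc", 3)
        self.gyro = _as_float_array(self.gyro, "gyro", 3)
        self.mag = _as_float_array(self.mag, "mag", 3)
        if self.quat is not None:
            self.quat = _as_float_array(self.quat, "quat", 4)

    def validate(self, quat_tol: float = 1e-6) -> "ImuRecording":
        """Check the container invariants; return self for chaining."""
        if self.site not in SITES:
            raise ValidationError(f"unknown site {self.site!r}")
        n = len(self.time)
        for name in ("acc", "gyro", "mag"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length != time length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValidationError(f"time not strictly increasing at index {i + 1}")
            med = float(np.median(dt))
            if abs(med - 1.0 / self.nominal_rate) > 0.01 / self.nominal_rate:
                raise ValidationError(
                    f"median sampling interval {med:.6f}s deviates >1% from "
                    f"nominal {1.0 / self.nominal_rate:.6f}s"
                )
        if self.quat is not None:
            if len(self.quat) != n:
                raise ValidationError("quat length != time length")
            norms = np.linalg.norm(self.quat, axis=1)
            if np.any(np.abs(norms - 1.0) > max(quat_tol, 1e-6)):
                raise ValidationError("quaternions are not unit norm within 1e-6")
        return self

    def gap_indices(self, factor: float = 1.5) -> np.ndarray:
        """Indices i where time[i+1]-time[i] exceeds factor / nominal_rate."""
        if len(self.time) < 2:
            return np.array([], dtype=int)
        dt = np.diff(self.time)
        return np.nonzero(dt > factor / self.nominal_rate)[0]


EVENT_LABELS = ("quiet_start", "quiet_end", "start", "stop", "sync", "turn", "custom")


@dataclass
class EventLog:
    """Labeled timestamps on the reference (session) clock."""

    entries: List[Tuple[float, str]] = field(default_factory=list)

    def __post_init__(self):
        self.entries = [(float(t), str(lab)) for t, lab in self.entries]

    def validate(self) -> "EventLog":
        times = [t for t, _ in self.entries]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("event times must be non-decreasing")
        for _, lab in self.entries:
            if lab not in EVENT_LABELS:
                raise ValidationError(f"unknown event label {lab!r}")
        return self

    def times(self, label: str) -> np.ndarray:
        return np.array([t for t, lab in self.entries if lab == label], dtype=float)

    def trials(self) -> List[Tuple[float, float]]:
        """Sequential (start, stop) pairs; raises if they do not pair up."""
        starts = self.times("start")
        stops = self.times("stop")
        if len(starts) != len(stops):
            raise ValidationError(
                f"{len(starts)} start vs {len(stops)} stop events do not pair"
            )
        pairs = list(zip(starts, stops))
        for a, b in pairs:
            if b <= a:
                raise ValidationError("stop event precedes its start event")
        return pairs

    def quiet_windows(self) -> List[Tuple[float, float]]:
        qs = self.times("quiet_start")
        qe = self.times("quiet_end")
        if len(qs) != len(qe):
            raise ValidationError("quiet_start / quiet_end events do not pair")
        return list(zip(qs, qe))


@dataclass
class SyncedSession:
    """Three recordings on one common clock plus the event log."""

    recordings: Dict[str, ImuRecording]
    events: EventLog
    applied_offsets: Dict[str, float]


@dataclass
class OrientationTrack:
    """Unit quaternions (sensor -> global, scalar-last) over time.

    Global Z is the gravity axis.  Consecutive quaternions are kept on the
    same hemisphere (no sign flips) so interpolation and averaging behave.
    """

    time: np.ndarray
    quat: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.quat = _as_float_array(self.quat, "quat", 4)


@dataclass
class HeadingFrameAcceleration:
    """Gravity-free acceleration in the heading-aligned global frame.

    ``ap`` is along the heading (global Y), ``ml`` the orthogonal horizontal
    axis (global X), ``v`` the gravity axis (global Z) with gravity removed.
    """

    time: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    v: np.ndarray

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.ap**2 + self.ml**2 + self.v**2)


@dataclass
class FootFlatMask:
    """Per-sample foot-flat (stance) classification of the ankle signal."""

    time: np.ndarray
    is_flat: np.ndarray
    threshold_used: float

    def moving_runs(self) -> List[Tuple[int, int]]:
        """Half-open index ranges [i0, i1) where the foot is moving."""
        moving = ~np.asarray(self.is_flat, dtype=bool)
        edges = np.diff(moving.astype(int))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0] + 1)
        if moving[0]:
            starts.insert(0, 0)
        if moving[-1]:
            ends.append(len(moving))
        return list(zip(starts, ends))


@dataclass
class StrideSet:
    """Right heel strikes and derived stride intervals.

    ``n`` heel strikes define ``n - 1`` strides.  ``valid`` flags strides
    whose duration lies in the physiological band; ``straight`` flags strides
    selected as steady straight-line walking (``None`` until selection ran).
    """

    heel_strikes: np.ndarray
    valid: np.ndarray
    straight: Optional[np.ndarray] = None
    source_task: str = "walk"

    def __post_init__(self):
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.straight is not None:
            self.straight = np.asarray(self.straight, dtype=bool)

    @property
    def n_strides(self) -> int:
        return max(len(self.heel_strikes) - 1, 0)

    @property
    def durations(self) -> np.ndarray:
        return np.diff(self.heel_strikes)

    @property
    def intervals(self) -> np.ndarray:
        """(n_strides, 2) array of (start, end) times."""
        return np.column_stack([self.heel_strikes[:-1], self.heel_strikes[1:]])


@dataclass
class DisplacementTrack:
    """Forward velocity and displacement from double integration."""

    time: np.ndarray
    velocity_ap: np.ndarray
    displacement_ap: np.ndarray
    integration_bounds: Tuple[float, float]
    drift_warning: bool = False


@dataclass
class GaitSummary:
    """Per-trial spatiotemporal gait metrics for one task."""

    stride_durations: np.ndarray
    stride_lengths: np.ndarray
    stride_speeds: np.ndarray
    walking_speed: float
    tug_duration: Optional[float] = None


@dataclass
class AverageCycle:
    """Time-normalized ensemble-average stride cycle for one segment."""

    segment: str
    normalized_time: np.ndarray
    acc_ap: np.ndarray
    acc_ml: np.ndarray
    acc_v: np.ndarray
    n_cycles: int


@dataclass
class StabilizationSummary:
    """Head/trunk stabilization metrics from the average cycle."""

    segment: str
    bobbing_frequency: float
    peak_power: float
    range_ap: float
    range_ml: float
    range_v: float
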