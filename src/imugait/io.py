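"""Reading, writing, synchronizing and repairing IMU logs.

CSV dialect: UTF-8, '.' decimal, header
``time_s,acc_x,acc_y,acc_z,gyro_x,gyro_y,gyro_z,mag_x,mag_y,mag_z``
optionally followed by ``quat_w,quat_x,quat_y,quat_z`` (scalar-first on
disk; in memory quaternions are scalar-last for scipy interoperability).
Events CSV: ``time_s,label``.

Synchronization follows the electromagnetic-pulse scheme: each sensor's
magnetometer records one pulse much shorter than a sample period, so the
pulse occupies a single dominant sample; aligning that sample with the
sync entry of the event log puts all sensors on the event-log clock.  A
tap-based fallback detects sharp accelerometer peaks instead.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

from .errors import (
    AlignmentError,
    AmbiguousPulseError,
    GapTooLongError,
    InsufficientTapsError,
    NoPulseError,
    ParseError,
    ValidationError,
)
from .types import EventLog, ImuRecording, SyncedSession

_BASE_COLUMNS = [
    "time_s",
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "mag_x", "mag_y", "mag_z",
]
_QUAT_COLUMNS = ["quat_w", "quat_x", "quat_y", "quat_z"]


def write_imu_log(rec: ImuRecording, path) -> None:
    """Write one recording in the documented CSV dialect."""
    data = {
        "time_s": rec.time,
        "acc_x": rec.acc[:, 0], "acc_y": rec.acc[:, 1], "acc_z": rec.acc[:, 2],
        "gyro_x": rec.gyro[:, 0], "gyro_y": rec.gyro[:, 1], "gyro_z": rec.gyro[:, 2],
        "mag_x": rec.mag[:, 0], "mag_y": rec.mag[:, 1], "mag_z": rec.mag[:, 2],
    }
    if rec.quat is not None:
        # disk order is scalar-first
        data["quat_w"] = rec.quat[:, 3]
        data["quat_x"] = rec.quat[:, 0]
        data["quat_y"] = rec.quat[:, 1]
        data["quat_z"] = rec.quat[:, 2]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_imu_log(path, site: Optional[str] = None, nominal_rate: float = 50.0) -> ImuRecording:
    """Read a per-sensor CSV log; timestamp gaps are preserved, not repaired.

    The site defaults to the file stem when it names a known site.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed content
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header missing columns {missing}")
    bad = df[_BASE_COLUMNS].isna().any(axis=1)
    if bad.any():
        line = int(np.nonzero(bad.values)[0][0]) + 2  # 1-based, after header
        raise ParseError(f"{path}: malformed or incomplete row at line {line}")
    quat = None
    if all(c in df.columns for c in _QUAT_COLUMNS):
        quat = df[["quat_x", "quat_y", "quat_z", "quat_w"]].to_numpy(float)
    if site is None:
        site = path.stem if path.stem in ("head", "trunk", "ankle") else "trunk"
    rec = ImuRecording(
        site=site,
        time=df["time_s"].to_numpy(float),
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(float),
        gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(float),
        mag=df[["mag_x", "mag_y", "mag_z"]].to_numpy(float),
        quat=quat,
        nominal_rate=nominal_rate,
    )
    return rec.validate()


def write_events_csv(events: EventLog, path) -> None:
    pd.DataFrame(events.entries, columns=["time_s", "label"]).to_csv(path, index=False)


def read_events_csv(path) -> EventLog:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "label"]:
        raise ParseError(f"{path}: expected columns time_s,label")
    return EventLog(list(zip(df["time_s"].astype(float), df["label"].astype(str)))).validate()


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def detect_mag_pulse(
    rec: ImuRecording,
    threshold_factor: float = 10.0,
    separation_s: float = 0.5,
) -> float:
    """Time of the synchronization pulse in the recording's own clock.

    The pulse is shorter than one sample period, so it appears in at most
    one or two samples; the maximal super-threshold sample wins.  The
    threshold is ``baseline + threshold_factor x robust SD`` of the
    magnetometer magnitude (median-absolute-deviation based).
    """
    mag = np.linalg.norm(rec.mag, axis=1)
    baseline = float(np.median(mag))
    rsd = max(_robust_sd(mag), 1e-12)
    thr = baseline + threshold_factor * rsd
    above = np.nonzero(mag > thr)[0]
    if len(above) == 0:
        raise NoPulseError(
            f"no magnetometer sample exceeds baseline + {threshold_factor} x robust SD"
        )
    # cluster super-threshold samples separated by < separation_s
    gaps = np.nonzero(np.diff(rec.time[above]) > separation_s)[0]
    clusters = np.split(above, gaps + 1)
    if len(clusters) > 1:
        raise AmbiguousPulseError([float(rec.time[c[np.argmax(mag[c])]]) for c in clusters])
    c = clusters[0]
    return float(rec.time[c[np.argmax(mag[c])]])


def detect_taps(
    rec: ImuRecording,
    min_count: int,
    threshold_factor: float = 8.0,
    refractory_s: float = 0.25,
) -> np.ndarray:
    """Times of sharp accelerometer-magnitude peaks (tap-based sync)."""
    mag = np.linalg.norm(rec.acc, axis=1)
    dev = np.abs(mag - np.median(mag))
    rsd = max(_robust_sd(mag), 1e-12)
    dist = max(int(round(refractory_s * rec.nominal_rate)), 1)
    peaks, _ = find_peaks(dev, height=threshold_factor * rsd, distance=dist)
    if len(peaks) < min_count:
        raise InsufficientTapsError(
            f"found {len(peaks)} tap peaks, need at least {min_count}"
        )
    return rec.time[peaks]


def align_streams(
    recordings: Mapping[str, ImuRecording],
    sync_times: Mapping[str, float],
    reference_time: float,
    events: Optional[EventLog] = None,
    max_offset_s: float = 60.0,
) -> SyncedSession:
    """Shift each sensor clock so its sync mark lands on ``reference_time``.

    Offsets are applied to the sensor streams only; the event log already
    lives on the reference clock.
    """
    shifted: Dict[str, ImuRecording] = {}
    offsets: Dict[str, float] = {}
    for site, rec in recordings.items():
        offset = reference_time - float(sync_times[site])
        if abs(offset) > max_offset_s:
            raise AlignmentError(
                f"{site}: implied offset {offset:.3f}s exceeds sanity bound "
                f"{max_offset_s}s"
            )
        offsets[site] = offset
        shifted[site] = ImuRecording(
            site=rec.site,
            time=rec.time + offset,
            acc=rec.acc,
            gyro=rec.gyro,
            mag=rec.mag,
            quat=rec.quat,
            nominal_rate=rec.nominal_rate,
            interpolated_fraction=rec.interpolated_fraction,
        )
    return SyncedSession(shifted, events or EventLog([]), offsets)


def synchronize_session(
    recordings: Mapping[str, ImuRecording],
    events: EventLog,
    method: str = "pulse",
    **kwargs,
) -> SyncedSession:
    """Detect per-sensor sync marks and align them to the event-log sync time."""
    sync_event = events.times("sync")
    if len(sync_event) != 1:
        raise ValidationError(f"event log has {len(sync_event)} sync entries, need 1")
    if method == "pulse":
        sync_times = {s: detect_mag_pulse(r, **kwargs) for s, r in recordings.items()}
    elif method == "tap":
        sync_times = {s: float(detect_taps(r, 1, **kwargs)[0]) for s, r in recordings.items()}
    else:
        raise ValidationError(f"unknown sync method {method!r}")
    return align_streams(recordings, sync_times, float(sync_event[0]), events)


def interpolate_missing(rec: ImuRecording, max_gap_s: float = 0.5) -> ImuRecording:
    """Repair dropped samples onto a uniform grid by linear interpolation.

    The output grid runs from the first to the last timestamp at the
    nominal rate.  Idempotent: a gap-free uniform recording is returned
    unchanged (up to float representation of the grid).
    """
    t = rec.time
    if len(t) < 2:
        return rec
    dt = np.diff(t)
    if np.max(dt) > max_gap_s:
        raise GapTooLongError(
            f"gap of {np.max(dt):.3f}s exceeds maximum repairable {max_gap_s}s"
        )
    n_grid = int(round((t[-1] - t[0]) * rec.nominal_rate)) + 1
    grid = t[0] + np.arange(n_grid) / rec.nominal_rate
    inserted = max(n_grid - len(t), 0)

    def interp_cols(x):
        return np.column_stack([np.interp(grid, t, x[:, j]) for j in range(x.shape[1])])

    quat = None
    if rec.quat is not None:
        quat = interp_cols(rec.quat)
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return ImuRecording(
        site=rec.site,
        time=grid,
        acc=interp_cols(rec.acc),
        gyro=interp_cols(rec.gyro),
        mag=interp_cols(rec.mag),
        quat=quat,
        nominal_rate=rec.nominal_rate,
        interpolated_fraction=inserted / n_grid,
    )


def lowpass(
    x: np.ndarray,
    cutoff_hz: float,
    rate_hz: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    ``order`` is the design order of the single pass; the forward-backward
    application squares the magnitude response (and doubles the effective
    roll-off) while cancelling phase, so detected event times are not
    shifted.  DC gain is exactly 1.
    """
    if cutoff_hz <= 0 or cutoff_hz >= rate_hz / 2.0:
        raise ValidationError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={rate_hz / 2.0} Hz)"
        )
    sos = butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)
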