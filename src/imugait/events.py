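"""Heel-strike detection, stride segmentation and straight-cycle selection.

The detection scheme works entirely from the right-ankle signal expressed
in the heading frame:

1. the gravity-free acceleration magnitude is low-pass filtered (3 Hz,
   2nd-order Butterworth, zero-phase) and thresholded to find foot-flat
   (stance) periods — the intervals when the foot rests on the floor;
2. within each moving (swing) period the absolute jerk — the finite
   difference of the anteroposterior acceleration — shows two dominant
   peaks, the first from toe off and the second from heel strike; the
   second super-threshold peak is taken as the heel strike, or the single
   peak when only one exists;
3. consecutive right heel strikes delimit strides; strides are then
   classified as steady straight-line walking by excluding each bout's
   first and last stride (gait initiation/termination) and every stride
   overlapping a turn, detected from the trunk yaw rate.
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    EmptySelectionError,
    EventDetectionError,
    ThresholdError,
    ValidationError,
)
from .io import lowpass
from .types import FootFlatMask, StrideSet

__all__ = [
    "auto_threshold",
    "detect_foot_flat",
    "detect_heel_strikes",
    "segment_strides",
    "select_straight_cycles",
]


def _prune_runs(mask: np.ndarray, min_len: int, value: bool) -> np.ndarray:
    """Flip runs of ``value`` shorter than ``min_len`` samples."""
    out = mask.copy()
    n = len(out)
    i = 0
    while i < n:
        if out[i] == value:
            j = i
            while j < n and out[j] == value:
                j += 1
            if j - i < min_len:
                out[i:j] = not value
            i = j
        else:
            i += 1
    return out


def auto_threshold(
    magnitude: np.ndarray,
    rate_hz: float,
    k: float = 0.2,
    min_spread: float = 1.0,
    cutoff_hz: float = 3.0,
    order: int = 2,
    prefiltered: bool = False,
) -> float:
    """Unattended foot-flat threshold for the filtered acceleration magnitude.

    Returns ``baseline + k x (p95 - baseline)`` of the 3 Hz-low-passed
    magnitude, with the baseline taken as the 5th percentile (the stance
    level).  A manual threshold always takes precedence over this default.
    Signals whose 5th-to-95th percentile spread falls below ``min_spread``
    (m/s^2) carry no stance/swing contrast and raise.
    """
    x = np.asarray(magnitude, dtype=float)
    if not prefiltered:
        x = lowpass(x, cutoff_hz, rate_hz, order)
    baseline = float(np.percentile(x, 5))
    p95 = float(np.percentile(x, 95))
    if p95 - baseline < min_spread:
        raise ThresholdError(
            f"magnitude spread {p95 - baseline:.3f} m/s^2 below {min_spread}; "
            "signal has no stance/swing contrast"
        )
    return baseline + k * (p95 - baseline)


def detect_foot_flat(
    time: np.ndarray,
    magnitude: np.ndarray,
    rate_hz: float,
    threshold: float,
    cutoff_hz: float = 3.0,
    order: int = 2,
    min_run_s: float = 0.1,
    prefiltered: bool = False,
    strict: bool = False,
) -> FootFlatMask:
    """Classify samples as foot-flat where the filtered magnitude < threshold.

    Runs (of either polarity) shorter than ``min_run_s`` are removed, flat
    runs first.  A mask that is entirely flat or entirely moving is
    degenerate: a warning by default, an error with ``strict=True``.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    x = np.asarray(magnitude, dtype=float)
    if not prefiltered:
        x = lowpass(x, cutoff_hz, rate_hz, order)
    mask = x < threshold
    min_len = max(int(round(min_run_s * rate_hz)), 1)
    mask = _prune_runs(mask, min_len, True)
    mask = _prune_runs(mask, min_len, False)
    if mask.all() or not mask.any():
        msg = "degenerate foot-flat mask: threshold excludes " + (
            "nothing" if mask.all() else "everything"
        )
        if strict:
            raise EventDetectionError(msg)
        warnings.warn(msg, stacklevel=2)
    return FootFlatMask(np.asarray(time, float), mask, float(threshold))


def detect_heel_strikes(
    time: np.ndarray,
    acc_ap: np.ndarray,
    mask: FootFlatMask,
    rate_hz: float,
    min_peak_height: Optional[float] = None,
    relative_height: float = 0.5,
    min_separation_s: float = 0.1,
    refine: bool = True,
) -> np.ndarray:
    """Heel-strike times from absolute-jerk peaks during leg motion.

    The jerk is the first-order central difference of the anteroposterior
    ankle acceleration.  Within each moving period, local maxima of |jerk|
    above the height threshold and separated by at least
    ``min_separation_s`` are found; with two or more peaks the second in
    temporal order is the heel strike (toe off precedes it within one
    swing), with exactly one that peak is used, and at most one strike is
    returned per moving period.

    ``min_peak_height`` is an absolute threshold in m/s^3 (the manual
    setting of the original workflow).  When ``None``, the threshold
    defaults per period to ``relative_height`` times that period's maximal
    |jerk| — a scale-invariant rule that keeps noise ripples and filter
    ringing sidelobes below the two comparable physiological spikes.
    """
    time = np.asarray(time, dtype=float)
    jerk = np.abs(np.gradient(np.asarray(acc_ap, dtype=float), 1.0 / rate_hz))
    dist = max(int(round(min_separation_s * rate_hz)), 1)
    strikes: List[float] = []
    skipped = 0
    for i0, i1 in mask.moving_runs():
        seg = jerk[i0:i1]
        if len(seg) < 2 or seg.max() <= 1e-12:
            skipped += 1
            continue
        height = (
            float(min_peak_height)
            if min_peak_height is not None
            else relative_height * float(seg.max())
        )
        peaks, _ = find_peaks(seg, height=height, distance=dist)
        if len(peaks) == 0:
            # a spike at the very edge of the run has no local-max neighbours
            if seg.max() >= height and np.argmax(seg) in (0, len(seg) - 1):
                peaks = np.array([int(np.argmax(seg))])
            else:
                skipped += 1
                continue
        choice = int(peaks[1] if len(peaks) >= 2 else peaks[0])
        t_peak = float(time[i0 + choice])
        if refine and 0 < choice < len(seg) - 1:
            # sub-sample localization: intensity-weighted centroid of the
            # pulse top (samples within 3 of the peak, above half its
            # height) — the true spike maximum rarely falls on a sample,
            # and the centroid also averages out noise on the pulse
            lo, hi = max(choice - 3, 0), min(choice + 4, len(seg))
            w = np.clip(seg[lo:hi] - 0.5 * seg[choice], 0.0, None)
            if w.sum() > 0:
                pos = float((w * np.arange(lo, hi)).sum() / w.sum())
                t_peak = float(np.interp(pos, np.arange(i1 - i0), time[i0:i1]))
        strikes.append(t_peak)
    if skipped:
        warnings.warn(
            f"{skipped} moving period(s) without a super-threshold jerk peak",
            stacklevel=2,
        )
    if not strikes:
        raise EventDetectionError("no heel strikes detected in any moving period")
    return np.asarray(strikes)


def segment_strides(
    heel_strikes: np.ndarray,
    duration_band: Tuple[float, float] = (0.4, 2.5),
    source_task: str = "walk",
) -> StrideSet:
    """Consecutive heel strikes -> strides; durations outside the band are
    flagged invalid (physiological band default 0.4-2.5 s)."""
    hs = np.sort(np.asarray(heel_strikes, dtype=float))
    if len(hs) < 2:
        raise EventDetectionError("need at least two heel strikes to form a stride")
    dur = np.diff(hs)
    valid = (dur >= duration_band[0]) & (dur <= duration_band[1])
    return StrideSet(hs, valid, straight=None, source_task=source_task)


def _smooth(x: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return x
    kernel = np.ones(win) / win
    return np.convolve(x, kernel, mode="same")


def select_straight_cycles(
    strides: StrideSet,
    time: np.ndarray,
    yaw_rate: np.ndarray,
    rate_hz: float,
    turn_threshold_dps: float = 30.0,
    bout_gap_s: float = 2.5,
    smooth_s: float = 0.2,
    dilate_s: float = 0.04,
    manual_indices: Optional[Iterable[int]] = None,
) -> StrideSet:
    """Flag steady straight-walking strides.

    An automated surrogate for manual cycle selection: a stride is straight
    iff (a) it is valid, (b) it is neither the first nor the last stride of
    its walking bout (gait initiation and termination), and (c) it contains
    no sample of turning, where turning means the smoothed absolute trunk
    yaw rate exceeds ``turn_threshold_dps`` (and, redundantly for smooth
    turns, its stride-mean stays below the threshold).  Bouts are delimited
    by invalid strides or inter-strike gaps longer than ``bout_gap_s``.

    ``manual_indices`` reproduces a manual workflow: when given, exactly
    those stride indices are flagged straight and the automatic rule is
    bypassed.
    """
    n = strides.n_strides
    if manual_indices is not None:
        flags = np.zeros(n, dtype=bool)
        flags[np.asarray(list(manual_indices), dtype=int)] = True
        return StrideSet(strides.heel_strikes, strides.valid, flags, strides.source_task)

    time = np.asarray(time, dtype=float)
    yaw = np.abs(_smooth(np.asarray(yaw_rate, dtype=float), int(round(smooth_s * rate_hz))))
    thr = np.deg2rad(turn_threshold_dps)
    turning = yaw > thr
    pad = int(round(dilate_s * rate_hz))
    if pad > 0 and turning.any():
        idx = np.nonzero(turning)[0]
        for i in idx[np.r_[True, np.diff(idx) > 1]]:  # run starts
            turning[max(i - pad, 0) : i] = True
        for i in idx[np.r_[np.diff(idx) > 1, True]]:  # run ends
            turning[i : i + pad + 1] = True

    # bout membership: invalid strides (including long inter-trial gaps,
    # which show up as one over-band "stride") isolate into their own bout
    # and thereby split the walking bouts around them
    durations = strides.durations
    bout_id = np.zeros(n, dtype=int)
    current = 0
    for i in range(1, n):
        if (
            not strides.valid[i - 1]
            or not strides.valid[i]
            or durations[i - 1] > bout_gap_s
            or durations[i] > bout_gap_s
        ):
            current += 1
        bout_id[i] = current

    flags = np.zeros(n, dtype=bool)
    for b in np.unique(bout_id):
        members = np.nonzero(bout_id == b)[0]
        if len(members) <= 2:
            continue
        for i in members[1:-1]:
            if not strides.valid[i]:
                continue
            s, e = strides.heel_strikes[i], strides.heel_strikes[i + 1]
            sel = (time >= s) & (time <= e)
            if not np.any(sel):
                continue
            if np.any(turning[sel]) or float(np.mean(yaw[sel])) >= thr:
                continue
            flags[i] = True
    if not flags.any():
        raise EmptySelectionError("no stride passed straight-walking selection")
    return StrideSet(strides.heel_strikes, strides.valid, flags, strides.source_task)
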