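"""Spatiotemporal gait metrics and head/trunk stabilization measures.

Stride length and walking speed come from double integration of the trunk
anteroposterior acceleration between walk initiation and termination.
Plain cumulative integration of accelerometer data drifts; the
direct-reverse scheme suppresses drift by blending a forward integral
(zero initial condition) with a time-reversed integral (zero final
condition) under a weight ramping linearly from 1 at the start to 0 at
the end, so the velocity honours the quasi-stationarity of the subject at
both bounds.  Displacement is then the plain cumulative integral of the
corrected velocity (only its initial value is known).

Stabilization metrics work on the time-normalized ensemble-average stride
cycle of the head and trunk: the bobbing frequency is the peak spectral
frequency of the vertical component (vertical acceleration peaks twice
per stride, once per step, making it a cadence proxy), and the amplitude
ranges are max-minus-min of the average-cycle trace per axis.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import DegenerateInputError, IntegrationError, ValidationError
from .types import (
    AverageCycle,
    DisplacementTrack,
    EventLog,
    GaitSummary,
    HeadingFrameAcceleration,
    StabilizationSummary,
    StrideSet,
)

__all__ = [
    "direct_reverse_integrate",
    "integrate_displacement",
    "stride_lengths_from_displacement",
    "summarize_gait",
    "average_cycle",
    "bobbing_frequency",
    "amplitude_ranges",
]


def direct_reverse_integrate(
    series: np.ndarray,
    rate_hz: float,
    detrend: Optional[str] = "mean",
) -> np.ndarray:
    """One direct-reverse integration pass (trapezoidal rule).

    The input is de-trended (``"mean"`` removes the constant bias — the
    default, since the boundary-condition blend then cancels any residual
    constant exactly; ``"linear"`` removes a least-squares line, which is
    only appropriate when the true integral vanishes at both ends, e.g.
    out-and-back bouts; ``None`` disables de-trending), integrated forward
    with zero initial condition, and blended with the zero-final-condition
    reverse integral under a linear weight ramp, which forces the output
    to be exactly zero at both ends.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValidationError("series must be one-dimensional")
    if len(y) < 2:
        raise ValidationError("series too short to integrate")
    if detrend == "mean":
        y = y - y.mean()
    elif detrend == "linear":
        t = np.arange(len(y))
        coef = np.polyfit(t, y, 1)
        y = y - np.polyval(coef, t)
    elif detrend is not None:
        raise ValidationError(f"unknown detrend mode {detrend!r}")
    dt = 1.0 / rate_hz
    forward = cumulative_trapezoid(y, dx=dt, initial=0.0)
    reverse = forward - forward[-1]
    w = np.linspace(1.0, 0.0, len(y))
    return w * forward + (1.0 - w) * reverse


def integrate_displacement(
    time: np.ndarray,
    acc_ap: np.ndarray,
    rate_hz: float,
    bounds: Tuple[float, float],
    detrend: Optional[str] = "mean",
    boundary_window_s: float = 0.5,
    boundary_rms_tol: float = 0.5,
) -> DisplacementTrack:
    """Forward velocity and displacement over one walking bout.

    ``bounds`` must be chosen so the subject is quasi-stationary at both
    ends; the accuracy of the displacement estimate depends directly on
    that.  When the acceleration RMS inside the boundary windows exceeds
    ``boundary_rms_tol`` (m/s^2) a drift warning is attached to the track.
    """
    time = np.asarray(time, dtype=float)
    acc_ap = np.asarray(acc_ap, dtype=float)
    t0, t1 = bounds
    sel = (time >= t0) & (time <= t1)
    if sel.sum() < 3:
        raise IntegrationError("integration bounds select fewer than 3 samples")
    tt = time[sel]
    dts = np.diff(tt)
    if np.any(np.abs(dts - 1.0 / rate_hz) > 0.01 / rate_hz):
        raise IntegrationError("non-uniform sampling inside integration bounds")
    a = acc_ap[sel]

    nb = max(int(round(boundary_window_s * rate_hz)), 1)
    rms0 = float(np.sqrt(np.mean(a[:nb] ** 2)))
    rms1 = float(np.sqrt(np.mean(a[-nb:] ** 2)))
    drift = rms0 > boundary_rms_tol or rms1 > boundary_rms_tol
    if drift:
        warnings.warn(
            f"boundary acceleration RMS ({rms0:.2f}/{rms1:.2f} m/s^2) exceeds "
            f"{boundary_rms_tol}; displacement may drift",
            stacklevel=2,
        )
    v = direct_reverse_integrate(a, rate_hz, detrend=detrend)
    d = cumulative_trapezoid(v, dx=1.0 / rate_hz, initial=0.0)
    return DisplacementTrack(tt, v, d, (float(t0), float(t1)), drift_warning=drift)


def stride_lengths_from_displacement(
    track: DisplacementTrack,
    strides: StrideSet,
    indices: Optional[np.ndarray] = None,
    warn_negative: bool = True,
) -> np.ndarray:
    """Per-stride forward displacement change (signed, metres).

    ``length_i = displacement(end_i) - displacement(start_i)``.  Negative
    values (walking against the reference heading, e.g. the return leg of
    a TUG) are flagged with a warning; consumers take magnitudes for
    speed.  Strides outside the integration bounds raise.
    """
    iv = strides.intervals
    if indices is not None:
        iv = iv[np.asarray(indices, dtype=int)]
    t0, t1 = track.integration_bounds
    if np.any(iv[:, 0] < t0 - 1e-9) or np.any(iv[:, 1] > t1 + 1e-9):
        raise IntegrationError("stride outside the integration bounds")
    d0 = np.interp(iv[:, 0], track.time, track.displacement_ap)
    d1 = np.interp(iv[:, 1], track.time, track.displacement_ap)
    lengths = d1 - d0
    if warn_negative and np.any(lengths < 0):
        warnings.warn(
            f"{int(np.sum(lengths < 0))} stride(s) with negative forward "
            "displacement (anti-heading walking)",
            stacklevel=2,
        )
    return lengths


def summarize_gait(
    strides: StrideSet,
    lengths: np.ndarray,
    events: Optional[EventLog] = None,
    task: str = "walk",
) -> GaitSummary:
    """Per-trial summary: straight-stride durations/lengths/speeds, walking
    speed (mean straight-stride speed) and, for TUG, the mean trial
    duration from the start/stop event triggers."""
    if strides.straight is None or not strides.straight.any():
        raise ValidationError("no straight strides; run selection first")
    lengths = np.abs(np.asarray(lengths, dtype=float))
    if len(lengths) != strides.n_strides:
        raise ValidationError("lengths must align with strides")
    sel = strides.straight
    durations = strides.durations[sel]
    lens = lengths[sel]
    speeds = lens / durations
    tug = None
    if task == "tug":
        if events is None:
            raise ValidationError("TUG summary requires the event log")
        trials = events.trials()
        if not trials:
            raise ValidationError("no start/stop trial pairs in event log")
        tug = float(np.mean([b - a for a, b in trials]))
    return GaitSummary(
        stride_durations=durations,
        stride_lengths=lens,
        stride_speeds=speeds,
        walking_speed=float(np.mean(speeds)),
        tug_duration=tug,
    )


def average_cycle(
    segment_acc: HeadingFrameAcceleration,
    strides: StrideSet,
    n_samples: int = 100,
    segment: str = "trunk",
) -> AverageCycle:
    """Time-normalized ensemble average over the straight stride cycles.

    Every straight cycle is linearly resampled onto ``n_samples`` points of
    normalized stride time [0, 1] and averaged per sample and axis.
    """
    if strides.straight is None or not strides.straight.any():
        raise ValidationError("no straight strides to average")
    grid = np.linspace(0.0, 1.0, n_samples)
    acc = {"ap": segment_acc.ap, "ml": segment_acc.ml, "v": segment_acc.v}
    sums = {k: np.zeros(n_samples) for k in acc}
    count = 0
    for i in np.nonzero(strides.straight)[0]:
        s, e = strides.heel_strikes[i], strides.heel_strikes[i + 1]
        ts = s + grid * (e - s)
        for k, x in acc.items():
            sums[k] += np.interp(ts, segment_acc.time, x)
        count += 1
    return AverageCycle(
        segment=segment,
        normalized_time=grid,
        acc_ap=sums["ap"] / count,
        acc_ml=sums["ml"] / count,
        acc_v=sums["v"] / count,
        n_cycles=count,
    )


def bobbing_frequency(
    cycle: AverageCycle,
    stride_duration: float,
    n_tiles: int = 64,
) -> Tuple[float, float]:
    """Peak spectral frequency (Hz) and power of the vertical average cycle.

    The mean-removed average cycle is periodically extended (tiled
    ``n_tiles`` times) before the discrete Fourier transform, giving a
    frequency resolution of ``1 / (n_tiles x stride_duration)`` — 0.016 Hz
    for a 1 s stride — while the exact periodicity of the tiled signal
    needs no window.  ``stride_duration`` (the mean straight-stride
    duration) maps normalized cycle samples back to seconds.  For
    symmetric gait the peak sits at twice the stride rate (one vertical
    bob per step).
    """
    if stride_duration <= 0:
        raise ValidationError("stride_duration must be positive")
    v = cycle.acc_v - np.mean(cycle.acc_v)
    if np.max(np.abs(v)) < 1e-12:
        raise DegenerateInputError("flat vertical cycle; no spectral peak")
    x = np.tile(v, n_tiles)
    coeffs = np.fft.rfft(x)
    power = np.abs(coeffs) ** 2 / len(x)
    freqs = np.fft.rfftfreq(len(x), d=stride_duration / len(v))
    k = 1 + int(np.argmax(power[1:]))  # skip the (zero) DC bin
    return float(freqs[k]), float(power[k])


def amplitude_ranges(cycle: AverageCycle) -> Tuple[float, float, float]:
    """(AP, ML, V) max-minus-min of the average-cycle traces, m/s^2."""
    return (
        float(np.ptp(cycle.acc_ap)),
        float(np.ptp(cycle.acc_ml)),
        float(np.ptp(cycle.acc_v)),
    )


def stabilization_summary(
    cycle: AverageCycle,
    stride_duration: float,
) -> StabilizationSummary:
    """Bundle bobbing frequency and amplitude ranges for one segment."""
    freq, power = bobbing_frequency(cycle, stride_duration)
    r_ap, r_ml, r_v = amplitude_ranges(cycle)
    return StabilizationSummary(
        segment=cycle.segment,
        bobbing_frequency=freq,
        peak_power=power,
        range_ap=r_ap,
        range_ml=r_ml,
        range_v=r_v,
    )
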