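"""End-to-end session processing: raw three-sensor recordings to metrics.

The stages mirror the instrumented-TUG/walking workflow: synchronize the
sensors on the event-log clock via the magnetometer pulse, repair missing
samples onto a uniform grid, low-pass filter (4th-order 5 Hz Butterworth,
zero-phase), estimate orientation (recorded quaternions when available,
accelerometer/gyro fusion otherwise), heading-align using the quiet-stance
reference, detect heel strikes from the ankle jerk, select straight
strides, double-integrate the trunk AP acceleration per trial for stride
lengths and walking speed, and summarize head/trunk stabilization from
the average cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import numpy as np

from .errors import ValidationError
from .events import (
    auto_threshold,
    detect_foot_flat,
    detect_heel_strikes,
    segment_strides,
    select_straight_cycles,
)
from .io import interpolate_missing, lowpass, synchronize_session
from .metrics import (
    average_cycle,
    integrate_displacement,
    stride_lengths_from_displacement,
    stabilization_summary,
    summarize_gait,
)
from .orientation import (
    fuse_orientation,
    global_yaw_rate,
    heading_correction,
    quiet_stance_orientation,
    to_heading_frame,
    track_from_quats,
)
from .types import (
    AverageCycle,
    DisplacementTrack,
    EventLog,
    FootFlatMask,
    GaitSummary,
    HeadingFrameAcceleration,
    ImuRecording,
    StabilizationSummary,
    StrideSet,
    SyncedSession,
)

__all__ = ["PipelineConfig", "PreparedSession", "SessionResult", "prepare_session", "process_session"]


@dataclass
class PipelineConfig:
    """Tunable pipeline parameters (defaults follow the standard workflow)."""

    sync_method: str = "pulse"
    filter_cutoff_hz: float = 5.0
    filter_order: int = 4
    footflat_cutoff_hz: float = 3.0
    footflat_order: int = 2
    foot_flat_threshold: Optional[float] = None  # None -> auto_threshold
    min_peak_height: Optional[float] = None  # None -> per-period relative rule
    turn_threshold_dps: float = 30.0
    n_cycle_samples: int = 100
    fusion_gain: float = 0.1
    use_recorded_quats: bool = True
    detrend: Optional[str] = "mean"


@dataclass
class SessionResult:
    """Everything the pipeline computed for one session of one task."""

    session: SyncedSession
    heading: Dict[str, HeadingFrameAcceleration]
    foot_flat: FootFlatMask
    strides: StrideSet
    stride_lengths: np.ndarray  # signed, NaN where no trial covers the stride
    displacement: List[DisplacementTrack]
    gait: GaitSummary
    cycles: Dict[str, AverageCycle]
    stabilization: Dict[str, StabilizationSummary]
    yaw_corrections: Dict[str, float]


def _resample(rec: ImuRecording, grid: np.ndarray) -> ImuRecording:
    def cols(x):
        return np.column_stack([np.interp(grid, rec.time, x[:, j]) for j in range(x.shape[1])])

    quat = None
    if rec.quat is not None:
        quat = cols(rec.quat)
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    return ImuRecording(
        site=rec.site,
        time=grid,
        acc=cols(rec.acc),
        gyro=cols(rec.gyro),
        mag=cols(rec.mag),
        quat=quat,
        nominal_rate=rec.nominal_rate,
        interpolated_fraction=rec.interpolated_fraction,
    )


@dataclass
class PreparedSession:
    """Output of the preparation stages: synchronized, repaired, filtered,
    orientation-tracked and heading-aligned streams on one uniform grid."""

    synced: SyncedSession
    grid: np.ndarray
    rate: float
    heading: Dict[str, HeadingFrameAcceleration]
    tracks: Dict[str, object]
    gyro_filtered: Dict[str, np.ndarray]
    yaw_corrections: Dict[str, float]


def prepare_session(
    recordings: Mapping[str, ImuRecording],
    events: EventLog,
    config: Optional[PipelineConfig] = None,
) -> PreparedSession:
    """Run the signal-conditioning front end of the pipeline.

    Synchronizes the sensors on the event-log clock, repairs dropped
    samples, resamples everything onto one uniform grid, low-pass filters
    the motion channels, builds orientation tracks and expresses each
    sensor's acceleration in the heading frame.
    """
    cfg = config or PipelineConfig()
    for site in ("head", "trunk", "ankle"):
        if site not in recordings:
            raise ValidationError(f"missing recording for site {site!r}")
    rate = recordings["trunk"].nominal_rate

    # 1. synchronize on the event-log clock, 2. repair gaps
    synced = synchronize_session(recordings, events, method=cfg.sync_method)
    recs = {s: interpolate_missing(r) for s, r in synced.recordings.items()}

    # 3. common uniform grid over the overlap of all three sensors
    t0 = max(r.time[0] for r in recs.values())
    t1 = min(r.time[-1] for r in recs.values())
    ref = recs["trunk"].time
    k0 = int(np.ceil((t0 - ref[0]) * rate - 1e-9))
    k1 = int(np.floor((t1 - ref[0]) * rate + 1e-9))
    grid = ref[0] + np.arange(k0, k1 + 1) / rate
    recs = {s: _resample(r, grid) for s, r in recs.items()}

    # 4. zero-phase low-pass of the motion channels
    filt_acc = {s: lowpass(r.acc, cfg.filter_cutoff_hz, rate, cfg.filter_order) for s, r in recs.items()}
    filt_gyro = {s: lowpass(r.gyro, cfg.filter_cutoff_hz, rate, cfg.filter_order) for s, r in recs.items()}

    # 5. orientation tracks (fusion runs on the raw repaired signals: the
    # zero-phase filter is non-causal and would leak motion backward in
    # time into the quasi-static gate)
    tracks = {}
    for s, r in recs.items():
        if cfg.use_recorded_quats and r.quat is not None:
            tracks[s] = track_from_quats(grid, r.quat)
        else:
            tracks[s] = fuse_orientation(grid, r.acc, r.gyro, gain=cfg.fusion_gain)

    # 6. quiet-stance reference and heading correction per sensor
    quiet = events.quiet_windows()
    if not quiet:
        raise ValidationError("event log contains no quiet-stance window")
    yaw_corr = {}
    for s in recs:
        q_ref = quiet_stance_orientation(tracks[s], quiet[0])
        yaw_corr[s] = heading_correction(q_ref)

    # 7. heading-frame accelerations
    heading = {
        s: to_heading_frame(grid, filt_acc[s], tracks[s], yaw_corr[s]) for s in recs
    }
    return PreparedSession(synced, grid, rate, heading, tracks, filt_gyro, yaw_corr)


def process_session(
    recordings: Mapping[str, ImuRecording],
    events: EventLog,
    task: str = "walk",
    config: Optional[PipelineConfig] = None,
) -> SessionResult:
    """Run the full pipeline on one session.

    ``recordings`` must contain ``head``, ``trunk`` and ``ankle`` entries on
    their raw per-sensor clocks; ``events`` lives on the reference clock and
    must contain one sync entry, one quiet window and start/stop pairs.
    ``task`` is ``"tug"`` or ``"walk"`` (controls the TUG-duration metric).
    """
    cfg = config or PipelineConfig()
    prep = prepare_session(recordings, events, cfg)
    grid, rate, heading = prep.grid, prep.rate, prep.heading
    synced, tracks, filt_gyro = prep.synced, prep.tracks, prep.gyro_filtered
    yaw_corr = prep.yaw_corrections

    # 8. foot-flat mask and heel strikes from the ankle
    ankle_mag = heading["ankle"].magnitude()
    thr = cfg.foot_flat_threshold
    if thr is None:
        thr = auto_threshold(
            ankle_mag, rate, cutoff_hz=cfg.footflat_cutoff_hz, order=cfg.footflat_order
        )
    mask = detect_foot_flat(
        grid, ankle_mag, rate, thr,
        cutoff_hz=cfg.footflat_cutoff_hz, order=cfg.footflat_order,
    )
    strikes = detect_heel_strikes(
        grid, heading["ankle"].ap, mask, rate, min_peak_height=cfg.min_peak_height
    )

    # 9. strides + straight-cycle selection on the trunk yaw rate
    strides = segment_strides(strikes, source_task=task)
    yaw_rate = global_yaw_rate(tracks["trunk"], filt_gyro["trunk"])
    strides = select_straight_cycles(
        strides, grid, yaw_rate, rate, turn_threshold_dps=cfg.turn_threshold_dps
    )

    # 10. per-trial displacement and stride lengths
    lengths = np.full(strides.n_strides, np.nan)
    tracks_out: List[DisplacementTrack] = []
    for bounds in events.trials():
        dtrack = integrate_displacement(
            grid, heading["trunk"].ap, rate, bounds, detrend=cfg.detrend
        )
        inside = np.nonzero(
            (strides.intervals[:, 0] >= bounds[0]) & (strides.intervals[:, 1] <= bounds[1])
        )[0]
        if len(inside):
            # negative lengths are expected on anti-heading legs (TUG/loop
            # returns); the summary uses magnitudes
            lengths[inside] = stride_lengths_from_displacement(
                dtrack, strides, inside, warn_negative=False
            )
        tracks_out.append(dtrack)

    measurable = strides.straight & np.isfinite(lengths)
    strides = StrideSet(strides.heel_strikes, strides.valid, measurable, task)

    # 11. summaries
    gait = summarize_gait(strides, np.nan_to_num(lengths), events=events, task=task)
    mean_dur = float(np.mean(gait.stride_durations))
    cycles = {}
    stab = {}
    for s in ("head", "trunk"):
        cycles[s] = average_cycle(heading[s], strides, cfg.n_cycle_samples, segment=s)
        stab[s] = stabilization_summary(cycles[s], mean_dur)

    return SessionResult(
        session=synced,
        heading=heading,
        foot_flat=mask,
        strides=strides,
        stride_lengths=lengths,
        displacement=tracks_out,
        gait=gait,
        cycles=cycles,
        stabilization=stab,
        yaw_corrections=yaw_corr,
    )
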