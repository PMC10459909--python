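"""Seeded synthetic IMU walking / timed-up-and-go sessions with ground truth.

The generator emits what the analysis pipeline assumes about real recordings:

* three body-site sensors (head, trunk, right ankle) sampled at a common
  nominal rate (50 Hz), each stream expressed in its own local frame after a
  mounting rotation, a small mounting tilt and an injected yaw misalignment;
* trunk/head translational acceleration built from an analytic
  ramp-cruise-ramp velocity profile per walking segment (so the double
  integral of the emitted AP acceleration equals the scripted path length by
  construction) plus harmonic gait components: vertical and anteroposterior
  at step frequency, mediolateral at stride frequency — the vertical
  component peaks twice per stride, which is the "bobbing" signature;
* head harmonics attenuated relative to the trunk by a per-axis shared
  factor, modelling the trunk-to-head shock-absorber behaviour;
* an ankle stream with a foot-flat stance plateau (near-zero gravity-free
  acceleration) and a swing-phase plateau bounded by two sharp transitions,
  so the absolute jerk shows exactly two dominant spikes per swing: toe off
  first, heel strike second;
* one sub-sample-duration magnetometer pulse shared by all sensors for
  synchronization, per-sensor clock offsets, and a small fraction of
  dropped samples (timestamp gaps);
* an event log (quiet stance, start, stop, turns, sync) on the true clock,
  and a :class:`GroundTruth` record used as the oracle by the test-suite.

Transitions (sit-to-stand, turns) are low-frequency ramps and yaw-rate
pulses — enough structure to exercise cycle exclusion, with no claim of
biomechanical fidelity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .types import GRAVITY, EventLog, ImuRecording

__all__ = [
    "GaitProfile",
    "TaskScript",
    "GroundTruth",
    "SimulatedSession",
    "simulate_session",
    "save_session",
]

#: Nominal mounting rotation (columns = global coordinates of the local
#: axes): local Z points along the heading (global +Y), local Y points up.
_R_MOUNT_NOMINAL = np.array(
    [
        [-1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 1.0, 0.0],
    ]
)

#: Constant ambient magnetic field in the global frame (arbitrary units,
#: magnitude ~1 so the sync pulse is >=10x the baseline scatter).
_MAG_GLOBAL = np.array([0.45, 0.85, -0.30])


@dataclass
class GaitProfile:
    """Ground-truth gait parameters of a synthetic walker.

    Defaults describe a healthy adult at habitual pace (speed
    stride_length / stride_duration = 1.1 m/s).  Amplitudes are
    peak-to-peak values of the harmonic components in m/s^2; trunk vertical
    and AP components oscillate at step frequency (2 / stride_duration),
    the ML component at stride frequency.  ``head_attenuation`` scales all
    head harmonic amplitudes relative to the trunk.  Positive
    ``yaw_misalignment_deg`` yaws a sensor clockwise (seen from above) away
    from the heading direction.
    """

    stride_duration: float = 1.0
    stride_length: float = 1.1
    trunk_amp_v: float = 3.0
    trunk_amp_ap: float = 1.5
    trunk_amp_ml: float = 1.0
    head_attenuation: float = 0.8
    noise_sd: float = 0.15
    yaw_misalignment_deg: float = 5.0
    # secondary signal-shape knobs (not swept by the study conditions)
    swing_amplitude: float = 3.0
    stance_fraction: float = 0.6
    step_sharpness: float = 0.012
    mount_tilt_deg: float = 3.0
    drop_fraction: float = 0.005
    gyro_noise_sd: float = 0.01
    mag_noise_sd: float = 0.02
    quat_noise_deg: float = 0.3

    @property
    def step_frequency(self) -> float:
        """Steps per second; 2 / stride_duration for symmetric gait."""
        return 2.0 / self.stride_duration

    @property
    def speed(self) -> float:
        return self.stride_length / self.stride_duration

    def validate(self) -> "GaitProfile":
        if self.stride_duration <= 0 or self.stride_length <= 0:
            raise ValidationError("stride_duration and stride_length must be > 0")
        if not (0.0 < self.head_attenuation <= 1.0):
            raise ValidationError("head_attenuation must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0.0 < self.stance_fraction < 1.0):
            raise ValidationError("stance_fraction must lie in (0, 1)")
        return self

    def noise_free(self) -> "GaitProfile":
        """Copy with every stochastic disturbance switched off."""
        return dataclasses.replace(
            self,
            noise_sd=0.0,
            drop_fraction=0.0,
            gyro_noise_sd=0.0,
            mag_noise_sd=0.0,
            quat_noise_deg=0.0,
        )


@dataclass
class TaskScript:
    """Task timeline: kind, geometry and repeat structure.

    ``tug``: sit quietly, stand, walk ``path_length`` (3 m), 180-degree
    turn, walk back, sit.  ``loop_walk``: stand quietly then walk between
    two floor lines ``path_length`` (4 m) apart, turning three times (four
    straight passes).  ``straight_walk``: a single ``path_length`` (7 m)
    straight pass.  Repeats are separate trials, each with its own quiet
    period and start/stop events.
    """

    task_kind: str
    path_length: float
    repeats: int
    quiet_period: float = 5.0
    turn_gap: float = 1.2
    transition_duration: float = 1.5
    rest_between: float = 2.0

    @classmethod
    def tug(cls, path_length: float = 3.0, repeats: int = 3, **kw) -> "TaskScript":
        return cls("tug", path_length, repeats, **kw)

    @classmethod
    def loop_walk(cls, path_length: float = 4.0, repeats: int = 2, **kw) -> "TaskScript":
        return cls("loop_walk", path_length, repeats, **kw)

    @classmethod
    def straight_walk(cls, path_length: float = 7.0, repeats: int = 2, **kw) -> "TaskScript":
        return cls("straight_walk", path_length, repeats, **kw)

    @property
    def n_passes(self) -> int:
        return {"tug": 2, "loop_walk": 4, "straight_walk": 1}[self.task_kind]

    def validate(self) -> "TaskScript":
        if self.task_kind not in ("tug", "loop_walk", "straight_walk"):
            raise ValidationError(f"unknown task kind {self.task_kind!r}")
        if self.path_length <= 0:
            raise ValidationError("path_length must be > 0")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")
        if self.quiet_period < 1.5:
            raise ValidationError("quiet_period must be >= 1.5 s")
        return self


@dataclass
class GroundTruth:
    """Everything the pipeline is supposed to recover, plus bookkeeping."""

    time: np.ndarray
    heel_strike_times: np.ndarray
    per_stride_lengths: np.ndarray
    per_stride_speeds: np.ndarray
    straight_cycle_flags: np.ndarray
    injected_sync_offsets: Dict[str, float]
    injected_yaw_deg: Dict[str, float]
    turn_intervals: List[Tuple[float, float]]
    stance_intervals: List[Tuple[float, float]]
    walk_segments: List[Tuple[float, float, float, int]]
    trial_bounds: List[Tuple[float, float]]
    tug_duration: Optional[float]
    stride_duration: float
    step_frequency: float
    sync_pulse_time: float
    heading_acc: Dict[str, Dict[str, np.ndarray]]
    velocity_ap: np.ndarray
    displacement_ap: np.ndarray

    def validate(self) -> "GroundTruth":
        if np.any(np.diff(self.heel_strike_times) <= 0):
            raise ValidationError("heel-strike times must be strictly increasing")
        iv = np.diff(self.heel_strike_times)
        ok = self.per_stride_lengths[iv > 0] / iv[iv > 0]
        if not np.allclose(ok, self.per_stride_speeds[iv > 0], rtol=1e-9, atol=1e-12):
            raise ValidationError("per-stride speeds inconsistent with lengths")
        return self


@dataclass
class SimulatedSession:
    """Bundle returned by :func:`simulate_session`."""

    profile: GaitProfile
    script: TaskScript
    recordings: Dict[str, ImuRecording]
    events: EventLog
    truth: GroundTruth


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _smoothstep_d(u: np.ndarray) -> np.ndarray:
    inside = (u > 0.0) & (u < 1.0)
    u = np.clip(u, 0.0, 1.0)
    return np.where(inside, 6.0 * u * (1.0 - u), 0.0)


@dataclass
class _WalkPhase:
    t0: float
    t1: float
    path: float
    sign: int
    v0: float
    t_ramp: float
    t_cruise: float


def _plan_trial(script: TaskScript, profile: GaitProfile, t0: float):
    """Lay out one trial; returns phase bookkeeping and the end time."""
    v0 = profile.speed
    t_ramp = profile.stride_duration / 2.0
    t_cruise = script.path_length / v0 - t_ramp
    if t_cruise <= 0:
        raise ValidationError(
            f"path_length {script.path_length} m too short for one "
            f"ramp-cruise-ramp segment at speed {v0:.2f} m/s"
        )
    walk_T = 2 * t_ramp + t_cruise

    events: List[Tuple[float, str]] = []
    walks: List[_WalkPhase] = []
    transitions: List[Tuple[float, float, int]] = []  # (t0, t1, sign of vertical)
    turns: List[Tuple[float, float, int]] = []  # yaw window (t0, t1, sign)

    cursor = t0
    events.append((cursor, "quiet_start"))
    cursor += script.quiet_period
    events.append((cursor, "quiet_end"))

    if script.task_kind == "tug":
        events.append((cursor, "start"))
        transitions.append((cursor, cursor + script.transition_duration, +1))
        cursor += script.transition_duration
    else:
        events.append((cursor + 0.5, "start"))
        cursor += 1.0

    sign = +1
    for i in range(script.n_passes):
        walks.append(
            _WalkPhase(cursor, cursor + walk_T, script.path_length, sign, v0, t_ramp, t_cruise)
        )
        cursor += walk_T
        if i < script.n_passes - 1:
            # turn anticipation: the body starts rotating while decelerating
            # into the turn and keeps rotating through the first accelerating
            # steps out of it, so the yaw window spans both ramps
            turns.append(
                (cursor - 2 * t_ramp, cursor + script.turn_gap + 2 * t_ramp, -1 if i % 2 else 1)
            )
            cursor += script.turn_gap
            sign = -sign

    if script.task_kind == "tug":
        cursor += 0.3
        transitions.append((cursor, cursor + script.transition_duration, -1))
        cursor += script.transition_duration
        events.append((cursor, "stop"))
    else:
        events.append((cursor + 0.5, "stop"))
        cursor += 1.0

    cursor += script.rest_between
    return walks, transitions, turns, events, cursor


def _turn_core(window: Tuple[float, float, int], peak_rate: float, thr_dps: float = 30.0):
    """Sub-interval of a yaw window where |yaw rate| exceeds thr_dps."""
    t0, t1, _ = window
    w = t1 - t0
    c = np.deg2rad(thr_dps) / peak_rate
    if c >= 1.0:
        return None
    u0 = np.arcsin(np.sqrt(c)) / np.pi
    return (t0 + u0 * w, t1 - u0 * w)


def simulate_session(
    profile: GaitProfile,
    script: TaskScript,
    seed: int,
    *,
    rate_hz: float = 50.0,
    sync_offsets: Optional[Dict[str, float]] = None,
    include_quats: bool = True,
) -> SimulatedSession:
    """Generate one synthetic three-sensor session.

    Parameters
    ----------
    profile, script
        Gait parameters and task timeline; validated on entry.
    seed
        Seed for every stochastic element (noise, drops, default offsets).
        Same seed and configuration give bit-identical output.
    rate_hz
        Nominal sampling rate of all sensors.
    sync_offsets
        Per-site clock offsets in seconds added to each sensor's
        timestamps.  ``None`` draws offsets uniformly from [-0.5, 0.5] s.
    include_quats
        Emit the acquisition-software orientation quaternion channel
        (true attitude plus small jitter).
    """
    profile.validate()
    script.validate()
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    sd = profile.stride_duration

    # ---- timeline ---------------------------------------------------------
    walks: List[_WalkPhase] = []
    transitions: List[Tuple[float, float, int]] = []
    yaw_windows: List[Tuple[float, float, int]] = []
    events: List[Tuple[float, str]] = []
    bouts: List[Tuple[float, float]] = []
    cursor = 1.0
    for _ in range(script.repeats):
        w, tr, tu, ev, cursor = _plan_trial(script, profile, cursor)
        walks += w
        transitions += tr
        yaw_windows += tu
        events += ev
        bouts.append((w[0].t0, w[-1].t1))
    total = cursor + 1.0

    n = int(round(total * rate_hz)) + 1
    t = np.arange(n) * dt

    # ---- base locomotion (analytic velocity, trapezoid displacement) ------
    a_base = np.zeros(n)
    v_base = np.zeros(n)
    for wp in walks:
        idx = (t >= wp.t0) & (t <= wp.t1)
        tau = t[idx] - wp.t0
        a = np.zeros_like(tau)
        v = np.zeros_like(tau)
        u1 = tau / wp.t_ramp
        r1 = tau < wp.t_ramp
        v[r1] = wp.v0 * _smoothstep(u1[r1])
        a[r1] = wp.v0 * _smoothstep_d(u1[r1]) / wp.t_ramp
        r2 = (tau >= wp.t_ramp) & (tau <= wp.t_ramp + wp.t_cruise)
        v[r2] = wp.v0
        u3 = (tau - wp.t_ramp - wp.t_cruise) / wp.t_ramp
        r3 = tau > wp.t_ramp + wp.t_cruise
        v[r3] = wp.v0 * (1.0 - _smoothstep(u3[r3]))
        a[r3] = -wp.v0 * _smoothstep_d(u3[r3]) / wp.t_ramp
        a_base[idx] += wp.sign * a
        v_base[idx] = wp.sign * v

    # ---- yaw-rate pulses (turns) ------------------------------------------
    yaw_rate = np.zeros(n)
    turn_cores: List[Tuple[float, float]] = []
    for win in yaw_windows:
        t0w, t1w, sgn = win
        w = t1w - t0w
        peak = 2.0 * np.pi / w  # 180 degrees total rotation
        idx = (t >= t0w) & (t <= t1w)
        u = (t[idx] - t0w) / w
        yaw_rate[idx] += sgn * peak * np.sin(np.pi * u) ** 2
        core = _turn_core(win, peak)
        if core is not None:
            turn_cores.append(core)

    # ---- vertical transition ramps (sit-to-stand / stand-to-sit) ----------
    a_trans_v = np.zeros(n)
    for t0s, t1s, sgn in transitions:
        idx = (t >= t0s) & (t <= t1s)
        u = (t[idx] - t0s) / (t1s - t0s)
        a_trans_v[idx] += sgn * 2.0 * np.sin(2.0 * np.pi * u)

    # ---- harmonic gait components -----------------------------------------
    f_step = profile.step_frequency
    t_ramp = sd / 2.0
    env = np.zeros(n)
    phase = np.zeros(n)
    for b0, b1 in bouts:
        idx = (t >= b0) & (t <= b1)
        tb = t[idx]
        env[idx] = _smoothstep((tb - b0) / t_ramp) * _smoothstep((b1 - tb) / t_ramp)
        phase[idx] = tb - b0
    h_ap = env * (profile.trunk_amp_ap / 2.0) * np.sin(2.0 * np.pi * f_step * phase)
    h_v = env * (profile.trunk_amp_v / 2.0) * np.sin(2.0 * np.pi * f_step * phase)
    h_ml = env * (profile.trunk_amp_ml / 2.0) * np.sin(np.pi * f_step * phase)

    # Remove the per-trial linear fit of the AP harmonic so it contributes
    # no net velocity or displacement over the integration bounds.
    ev_log = EventLog(sorted(events)).validate()
    trial_bounds = ev_log.trials()
    for t0b, t1b in trial_bounds:
        idx = (t >= t0b) & (t <= t1b)
        if idx.sum() < 2:
            continue
        A = np.column_stack([np.ones(idx.sum()), t[idx]])
        coef, *_ = np.linalg.lstsq(A, h_ap[idx], rcond=None)
        h_ap[idx] -= A @ coef

    # ---- trunk/head global gravity-free accelerations ---------------------
    att = profile.head_attenuation
    acc_global = {
        "trunk": np.column_stack([h_ml, a_base + h_ap, h_v + a_trans_v]),
        "head": np.column_stack([att * h_ml, a_base + att * h_ap, att * h_v + a_trans_v]),
    }

    # ---- ground-truth trunk kinematics ------------------------------------
    v_gt = v_base + cumulative_trapezoid(h_ap, t, initial=0.0)
    d_gt = cumulative_trapezoid(v_gt, t, initial=0.0)

    # ---- heel strikes, stance intervals, ankle swing signal ----------------
    strikes: List[float] = []
    stance: List[Tuple[float, float]] = []
    bout_stride_ranges: List[Tuple[int, int]] = []  # [i0, i1) stride indices
    ankle_ap = np.zeros(n)
    tau_s = profile.step_sharpness
    for b0, b1 in bouts:
        n_str = int(np.floor((b1 - b0) / sd))
        if n_str < 1:
            raise ValidationError("gait bout shorter than one stride")
        # cadence instants: k=0 is gait onset (foot already on the floor,
        # no swing, no jerk spike — not a heel strike); the walker keeps
        # striding through the deceleration, so the final strike lands at
        # the stop point, as either an extra shortened stride or a stretch
        # of the last cadence stride
        cadence = b0 + sd * np.arange(n_str + 1)
        if b1 - cadence[-1] >= 0.3 * sd:
            cadence = np.append(cadence, b1)
        else:
            cadence[-1] = b1
        bout_stride_ranges.append((len(strikes), len(strikes) + len(cadence) - 2))
        strikes += list(cadence[1:])
        for k in range(len(cadence)):
            hs = cadence[k]
            if k + 1 < len(cadence):
                t_to = hs + profile.stance_fraction * (cadence[k + 1] - hs)
                t_hs = cadence[k + 1]
                stance.append((hs, t_to))
                idx = (t > t_to - 8 * tau_s) & (t < t_hs + 8 * tau_s)
                up = 0.5 * (1.0 + np.tanh((t[idx] - t_to) / tau_s))
                dn = 0.5 * (1.0 + np.tanh((t[idx] - t_hs) / tau_s))
                ankle_ap[idx] += profile.swing_amplitude * (up - dn)
            else:
                stance.append((hs, hs + profile.stance_fraction * sd))
    heel_strikes = np.asarray(strikes)
    acc_global["ankle"] = np.column_stack([np.zeros(n), ankle_ap, np.zeros(n)])

    # ---- per-stride ground truth ------------------------------------------
    d_at_strikes = np.interp(heel_strikes, t, d_gt)
    iv = np.diff(heel_strikes)
    lengths = np.abs(np.diff(d_at_strikes))
    speeds = np.where(iv > 0, lengths / np.where(iv > 0, iv, 1.0), 0.0)

    # A stride counts as steady straight walking when it lies entirely in
    # the cruise portion of one walking pass and is neither the first nor
    # the last stride of its gait bout (initiation / termination cycles,
    # which a manual reviewer would also exclude).
    straight = np.zeros(len(heel_strikes) - 1, dtype=bool)
    for i in range(len(straight)):
        s, e = heel_strikes[i], heel_strikes[i + 1]
        for wp in walks:
            if s >= wp.t0 + wp.t_ramp and e <= wp.t1 - wp.t_ramp:
                straight[i] = True
                break
    for i0, i1 in bout_stride_ranges:
        if i1 > i0:
            straight[i0] = False
            straight[i1 - 1] = False

    # ---- sensor-local measurements ----------------------------------------
    if sync_offsets is None:
        sync_offsets = {
            site: float(rng.uniform(-0.5, 0.5)) for site in ("head", "trunk", "ankle")
        }
    yaw_mis = {
        "head": profile.yaw_misalignment_deg,
        "trunk": profile.yaw_misalignment_deg,
        "ankle": profile.yaw_misalignment_deg,
    }

    pulse_time = ev_log.quiet_windows()[0]
    pulse_time = round((0.5 * (pulse_time[0] + pulse_time[1])) * rate_hz) / rate_hz
    pulse_idx = int(round(pulse_time * rate_hz))
    events.append((pulse_time, "sync"))
    ev_log = EventLog(sorted(events)).validate()

    omega_global = np.column_stack([np.zeros(n), np.zeros(n), yaw_rate])
    g_vec = np.array([0.0, 0.0, GRAVITY])

    recordings: Dict[str, ImuRecording] = {}
    for site in ("head", "trunk", "ankle"):
        tilt = Rotation.from_rotvec([np.deg2rad(profile.mount_tilt_deg), 0.0, 0.0])
        r_mount = Rotation.from_matrix(_R_MOUNT_NOMINAL) * tilt
        r_att = Rotation.from_rotvec([0.0, 0.0, -np.deg2rad(yaw_mis[site])]) * r_mount
        r_inv = r_att.inv()

        acc_local = r_inv.apply(acc_global[site] + g_vec)
        gyro_local = r_inv.apply(omega_global)
        mag_local = np.tile(r_inv.apply(_MAG_GLOBAL), (n, 1))
        mag_local[pulse_idx] += 5.0 / np.sqrt(3.0)

        if profile.noise_sd > 0:
            acc_local = acc_local + rng.normal(0.0, profile.noise_sd, (n, 3))
        if profile.gyro_noise_sd > 0:
            gyro_local = gyro_local + rng.normal(0.0, profile.gyro_noise_sd, (n, 3))
        if profile.mag_noise_sd > 0:
            mag_local = mag_local + rng.normal(0.0, profile.mag_noise_sd, (n, 3))

        quat = None
        if include_quats:
            if profile.quat_noise_deg > 0:
                jit = Rotation.from_rotvec(
                    rng.normal(0.0, np.deg2rad(profile.quat_noise_deg), (n, 3))
                )
                q = (jit * r_att).as_quat()
            else:
                q = np.tile(r_att.as_quat(), (n, 1))
            # hemisphere continuity
            flips = np.cumsum(np.sum(q[1:] * q[:-1], axis=1) < 0) % 2
            q[1:][flips == 1] *= -1.0
            quat = q

        time_s = t + sync_offsets[site]
        keep = np.ones(n, dtype=bool)
        if profile.drop_fraction > 0:
            eligible = np.ones(n, dtype=bool)
            eligible[[0, n - 1]] = False
            eligible[max(pulse_idx - 2, 0) : pulse_idx + 3] = False
            k = int(round(profile.drop_fraction * n))
            if k > 0:
                drop = rng.choice(np.nonzero(eligible)[0], size=k, replace=False)
                keep[drop] = False

        recordings[site] = ImuRecording(
            site=site,
            time=time_s[keep],
            acc=acc_local[keep],
            gyro=gyro_local[keep],
            mag=mag_local[keep],
            quat=quat[keep] if quat is not None else None,
            nominal_rate=rate_hz,
        ).validate()

    tug_duration = None
    if script.task_kind == "tug":
        tug_duration = float(np.mean([b - a for a, b in trial_bounds]))

    truth = GroundTruth(
        time=t,
        heel_strike_times=heel_strikes,
        per_stride_lengths=lengths,
        per_stride_speeds=speeds,
        straight_cycle_flags=straight,
        injected_sync_offsets=dict(sync_offsets),
        injected_yaw_deg=dict(yaw_mis),
        turn_intervals=turn_cores,
        stance_intervals=stance,
        walk_segments=[(w.t0, w.t1, w.path, w.sign) for w in walks],
        trial_bounds=trial_bounds,
        tug_duration=tug_duration,
        stride_duration=sd,
        step_frequency=f_step,
        sync_pulse_time=pulse_time,
        heading_acc={
            site: {
                "ml": acc_global[site][:, 0],
                "ap": acc_global[site][:, 1],
                "v": acc_global[site][:, 2],
            }
            for site in acc_global
        },
        velocity_ap=v_gt,
        displacement_ap=d_gt,
    ).validate()

    return SimulatedSession(profile, script, recordings, ev_log, truth)


def save_session(sim: SimulatedSession, outdir) -> None:
    """Write per-sensor CSV logs, an events CSV and a ground-truth sidecar.

    The sidecar carries the scalar and per-stride truth (not the full
    per-sample traces, which are reproducible from the seed).
    """
    from pathlib import Path

    from .io import write_events_csv, write_imu_log

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for site, rec in sim.recordings.items():
        write_imu_log(rec, outdir / f"{site}.csv")
    write_events_csv(sim.events, outdir / "events.csv")
    tr = sim.truth
    sidecar = {
        "heel_strike_times": tr.heel_strike_times.tolist(),
        "per_stride_lengths": tr.per_stride_lengths.tolist(),
        "per_stride_speeds": tr.per_stride_speeds.tolist(),
        "straight_cycle_flags": tr.straight_cycle_flags.astype(int).tolist(),
        "injected_sync_offsets": tr.injected_sync_offsets,
        "injected_yaw_deg": tr.injected_yaw_deg,
        "turn_intervals": tr.turn_intervals,
        "trial_bounds": tr.trial_bounds,
        "tug_duration": tr.tug_duration,
        "stride_duration": tr.stride_duration,
        "step_frequency": tr.step_frequency,
        "sync_pulse_time": tr.sync_pulse_time,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
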