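"""Integration, stride metrics, average cycles and spectral measures."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

import imugait as ig
from imugait.errors import DegenerateInputError, IntegrationError, ValidationError
from imugait.types import AverageCycle, DisplacementTrack, HeadingFrameAcceleration, StrideSet

RATE = 50.0


class TestDirectReverseIntegrate:
    def test_all_zero_in_all_zero_out(self):
        out = ig.direct_reverse_integrate(np.zeros(100), RATE)
        assert np.all(out == 0.0)

    def test_sine_matches_analytic_antiderivative(self):
        # acc = sin(2 pi t) over 4 whole periods: velocity must follow
        # -cos(2 pi t)/(2 pi) + c and vanish at both ends
        t = np.arange(0, 4.0 + 1e-9, 1 / RATE)
        acc = np.sin(2 * np.pi * t)
        v = ig.direct_reverse_integrate(acc, RATE)
        expect = (1 - np.cos(2 * np.pi * t)) / (2 * np.pi)
        assert abs(v[0]) < 1e-12 and abs(v[-1]) < 1e-12
        assert np.sqrt(np.mean((v - expect) ** 2)) < 0.01 * np.sqrt(np.mean(expect**2))
        # displacement: plain integral of the corrected velocity
        d = cumulative_trapezoid(v, t, initial=0.0)
        expect_d = (t - np.sin(2 * np.pi * t) / (2 * np.pi)) / (2 * np.pi)
        assert np.sqrt(np.mean((d - expect_d) ** 2)) < 0.01 * np.sqrt(np.mean(expect_d**2))

    def test_equals_plain_integration_when_boundary_conditions_hold(self):
        # any signal whose true integral starts and ends at zero: the
        # direct-reverse blend must coincide with plain cumulative trapezoid
        rng = np.random.default_rng(5)
        t = np.arange(0, 6.0, 1 / RATE)
        v_true = np.zeros_like(t)
        for k in range(1, 5):
            v_true += rng.normal() * np.sin(np.pi * k * t / t[-1])
        acc = np.gradient(v_true, 1 / RATE)
        plain = cumulative_trapezoid(acc - acc.mean(), dx=1 / RATE, initial=0.0)
        dr = ig.direct_reverse_integrate(acc, RATE)
        assert np.allclose(dr, plain, atol=5e-3 * max(1.0, np.abs(v_true).max()))

    def test_constant_bias_fully_absorbed(self):
        out = ig.direct_reverse_integrate(np.full(200, 2.5), RATE)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_rejects_two_dimensional_input(self):
        with pytest.raises(ValidationError):
            ig.direct_reverse_integrate(np.zeros((10, 3)), RATE)


class TestStrideLengths:
    def _track(self, t, d):
        return DisplacementTrack(t, np.gradient(d, t), d, (t[0], t[-1]))

    def test_linear_displacement_gives_constant_lengths(self):
        t = np.arange(0, 10, 1 / RATE)
        track = self._track(t, 1.2 * t)
        strides = ig.segment_strides(np.arange(1.0, 9.0))
        lengths = ig.stride_lengths_from_displacement(track, strides)
        assert np.allclose(lengths, 1.2)

    def test_zero_displacement_zero_lengths(self):
        t = np.arange(0, 10, 1 / RATE)
        track = self._track(t, np.zeros_like(t))
        strides = ig.segment_strides(np.arange(1.0, 9.0))
        assert np.allclose(ig.stride_lengths_from_displacement(track, strides), 0.0)

    def test_stride_outside_bounds_rejected(self):
        t = np.arange(0, 5, 1 / RATE)
        track = self._track(t, t.copy())
        strides = ig.segment_strides([1.0, 2.0, 6.0], duration_band=(0.4, 10.0))
        with pytest.raises(IntegrationError):
            ig.stride_lengths_from_displacement(track, strides)

    def test_simulator_lengths_within_tolerance(self, walk_session, walk_result):
        gt = walk_session.truth
        det = walk_result.strides
        for i in np.nonzero(det.straight)[0]:
            j = int(np.argmin(np.abs(gt.heel_strike_times[:-1] - det.heel_strikes[i])))
            ref = gt.per_stride_lengths[j]
            assert abs(abs(walk_result.stride_lengths[i]) - ref) <= 0.10 * ref


class TestSummarize:
    def test_single_stride_speed_is_ratio(self):
        strides = StrideSet(np.array([0.0, 1.0]), np.array([True]), np.array([True]))
        summary = ig.summarize_gait(strides, np.array([1.2]))
        assert summary.walking_speed == pytest.approx(1.2)

    def test_tug_duration_is_mean_of_trials(self):
        entries = []
        for k, dur in enumerate([10.0, 11.0, 12.0]):
            t0 = 100.0 * k
            entries += [(t0, "start"), (t0 + dur, "stop")]
        events = ig.EventLog(sorted(entries)).validate()
        strides = StrideSet(np.array([0.0, 1.0]), np.array([True]), np.array([True]))
        summary = ig.summarize_gait(strides, np.array([1.2]), events=events, task="tug")
        assert summary.tug_duration == pytest.approx(11.0)

    def test_no_straight_strides_rejected(self):
        strides = StrideSet(np.array([0.0, 1.0]), np.array([True]), np.array([False]))
        with pytest.raises(ValidationError):
            ig.summarize_gait(strides, np.array([1.2]))

    def test_simulator_walking_speed(self, walk_session, walk_result):
        p = walk_session.profile
        assert walk_result.gait.walking_speed == pytest.approx(p.speed, rel=0.10)

    def test_simulator_tug_duration_matches_events(self, tug_session, tug_result):
        assert tug_result.gait.tug_duration == pytest.approx(
            tug_session.truth.tug_duration, abs=1e-9
        )


def _hfa_from_cycles(cycle_fn, n_cycles, stride_s=1.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(0, n_cycles * stride_s + 1e-9, 1 / RATE)
    phase = (t / stride_s) % 1.0
    sig = cycle_fn(phase)
    noise = rng.normal(0, noise_sd, (len(t), 3)) if noise_sd else np.zeros((len(t), 3))
    hfa = HeadingFrameAcceleration(t, sig + noise[:, 0], sig + noise[:, 1], sig + noise[:, 2])
    strikes = stride_s * np.arange(n_cycles + 1)
    strides = StrideSet(strikes, np.ones(n_cycles, bool), np.ones(n_cycles, bool))
    return hfa, strides


class TestAverageCycle:
    def test_identical_cycles_average_to_one_cycle(self):
        fn = lambda u: np.sin(2 * np.pi * u)
        hfa, strides = _hfa_from_cycles(fn, 6)
        cyc = ig.average_cycle(hfa, strides, n_samples=100)
        assert cyc.n_cycles == 6
        assert np.allclose(cyc.acc_v, np.sin(2 * np.pi * cyc.normalized_time), atol=0.01)

    def test_opposite_cycles_cancel(self):
        t = np.arange(0, 2.0 + 1e-9, 1 / RATE)
        sig = np.where(t < 1.0, np.sin(2 * np.pi * t), -np.sin(2 * np.pi * t))
        hfa = HeadingFrameAcceleration(t, sig, sig, sig)
        strides = StrideSet(np.array([0.0, 1.0, 2.0]), np.ones(2, bool), np.ones(2, bool))
        cyc = ig.average_cycle(hfa, strides, n_samples=50)
        assert np.allclose(cyc.acc_ap, 0.0, atol=0.02)

    def test_noise_shrinks_like_root_n_cycles(self):
        fn = lambda u: np.sin(2 * np.pi * u)

        def rms_err(n_cycles):
            errs = []
            for seed in range(12):
                hfa, strides = _hfa_from_cycles(fn, n_cycles, noise_sd=0.5, seed=seed)
                cyc = ig.average_cycle(hfa, strides, n_samples=50)
                ref = np.sin(2 * np.pi * cyc.normalized_time)
                errs.append(np.sqrt(np.mean((cyc.acc_v - ref) ** 2)))
            return np.mean(errs)

        ratio = rms_err(16) / rms_err(4)
        assert 0.3 < ratio < 0.75  # ~1/2 expected for 4x the cycles


class TestBobbingFrequency:
    def _cycle(self, v):
        n = len(v)
        return AverageCycle("trunk", np.linspace(0, 1, n), np.zeros(n), np.zeros(n), v, 4)

    def test_two_cycles_per_stride_at_one_second(self):
        u = np.linspace(0, 1, 100)
        f, power = ig.bobbing_frequency(self._cycle(np.sin(4 * np.pi * u)), 1.0)
        assert f == pytest.approx(2.0, abs=0.02)
        assert power > 0

    def test_one_cycle_per_stride_at_1p25_seconds(self):
        u = np.linspace(0, 1, 100)
        f, _ = ig.bobbing_frequency(self._cycle(np.sin(2 * np.pi * u)), 1.25)
        assert f == pytest.approx(0.8, abs=0.02)

    def test_flat_cycle_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ig.bobbing_frequency(self._cycle(np.zeros(100)), 1.0)

    @pytest.mark.parametrize("stride_s", [0.9, 1.1, 1.3])
    def test_symmetric_gait_product_is_two(self, stride_s):
        p = ig.GaitProfile(stride_duration=stride_s, stride_length=1.1 * stride_s)
        sim = ig.simulate_session(p, ig.TaskScript.straight_walk(repeats=1), seed=31)
        res = ig.process_session(sim.recordings, sim.events, task="walk")
        mean_dur = float(np.mean(res.gait.stride_durations))
        for seg in ("head", "trunk"):
            f = res.stabilization[seg].bobbing_frequency
            assert f * mean_dur == pytest.approx(2.0, abs=0.05)
            assert f == pytest.approx(p.step_frequency, abs=0.05)


class TestAmplitudeRanges:
    def test_sinusoid_range_is_twice_amplitude(self):
        u = np.linspace(0, 1, 200)
        cyc = AverageCycle(
            "trunk", u, 0.7 * np.sin(2 * np.pi * u), np.zeros(200), 2.0 * np.cos(2 * np.pi * u), 3
        )
        r_ap, r_ml, r_v = ig.amplitude_ranges(cyc)
        assert r_ap == pytest.approx(1.4, rel=1e-3)
        assert r_ml == 0.0
        assert r_v == pytest.approx(4.0, rel=1e-3)

    def test_head_trunk_attenuation_ratio(self):
        # noise-free, aligned mounting: the range ratio isolates the
        # shock-absorber attenuation (noisy statistics live in the
        # acceptance suite)
        import dataclasses

        p = dataclasses.replace(ig.GaitProfile().noise_free(), yaw_misalignment_deg=0.0)
        sim = ig.simulate_session(p, ig.TaskScript.straight_walk(repeats=1), seed=33)
        res = ig.process_session(sim.recordings, sim.events, task="walk")
        h, t = res.stabilization["head"], res.stabilization["trunk"]
        for axis in ("range_ap", "range_ml", "range_v"):
            ratio = getattr(h, axis) / getattr(t, axis)
            assert ratio == pytest.approx(p.head_attenuation, rel=0.10)


def test_stride_length_sum_bounded_by_bout_displacement(walk_result):
    """Monotone displacement: per-stride lengths over a bout sum to at most
    the total bout displacement."""
    track = walk_result.displacement[0]
    lengths = walk_result.stride_lengths
    finite = np.isfinite(lengths)
    assert np.nansum(np.abs(lengths[finite])) <= abs(track.displacement_ap[-1]) + 0.05
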