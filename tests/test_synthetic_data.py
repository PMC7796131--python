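"""Generator contracts: schedules, speed, sEMG, accelerometer, forces."""

from __future__ import annotations

import numpy as np
import pytest

from gaitablation.synthetic_data import (
    ACTIVITIES,
    ChannelSpec,
    SimulationConfig,
    SubjectProfile,
    default_profiles,
    full_channel_specs,
    generate_schedule,
    generate_session,
    generate_study_schedules,
    simulate_speed,
    synthesize_accelerometer,
    synthesize_force_plates,
    synthesize_semg,
)


def _single_command_schedule(activity: str, duration: float):
    from gaitablation.synthetic_data import CommandSchedule

    return CommandSchedule(((activity, 0.0, duration),))


@pytest.fixture(scope="module")
def profile():
    return default_profiles()[0]  # walk band (0, 1.3], run (1.3, 2.4]


class TestSchedule:
    def test_default_trial_spans_150_seconds(self):
        sched = generate_schedule(3, n_commands=15, duration_per=10.0)
        assert sched.duration == pytest.approx(150.0)
        assert len(sched.commands) == 15

    def test_single_command_occupies_first_block(self):
        sched = generate_schedule(1, n_commands=1, duration_per=10.0)
        assert len(sched.commands) == 1
        _, start, dur = sched.commands[0]
        assert (start, dur) == (0.0, 10.0)

    def test_same_seed_reproduces_schedule(self):
        a = generate_schedule(11, 15, 10.0)
        b = generate_schedule(11, 15, 10.0)
        assert a == b

    @pytest.mark.parametrize("seed", range(10))
    def test_all_activities_present_when_commands_allow(self, seed):
        sched = generate_schedule(seed, n_commands=4, duration_per=10.0)
        assert set(sched.activities) == set(ACTIVITIES)

    @pytest.mark.parametrize("seed", range(5))
    def test_study_schedules_cover_all_ordered_transitions(self, seed):
        schedules = generate_study_schedules(seed, n_trials=6)
        seen = set()
        for sched in schedules:
            acts = sched.activities
            seen |= set(zip(acts[:-1], acts[1:]))
        assert seen == {(a, b) for a in ACTIVITIES for b in ACTIVITIES}

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_schedule(0, n_commands=0)
        with pytest.raises(ValueError):
            generate_schedule(0, n_commands=3, duration_per=-1.0)


class TestSpeed:
    def test_stand_only_zero_noise_is_identically_zero(self, profile):
        sched = _single_command_schedule("stand", 30.0)
        _, v = simulate_speed(sched, profile, fs=300.0, seed=0, noise_sd=0.0)
        assert np.all(v == 0.0)

    def test_walk_command_converges_to_preferred_speed(self):
        profile = SubjectProfile(
            "X",
            walk_upper=1.4,
            run_upper=2.5,
            preferred_speeds={"stand": 0, "walk": 1.3, "run": 2.0, "sprint": 3.3},
            response_lag=1.0,
        )
        sched = _single_command_schedule("walk", 20.0)
        t, v = simulate_speed(sched, profile, fs=300.0, seed=1, noise_sd=0.05)
        steady = v[t >= 5 * profile.response_lag]
        assert abs(steady.mean() - 1.3) < 0.05

    def test_fixed_seed_gives_bitwise_identical_stream(self, profile):
        sched = generate_schedule(5, 6, 10.0)
        _, a = simulate_speed(sched, profile, 300.0, seed=9)
        _, b = simulate_speed(sched, profile, 300.0, seed=9)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("prof", default_profiles(), ids=lambda p: p.subject_id)
    def test_steady_state_means_fall_in_threshold_bands(self, prof):
        """After the lag settles, each activity's speed sits in its band."""
        sched = generate_schedule(2, 8, 10.0)
        t, v = simulate_speed(sched, prof, 300.0, seed=4, noise_sd=0.0)
        for activity, start, dur in sched.commands:
            steady = v[(t >= start + dur - 2.0) & (t < start + dur)]
            mean = steady.mean()
            if activity == "stand":
                assert mean < 0.05
            elif activity == "walk":
                assert 0 < mean <= prof.walk_upper
            elif activity == "run":
                assert prof.walk_upper < mean <= prof.run_upper
            else:
                assert mean > prof.run_upper


class TestSemg:
    def test_stand_rms_matches_configured_baseline(self, profile):
        config = SimulationConfig()
        spec = next(
            c for c in full_channel_specs(config) if c.channel_id == "semg_tibialis_anterior_left"
        )
        t = np.arange(0, 10.0 + 1e-9, 1 / 300)
        times, x = synthesize_semg(t, np.zeros_like(t), spec, profile, seed=3, config=config)
        rms = np.sqrt(np.mean(x**2))
        baseline = config.semg.rms_gain["shank"]["stand"]
        assert abs(rms - baseline) / baseline < 0.10

    def test_run_rms_exceeds_walk_rms_for_gastrocnemius(self, profile):
        config = SimulationConfig()
        spec = next(
            c for c in full_channel_specs(config) if c.channel_id == "semg_gastrocnemius_left"
        )
        t = np.arange(0, 20.0 + 1e-9, 1 / 300)
        walk_v = np.full_like(t, profile.preferred_speeds["walk"])
        run_v = np.full_like(t, profile.preferred_speeds["run"])
        _, x_walk = synthesize_semg(t, walk_v, spec, profile, seed=7, config=config)
        _, x_run = synthesize_semg(t, run_v, spec, profile, seed=7, config=config)
        assert np.sqrt(np.mean(x_run**2)) > np.sqrt(np.mean(x_walk**2))

    def test_zero_amplitude_config_gives_silent_stream(self, profile):
        config = SimulationConfig()
        for seg in config.semg.rms_gain:
            for act in config.semg.rms_gain[seg]:
                config.semg.rms_gain[seg][act] = 0.0
        spec = full_channel_specs(config)[0]
        t = np.arange(0, 5.0 + 1e-9, 1 / 300)
        _, x = synthesize_semg(t, np.ones_like(t), spec, profile, seed=0, config=config)
        assert np.all(x == 0.0)

    def test_modality_mismatch_rejected(self, profile):
        accel_spec = ChannelSpec("a", "accel", "gastrocnemius", "shank", "left", 100.0)
        t = np.arange(0, 1.0 + 1e-9, 1 / 300)
        with pytest.raises(ValueError):
            synthesize_semg(t, np.zeros_like(t), accel_spec, profile, seed=0)


class TestAccelerometer:
    def test_standing_with_zero_noise_reads_one_g(self, profile):
        config = SimulationConfig()
        config.accel.noise_sd = 0.0
        spec = next(c for c in full_channel_specs(config) if c.modality == "accel")
        t = np.arange(0, 5.0 + 1e-9, 1 / 300)
        _, xyz = synthesize_accelerometer(t, np.zeros_like(t), spec, profile, seed=0, config=config)
        assert np.allclose(np.linalg.norm(xyz, axis=1), 1.0)

    def test_shank_harmonics_stronger_than_thigh_at_fixed_speed(self, profile):
        config = SimulationConfig()
        config.accel.noise_sd = 0.0
        specs = full_channel_specs(config)
        shank = next(c for c in specs if c.modality == "accel" and c.segment == "shank")
        thigh = next(c for c in specs if c.modality == "accel" and c.segment == "thigh")
        t = np.arange(0, 10.0 + 1e-9, 1 / 300)
        v = np.full_like(t, 2.0)
        _, a_shank = synthesize_accelerometer(t, v, shank, profile, seed=1, config=config)
        _, a_thigh = synthesize_accelerometer(t, v, thigh, profile, seed=1, config=config)
        assert np.std(np.linalg.norm(a_shank, axis=1)) > np.std(np.linalg.norm(a_thigh, axis=1))

    def test_mean_norm_does_not_decrease_when_speed_doubles(self, profile):
        config = SimulationConfig()
        spec = next(c for c in full_channel_specs(config) if c.modality == "accel")
        t = np.arange(0, 10.0 + 1e-9, 1 / 300)
        norms = []
        for speed in (1.0, 2.0):
            _, xyz = synthesize_accelerometer(
                t, np.full_like(t, speed), spec, profile, seed=2, config=config
            )
            norms.append(np.mean(np.linalg.norm(xyz, axis=1)))
        assert norms[1] >= norms[0]

    def test_modality_mismatch_rejected(self, profile):
        semg_spec = ChannelSpec("s", "semg", "gastrocnemius", "shank", "left", 1000.0)
        t = np.arange(0, 1.0 + 1e-9, 1 / 300)
        with pytest.raises(ValueError):
            synthesize_accelerometer(t, np.zeros_like(t), semg_spec, profile, seed=0)


class TestForcePlates:
    def test_quiet_standing_splits_body_weight_exactly(self, profile):
        config = SimulationConfig()
        config.force.sway_amplitude = 0.0
        config.force.noise_sd = 0.0
        t = np.arange(0, 5.0 + 1e-9, 1 / 300)
        _, left, right = synthesize_force_plates(t, np.zeros_like(t), profile, seed=0, config=config)
        assert np.allclose(left, config.body_weight_n / 2)
        assert np.allclose(left - right, 0.0)

    def test_walking_has_double_support_and_running_has_flight(self, profile):
        config = SimulationConfig()
        t = np.arange(0, 20.0 + 1e-9, 1 / 300)
        walk_v = np.full_like(t, profile.preferred_speeds["walk"])
        run_v = np.full_like(t, profile.preferred_speeds["run"])
        _, lw, rw = synthesize_force_plates(t, walk_v, profile, seed=5, config=config)
        _, lr, rr = synthesize_force_plates(t, run_v, profile, seed=5, config=config)
        assert np.any((lw > 0) & (rw > 0))  # double support
        assert np.any((lr == 0) & (rr == 0))  # flight phase

    @pytest.mark.parametrize("activity", ["walk", "run"])
    def test_mean_total_force_balances_body_weight(self, profile, activity):
        config = SimulationConfig()
        t = np.arange(0, 30.0 + 1e-9, 1 / 300)
        v = np.full_like(t, profile.preferred_speeds[activity])
        _, left, right = synthesize_force_plates(t, v, profile, seed=6, config=config)
        total = (left + right).mean()
        assert abs(total - config.body_weight_n) / config.body_weight_n < 0.10

    def test_forces_never_negative_in_full_session(self, profile):
        session = generate_session(profile, "t1", seed=12)
        for cid in ("force_left", "force_right"):
            _, _, values = session.channel(cid)
            assert np.all(values >= 0)

    def test_cross_plate_strikes_swap_some_stances(self, profile):
        t = np.arange(0, 30.0 + 1e-9, 1 / 300)
        v = np.full_like(t, profile.preferred_speeds["run"])
        clean = SimulationConfig()
        clean.force.noise_sd = 0.0
        corrupted = SimulationConfig(cross_strike_fraction=0.5)
        corrupted.force.noise_sd = 0.0
        _, l0, r0 = synthesize_force_plates(t, v, profile, seed=8, config=clean)
        _, l1, r1 = synthesize_force_plates(t, v, profile, seed=8, config=corrupted)
        assert not np.array_equal(l0, l1)
        # swapped, not invented: the set of (left+right) totals is preserved
        assert np.allclose(l0 + r0, l1 + r1)


class TestSession:
    def test_full_session_has_canonical_channel_layout(self, profile):
        session = generate_session(profile, "t1", seed=1)
        modalities = [spec.modality for spec, _, _ in session.channels]
        assert modalities.count("semg") == 8
        assert modalities.count("accel") == 8
        assert modalities.count("force_plate") == 2
        assert modalities.count("speed") == 1

    def test_identical_seed_reproduces_session_bitwise(self, profile):
        a = generate_session(profile, "t1", seed=33)
        b = generate_session(profile, "t1", seed=33)
        for (_, _, va), (_, _, vb) in zip(a.channels, b.channels):
            assert np.array_equal(va, vb)

    def test_different_seeds_share_schedule_when_given(self, profile):
        sched = generate_schedule(4, 15, 10.0)
        a = generate_session(profile, "t1", seed=1, schedule=sched)
        b = generate_session(profile, "t1", seed=2, schedule=sched)
        assert a.schedule == b.schedule
        _, _, va = a.channel("semg_gastrocnemius_left")
        _, _, vb = b.channel("semg_gastrocnemius_left")
        assert not np.array_equal(va, vb)

    def test_streams_are_uniform_and_span_the_trial(self, profile):
        session = generate_session(profile, "t1", seed=2)
        for spec, times, _ in session.channels:
            dt = np.diff(times)
            assert np.all(dt > 0)
            assert np.allclose(dt, 1.0 / spec.sampling_rate)
            assert times[0] == 0.0
            assert times[-1] == pytest.approx(session.schedule.duration)


class TestProfileValidation:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            SubjectProfile(
                "bad",
                walk_upper=2.0,
                run_upper=1.0,
                preferred_speeds={"stand": 0, "walk": 1, "run": 1.5, "sprint": 3},
            )

    def test_preferred_speeds_must_respect_bands(self):
        with pytest.raises(ValueError):
            SubjectProfile(
                "bad",
                walk_upper=1.0,
                run_upper=2.0,
                preferred_speeds={"stand": 0, "walk": 1.5, "run": 1.8, "sprint": 3},
            )
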