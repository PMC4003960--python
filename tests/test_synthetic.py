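import numpy as np
import pytest
from scipy import integrate, signal

from pdgait.ban_io import SENSOR_IDS
from pdgait.features import SampEnParams, sample_entropy
from pdgait.qc import detect_gaps
from pdgait.synthetic import (
    ActivitySchedule,
    GaitProfile,
    LossModel,
    ProfileError,
    apply_loss_model,
    simulate_gait_acceleration,
    simulate_session,
)


class TestGaitProfile:
    def test_defaults_valid(self):
        GaitProfile()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("step_frequency_hz", 0.0),
            ("step_frequency_hz", float("nan")),
            ("stride_time_cv", -0.1),
            ("stride_time_cv", 1.0),
            ("com_excursion_m", 0.0),
            ("com_excursion_m", 2.0),  # >= leg length
            ("leg_length_m", -1.0),
            ("asymmetry", 1.0),
            ("harmonic_noise_sd", -0.01),
            ("harmonic_noise_sd", float("inf")),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(ProfileError, match=field):
            GaitProfile(**{field: value})

    def test_step_length_closed_form(self):
        # 2*sqrt(2*1.0*0.05 - 0.05^2) = 0.6244997998...
        p = GaitProfile(leg_length_m=1.0, com_excursion_m=0.05)
        assert p.step_length_m == pytest.approx(0.6244997998398398, abs=1e-12)


class TestSimulateGait:
    def test_all_sensors_emitted(self, healthy_profile):
        sim = simulate_gait_acceleration(healthy_profile, 10.0, seed=0)
        assert set(sim.signals) == set(SENSOR_IDS)
        n = int(round(10.0 * 62.5))
        for sig in sim.signals.values():
            assert sig.shape == (n, 3)

    def test_zero_cv_intervals_exact(self):
        p = GaitProfile(step_frequency_hz=2.0, stride_time_cv=0.0, harmonic_noise_sd=0.0)
        sim = simulate_gait_acceleration(p, 30.0, seed=3)
        intervals = np.diff(sim.step_times_s)
        assert np.allclose(intervals, 0.5, atol=1e-12)

    def test_ground_truth_step_lengths(self):
        p = GaitProfile(leg_length_m=1.0, com_excursion_m=0.05)
        sim = simulate_gait_acceleration(p, 10.0, seed=0)
        assert np.allclose(sim.step_lengths_m, 0.6244997998398398)
        assert sim.step_lengths_m.size == sim.step_times_s.size

    def test_nyquist_precondition(self, healthy_profile):
        with pytest.raises(ProfileError, match="fs_hz"):
            simulate_gait_acceleration(healthy_profile, 10.0, fs_hz=3.0)

    def test_duration_precondition(self, healthy_profile):
        with pytest.raises(ProfileError, match="duration_s"):
            simulate_gait_acceleration(healthy_profile, 0.0)

    def test_stride_cv_converges(self):
        # >= 500 strides: CV of ground-truth stride intervals within 10% rel
        p = GaitProfile(step_frequency_hz=2.0, stride_time_cv=0.10, harmonic_noise_sd=0.0)
        sim = simulate_gait_acceleration(p, 550.0, seed=11)  # ~1100 steps
        t = sim.step_times_s
        assert t.size >= 1000
        strides = t[2:] - t[:-2]
        cv = np.std(strides) / np.mean(strides)
        assert cv == pytest.approx(0.10, rel=0.10)

    def test_double_integration_recovers_excursion(self, noiseless_profile):
        # noiseless x-channel double integral per step: peak-to-trough = h +/- 2%
        sim = simulate_gait_acceleration(noiseless_profile, 60.0, seed=1)
        fs = sim.fs_hz
        a = (sim.signals["belt"][:, 0] - 1.0) * 9.80665  # remove gravity offset
        v = integrate.cumulative_trapezoid(a, dx=1.0 / fs, initial=0.0)
        d = integrate.cumulative_trapezoid(v, dx=1.0 / fs, initial=0.0)
        steps = sim.step_times_s
        hs = []
        for t0, t1 in zip(steps[5:-5], steps[6:-4]):
            seg = signal.detrend(d[int(round(t0 * fs)) : int(round(t1 * fs)) + 1])
            hs.append(np.ptp(seg))
        assert np.mean(hs) == pytest.approx(noiseless_profile.com_excursion_m, rel=0.02)

    def test_entropy_direction_pd_vs_healthy(self):
        pd_like = GaitProfile(stride_time_cv=0.10, harmonic_noise_sd=0.03)
        healthy = GaitProfile(stride_time_cv=0.02, harmonic_noise_sd=0.03)
        params = SampEnParams()
        e = {}
        for name, prof in (("pd", pd_like), ("healthy", healthy)):
            sim = simulate_gait_acceleration(prof, 40.0, seed=4)
            x = sim.signals["belt"][:, 0]
            e[name] = sample_entropy(x - x.mean(), params)
        assert e["pd"] > e["healthy"]

    def test_same_seed_bit_identical(self, healthy_profile):
        a = simulate_gait_acceleration(healthy_profile, 20.0, seed=7)
        b = simulate_gait_acceleration(healthy_profile, 20.0, seed=7)
        assert np.array_equal(a.step_times_s, b.step_times_s)
        for name in SENSOR_IDS:
            assert np.array_equal(a.signals[name], b.signals[name])

    def test_full_scale_respected(self, pd_profile):
        sim = simulate_gait_acceleration(pd_profile, 20.0, seed=2)
        for sig in sim.signals.values():
            assert np.all(np.abs(sig) <= 6.0)


class TestActivitySchedule:
    def test_valid(self):
        s = ActivitySchedule.from_pairs([(0, 60, "walking"), (60, 120, "resting")])
        assert s.duration_s == 120

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            ActivitySchedule.from_pairs([(0, 60, "walking"), (50, 120, "resting")])

    def test_gap_rejected(self):
        with pytest.raises(ValueError):
            ActivitySchedule.from_pairs([(0, 60, "walking"), (70, 120, "resting")])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            ActivitySchedule.from_pairs([(0, 60, "jogging")])


class TestSimulateSession:
    def test_labels_aligned(self, healthy_profile):
        sched = ActivitySchedule.from_pairs([(0, 60, "walking"), (60, 120, "resting")])
        sim = simulate_session(sched, healthy_profile, seed=0)
        assert sim.labels.size == sim.n_samples
        assert np.all(sim.labels[: int(60 * 62.5)] == "walking")
        assert np.all(sim.labels[int(60 * 62.5) :] == "resting")

    def test_single_walking_interval_ground_truth(self, healthy_profile):
        sched = ActivitySchedule.from_pairs([(0, 60, "walking"), (60, 120, "resting")])
        sim = simulate_session(sched, healthy_profile, seed=0)
        assert sim.step_times_s.size > 0
        assert sim.step_times_s.min() >= 0
        assert sim.step_times_s.max() < 60

    def test_resting_legs_quiet(self, healthy_profile):
        sched = ActivitySchedule.from_pairs([(0, 60, "resting")])
        sim = simulate_session(sched, healthy_profile, seed=0)
        for leg in ("left_leg", "right_leg"):
            assert np.var(sim.signals[leg][:, 0]) < 0.01
        assert sim.step_times_s.size == 0

    def test_arm_task_moves_wrists_not_legs(self, healthy_profile):
        sched = ActivitySchedule.from_pairs([(0, 60, "arm_task")])
        sim = simulate_session(sched, healthy_profile, seed=1)
        wrist_var = max(np.var(sim.signals[w]) for w in ("left_wrist", "right_wrist"))
        leg_var = max(np.var(sim.signals[s][:, 0]) for s in ("left_leg", "right_leg"))
        assert wrist_var > 5 * leg_var


class TestApplyLossModel:
    def test_identity_when_lossless(self, healthy_profile):
        sim = simulate_gait_acceleration(healthy_profile, 10.0, seed=0)
        loss = LossModel(disconnect_rate_per_s=0.0, burst_extra_samples_mean=0.0,
                         startup_burst_ms=0.0, seed=1)
        streams, dropped = apply_loss_model(sim.signals, loss)
        for name, stream in streams.items():
            assert len(stream) == sim.n_samples
            assert dropped[name].size == 0
            assert np.array_equal(stream.acc_g, sim.signals[name])

    def test_zero_extension_bursts_exactly_64ms(self, healthy_profile):
        sim = simulate_gait_acceleration(healthy_profile, 120.0, seed=0)
        loss = LossModel(disconnect_rate_per_s=0.3, burst_extra_samples_mean=0.0,
                         startup_burst_ms=0.0, seed=5)
        streams, _ = apply_loss_model(sim.signals, loss)
        durations = [
            b.duration_ms for s in streams.values() for b in detect_gaps(s)
        ]
        assert durations, "expected some bursts"
        # bursts may merge by collision; each is a multiple of the 64 ms minimum
        assert all(d >= 64 and d % 16 == 0 for d in durations)
        assert 64 in durations

    def test_minimum_burst_length(self, healthy_profile):
        sim = simulate_gait_acceleration(healthy_profile, 120.0, seed=0)
        loss = LossModel(disconnect_rate_per_s=0.2, startup_burst_ms=0.0, seed=9)
        streams, _ = apply_loss_model(sim.signals, loss)
        for s in streams.values():
            for b in detect_gaps(s):
                assert b.missing_samples >= 4

    def test_startup_burst_removes_leading_packets(self, healthy_profile):
        sim = simulate_gait_acceleration(healthy_profile, 30.0, seed=0)
        loss = LossModel(disconnect_rate_per_s=0.0, startup_burst_ms=1000.0, seed=0)
        streams, dropped = apply_loss_model(sim.signals, loss)
        for name, stream in streams.items():
            assert stream.timestamps_ms[0] >= 1000
            n_startup = int(np.ceil(1000 / 16))
            assert np.array_equal(dropped[name][:n_startup], np.arange(n_startup))

    def test_measure_consistency(self, healthy_profile):
        # packets emitted + dropped = expected, always
        sim = simulate_gait_acceleration(healthy_profile, 60.0, seed=0)
        loss = LossModel(disconnect_rate_per_s=0.5, burst_extra_samples_mean=10.0,
                         startup_burst_ms=3000.0, seed=3)
        streams, dropped = apply_loss_model(sim.signals, loss)
        for name in streams:
            assert len(streams[name]) + dropped[name].size == sim.n_samples

    def test_timestamps_on_grid(self, healthy_profile):
        sim = simulate_gait_acceleration(healthy_profile, 30.0, seed=0)
        streams, _ = apply_loss_model(sim.signals, LossModel(seed=2))
        for s in streams.values():
            assert np.all(s.timestamps_ms % 16 == 0)
            s.validate()

    def test_seed_reproducibility(self, healthy_profile):
        sim = simulate_gait_acceleration(healthy_profile, 30.0, seed=0)
        s1, d1 = apply_loss_model(sim.signals, LossModel(seed=42))
        s2, d2 = apply_loss_model(sim.signals, LossModel(seed=42))
        for name in s1:
            assert np.array_equal(s1[name].timestamps_ms, s2[name].timestamps_ms)
            assert np.array_equal(d1[name], d2[name])

    def test_loss_percentage_matches_constructed_input(self):
        # 10,000 expected samples with 95 dropped -> 0.95% downstream
        from pdgait.ban_io import PacketStream
        from pdgait.qc import loss_percentage

        n = 10_000
        rng = np.random.default_rng(0)
        drop = rng.choice(np.arange(1, n - 1), size=95, replace=False)
        kept = np.setdiff1d(np.arange(n), drop)
        stream = PacketStream(
            "belt", kept * 16, np.zeros((kept.size, 3)), session_expected_span_ms=n * 16
        )
        stats = loss_percentage(stream, window_s=n / 62.5)
        assert stats.mean_percent == pytest.approx(0.95, abs=1e-9)
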