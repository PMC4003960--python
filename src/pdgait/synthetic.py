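"""Synthetic multi-sensor accelerometer sessions with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not validated biomechanics: tri-axial belt/limb acceleration
during walking and non-walking activity with controllable step frequency,
amplitude, stride-time variability and left/right asymmetry, plus a
wireless packet-loss process with a 4-sample (64 ms at 62.5 Hz) minimum
reconnect burst and a long startup burst.

Gait signal model
-----------------
Vertical centre-of-mass displacement is a raised-cosine arc of amplitude
``com_excursion_m`` per step; the cranio-caudal acceleration is its
analytic second derivative, so double integration recovers the excursion
exactly and the inverted-pendulum step length has the closed form
``s = 2*sqrt(2*l*h - h**2)``.  When ``harmonic_noise_sd > 0`` the signal
is enriched with 2nd/3rd harmonics at -12 dB plus white noise; at 0 the
channel is the pure closed-form waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pdgait.ban_io import FS_HZ, FULL_SCALE_G, NOMINAL_INTERVAL_MS, SENSOR_IDS, PacketStream

G0 = 9.80665  # m/s^2 per g

#: Harmonic enrichment level relative to the fundamental (-12 dB).
HARMONIC_GAIN = 10.0 ** (-12.0 / 20.0)

#: Minimum burst: the logger needs 4 sample periods (64 ms) to reconnect.
MIN_BURST_SAMPLES = 4

ACTIVITY_LABELS = ("walking", "resting", "arm_task")

#: Per-patient mean data-loss percentages measured in the reference
#: home deployment of the sensor network (one value per participant);
#: used to parameterize realistic loss simulations.
DEPLOYMENT_LOSS_PERCENT = (0.95, 0.97, 2.02, 1.14, 1.51, 0.32, 1.83, 1.25, 1.31, 1.27, 1.84)


def loss_model_for_target(
    loss_percent: float,
    burst_extra_samples_mean: float = 4.0,
    fs_hz: float = FS_HZ,
    seed: int = 0,
) -> "LossModel":
    """Loss model whose expected steady-state loss matches ``loss_percent``.

    The expected loss fraction of the Poisson-disconnect process is
    ``rate * mean_burst / fs``, so the rate is solved from the target
    percentage (startup burst disabled; it is a separate phenomenon).
    """
    mean_burst = MIN_BURST_SAMPLES + burst_extra_samples_mean
    rate = loss_percent / 100.0 * fs_hz / mean_burst
    return LossModel(
        disconnect_rate_per_s=rate,
        burst_extra_samples_mean=burst_extra_samples_mean,
        startup_burst_ms=0.0,
        seed=seed,
    )


class ProfileError(ValueError):
    """A gait/loss profile field is non-finite or out of range."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ProfileError(f"{name}: {msg}")


@dataclass(frozen=True)
class GaitProfile:
    """Parameters of the simulated gait pattern.

    Attributes
    ----------
    step_frequency_hz:
        Mean steps per second.
    stride_time_cv:
        Coefficient of variation of stride (two-step) intervals.
    com_excursion_m:
        Peak-to-trough vertical centre-of-mass displacement per step (m).
    leg_length_m:
        Pendulum length ``l`` (m).
    asymmetry:
        Fractional left/right amplitude difference in [0, 1); applied to
        the leg sensors only so the belt channel keeps the closed-form
        excursion.
    harmonic_noise_sd:
        White-noise standard deviation in g; also gates the -12 dB
        harmonic enrichment (0 means a pure noiseless waveform).
    """

    step_frequency_hz: float = 2.0
    stride_time_cv: float = 0.02
    com_excursion_m: float = 0.05
    leg_length_m: float = 1.0
    asymmetry: float = 0.0
    harmonic_noise_sd: float = 0.03

    def __post_init__(self) -> None:
        for name in (
            "step_frequency_hz",
            "stride_time_cv",
            "com_excursion_m",
            "leg_length_m",
            "asymmetry",
            "harmonic_noise_sd",
        ):
            _check(math.isfinite(getattr(self, name)), name, "must be finite")
        _check(self.step_frequency_hz > 0, "step_frequency_hz", "must be > 0")
        _check(0 <= self.stride_time_cv < 1, "stride_time_cv", "must be in [0, 1)")
        _check(self.leg_length_m > 0, "leg_length_m", "must be > 0")
        _check(
            0 < self.com_excursion_m < self.leg_length_m,
            "com_excursion_m",
            "must be in (0, leg_length_m)",
        )
        _check(0 <= self.asymmetry < 1, "asymmetry", "must be in [0, 1)")
        _check(self.harmonic_noise_sd >= 0, "harmonic_noise_sd", "must be >= 0")

    @property
    def step_length_m(self) -> float:
        """Inverted-pendulum step length ``2*sqrt(2*l*h - h**2)``."""
        l, h = self.leg_length_m, self.com_excursion_m
        return 2.0 * math.sqrt(2.0 * l * h - h * h)


@dataclass(frozen=True)
class LossModel:
    """Wireless-loss process parameters.

    Disconnections arrive as a Poisson process; each removes the
    4-sample reconnect minimum plus a geometric number of extra samples
    with mean ``burst_extra_samples_mean``.  The startup burst removes
    the first ``startup_burst_ms`` of packets (pre-connection loss).
    """

    disconnect_rate_per_s: float = 0.05
    burst_extra_samples_mean: float = 4.0
    startup_burst_ms: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.disconnect_rate_per_s >= 0, "disconnect_rate_per_s", "must be >= 0")
        _check(self.burst_extra_samples_mean >= 0, "burst_extra_samples_mean", "must be >= 0")
        _check(self.startup_burst_ms >= 0, "startup_burst_ms", "must be >= 0")


@dataclass(frozen=True)
class ActivitySchedule:
    """Ordered, non-overlapping (start_s, end_s, label) intervals covering [0, duration]."""

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("schedule must contain at least one interval")
        prev_end = 0.0
        for start, end, label in self.intervals:
            if label not in ACTIVITY_LABELS:
                raise ValueError(f"unknown activity label {label!r}")
            if end <= start:
                raise ValueError(f"interval ({start}, {end}) is empty or reversed")
            if not math.isclose(start, prev_end, abs_tol=1e-9):
                raise ValueError(
                    f"intervals must tile [0, duration] without gaps/overlaps; "
                    f"got start {start} after end {prev_end}"
                )
            prev_end = end

    @classmethod
    def from_pairs(cls, intervals: Sequence[tuple[float, float, str]]) -> "ActivitySchedule":
        return cls(tuple((float(a), float(b), str(c)) for a, b, c in intervals))

    @property
    def duration_s(self) -> float:
        return self.intervals[-1][1]


@dataclass
class GaitSimulation:
    """Output of :func:`simulate_gait_acceleration`."""

    fs_hz: float
    signals: dict[str, np.ndarray]  # sensor -> (n, 3) acceleration in g
    step_times_s: np.ndarray  # ground-truth step-event (foot contact) times
    step_lengths_m: np.ndarray  # per-step inverted-pendulum length
    profile: GaitProfile

    @property
    def n_samples(self) -> int:
        return next(iter(self.signals.values())).shape[0]


@dataclass
class SessionSimulation(GaitSimulation):
    """Output of :func:`simulate_session`: adds sample-aligned activity labels."""

    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    schedule: ActivitySchedule | None = None


def _step_boundaries(profile: GaitProfile, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Step boundary times in [0, duration].

    Step intervals are i.i.d. log-normal with mean ``1/f``.  Their CV is
    ``stride_time_cv * sqrt(2)`` so that stride intervals (sums of two
    consecutive step intervals) carry the target CV regardless of which
    foot starts a stride.
    """
    f = profile.step_frequency_hz
    mean = 1.0 / f
    n_guess = int(duration_s * f * 1.6) + 8
    if profile.stride_time_cv == 0:
        intervals = np.full(n_guess, mean)
    else:
        cv_step = profile.stride_time_cv * math.sqrt(2.0)
        sigma2 = math.log(1.0 + cv_step**2)
        mu = math.log(mean) - sigma2 / 2.0
        intervals = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n_guess)
    bounds = np.concatenate([[0.0], np.cumsum(intervals)])
    return bounds[bounds <= duration_s + mean]  # keep one spare boundary past the end


def _raised_cosine_accel(
    t: np.ndarray, bounds: np.ndarray, h: float, gain_per_step: np.ndarray | None = None
) -> np.ndarray:
    """Second derivative (m/s^2) of a per-step raised-cosine COM arc.

    Displacement within step i of duration U is ``(h/2)*(1 - cos(2*pi*u))``
    with ``u = (t - t_i)/U``; acceleration is ``(h/2)*(2*pi/U)^2 * cos``.
    """
    idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(bounds) - 2)
    U = bounds[idx + 1] - bounds[idx]
    phase = (t - bounds[idx]) / U
    amp = (h / 2.0) * (2.0 * np.pi / U) ** 2
    if gain_per_step is not None:
        amp = amp * gain_per_step[idx]
    return amp * np.cos(2.0 * np.pi * phase), phase, idx


def simulate_gait_acceleration(
    profile: GaitProfile,
    duration_s: float,
    fs_hz: float = FS_HZ,
    seed: int = 0,
) -> GaitSimulation:
    """Simulate walking for all five sensors with ground-truth step events.

    The cranio-caudal (x) belt channel carries 1 g gravity plus the
    closed-form vertical acceleration; its noiseless double integral per
    step has peak-to-trough amplitude ``com_excursion_m``.  Leg sensors
    carry the same pattern with alternating left/right gain set by
    ``asymmetry``; wrists carry arm swing at stride frequency.
    """
    if not (duration_s > 0):
        raise ProfileError("duration_s: must be > 0")
    if not (fs_hz > 2.0 * profile.step_frequency_hz):
        raise ProfileError(
            f"fs_hz: {fs_hz} violates Nyquist for step frequency {profile.step_frequency_hz} Hz"
        )

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    bounds = _step_boundaries(profile, duration_s, rng)
    step_times = bounds[:-1]
    step_times = step_times[step_times < duration_s]
    h = profile.com_excursion_m

    a_vert, phase, step_idx = _raised_cosine_accel(t, bounds, h)
    a_vert_g = a_vert / G0

    noisy = profile.harmonic_noise_sd > 0

    def enrich(base_g: np.ndarray, k_start: int = 2) -> np.ndarray:
        if not noisy:
            return base_g
        amp = np.abs(base_g).max() or 1.0
        out = base_g.copy()
        for k in (2, 3):
            out = out + HARMONIC_GAIN * amp * np.cos(2.0 * np.pi * k * phase)
        return out

    def noise(sd_scale: float = 1.0) -> np.ndarray:
        if not noisy:
            return 0.0
        return rng.normal(0.0, profile.harmonic_noise_sd * sd_scale, size=n)

    stride_phase = 2.0 * np.pi * (step_idx + phase) / 2.0  # half the step rate

    signals: dict[str, np.ndarray] = {}

    # Belt: x (cranio-caudal) gravity + vertical accel; z (anterio-posterior)
    # rises and falls with the gait cycle; y (medio-lateral) sways at stride rate.
    belt = np.empty((n, 3))
    belt[:, 0] = 1.0 + enrich(a_vert_g) + noise()
    belt[:, 1] = 0.10 * np.sin(stride_phase) + noise(0.8)
    belt[:, 2] = 0.35 * np.sin(2.0 * np.pi * phase) * np.abs(a_vert_g).max() + noise()
    signals["belt"] = belt

    # Legs: same vertical pattern, gain alternating with foot parity.
    parity = step_idx % 2  # 0 = left foot steps, 1 = right
    for name, foot in (("left_leg", 0), ("right_leg", 1)):
        gain = np.where(parity == foot, 1.0 + profile.asymmetry, 1.0 - profile.asymmetry)
        own = np.where(parity == foot, 1.4, 0.6)  # stance leg feels the impact
        leg = np.empty((n, 3))
        leg[:, 0] = 1.0 + gain * own * enrich(a_vert_g) + noise()
        leg[:, 1] = 0.08 * np.sin(stride_phase + (0.0 if foot == 0 else np.pi)) + noise(0.8)
        leg[:, 2] = 0.5 * gain * own * enrich(a_vert_g) + noise()
        signals[name] = leg

    # Wrists: gravity along y (arm hanging), swing at stride frequency.
    for name, sign in (("left_wrist", 1.0), ("right_wrist", -1.0)):
        wrist = np.empty((n, 3))
        wrist[:, 0] = 0.12 * sign * np.sin(stride_phase) + noise(0.8)
        wrist[:, 1] = 1.0 + noise(0.8)
        wrist[:, 2] = 0.15 * sign * np.cos(stride_phase) + noise(0.8)
        signals[name] = wrist

    for v in signals.values():
        np.clip(v, -FULL_SCALE_G, FULL_SCALE_G, out=v)

    step_lengths = np.full(step_times.shape, profile.step_length_m)
    return GaitSimulation(
        fs_hz=fs_hz,
        signals=signals,
        step_times_s=step_times,
        step_lengths_m=step_lengths,
        profile=profile,
    )


def _resting_signals(n: int, rng: np.random.Generator, sd: float) -> dict[str, np.ndarray]:
    """Near-constant gravity plus small sensor noise (sitting still)."""
    out: dict[str, np.ndarray] = {}
    for name in SENSOR_IDS:
        sig = rng.normal(0.0, sd, size=(n, 3))
        if name.endswith("wrist"):
            sig[:, 1] += 1.0
        else:
            sig[:, 0] += 1.0
        out[name] = sig
    return out


def _arm_task_signals(n: int, fs_hz: float, rng: np.random.Generator, sd: float) -> dict[str, np.ndarray]:
    """Resting posture with sporadic wrist transients (reaching, handling)."""
    out = _resting_signals(n, rng, sd)
    t = np.arange(n) / fs_hz
    duration = n / fs_hz
    for name in ("left_wrist", "right_wrist"):
        n_events = max(1, rng.poisson(0.5 * duration))
        for _ in range(n_events):
            centre = rng.uniform(0.0, duration)
            width = rng.uniform(0.15, 0.5)
            amp = rng.uniform(0.4, 1.2) * rng.choice([-1.0, 1.0])
            bump = amp * np.exp(-0.5 * ((t - centre) / width) ** 2)
            axis = rng.integers(0, 3)
            out[name][:, axis] += bump
    for v in out.values():
        np.clip(v, -FULL_SCALE_G, FULL_SCALE_G, out=v)
    return out


def simulate_session(
    schedule: ActivitySchedule,
    profile: GaitProfile,
    fs_hz: float = FS_HZ,
    seed: int = 0,
) -> SessionSimulation:
    """Simulate a scheduled session of walking / resting / arm-task intervals.

    Walking intervals are filled by :func:`simulate_gait_acceleration`
    (independent sub-seeds per interval); ground-truth step times are
    shifted into session time.  Labels are returned sample-aligned.
    """
    rest_sd = max(profile.harmonic_noise_sd, 0.01)
    seeds = np.random.SeedSequence(seed).spawn(len(schedule.intervals))

    chunks: list[dict[str, np.ndarray]] = []
    labels: list[np.ndarray] = []
    step_times: list[np.ndarray] = []
    step_lengths: list[np.ndarray] = []
    for (start, end, label), ss in zip(schedule.intervals, seeds):
        n = int(round((end - start) * fs_hz))
        if n == 0:
            continue
        rng = np.random.default_rng(ss)
        if label == "walking":
            sim = simulate_gait_acceleration(
                profile, n / fs_hz, fs_hz=fs_hz, seed=int(ss.generate_state(1)[0])
            )
            chunks.append(sim.signals)
            step_times.append(sim.step_times_s + start)
            step_lengths.append(sim.step_lengths_m)
        elif label == "resting":
            chunks.append(_resting_signals(n, rng, rest_sd))
        else:
            chunks.append(_arm_task_signals(n, fs_hz, rng, rest_sd))
        labels.append(np.full(n, label, dtype=object))

    signals = {
        name: np.concatenate([c[name] for c in chunks], axis=0) for name in SENSOR_IDS
    }
    return SessionSimulation(
        fs_hz=fs_hz,
        signals=signals,
        step_times_s=np.concatenate(step_times) if step_times else np.array([]),
        step_lengths_m=np.concatenate(step_lengths) if step_lengths else np.array([]),
        profile=profile,
        labels=np.concatenate(labels),
        schedule=schedule,
    )


def walking_mask(labels: np.ndarray) -> np.ndarray:
    return labels == "walking"


def apply_loss_model(
    signals: dict[str, np.ndarray],
    loss: LossModel,
    fs_hz: float = FS_HZ,
) -> tuple[dict[str, PacketStream], dict[str, np.ndarray]]:
    """Drop packets from uniformly sampled signals per the loss process.

    Returns the surviving :class:`PacketStream` per sensor (timestamps on
    the 16 ms grid) and the ground-truth sorted dropped-sample indices.
    Always: packets emitted + dropped = expected sample count.
    """
    interval_ms = round(1000.0 / fs_hz)
    streams: dict[str, PacketStream] = {}
    dropped: dict[str, np.ndarray] = {}
    seeds = np.random.SeedSequence(loss.seed).spawn(len(signals))
    for (name, sig), ss in zip(sorted(signals.items()), seeds):
        rng = np.random.default_rng(ss)
        n = sig.shape[0]
        duration_s = n / fs_hz
        drop = np.zeros(n, dtype=bool)

        n_startup = min(n, int(math.ceil(loss.startup_burst_ms / interval_ms)))
        drop[:n_startup] = True

        n_events = rng.poisson(loss.disconnect_rate_per_s * duration_s)
        if n_events:
            starts = rng.integers(0, n, size=n_events)
            if loss.burst_extra_samples_mean > 0:
                # geometric on {0, 1, ...} with the requested mean
                p = 1.0 / (1.0 + loss.burst_extra_samples_mean)
                extras = rng.geometric(p, size=n_events) - 1
            else:
                extras = np.zeros(n_events, dtype=int)
            for s0, extra in zip(starts, extras):
                drop[s0 : s0 + MIN_BURST_SAMPLES + int(extra)] = True

        kept = np.flatnonzero(~drop)
        streams[name] = PacketStream(
            sensor_id=name,
            timestamps_ms=kept.astype(np.int64) * interval_ms,
            acc_g=sig[kept],
            nominal_interval_ms=interval_ms,
            session_expected_span_ms=n * interval_ms,
        )
        dropped[name] = np.flatnonzero(drop)
    return streams, dropped


def ground_truth_dict(sim: SessionSimulation, dropped: dict[str, np.ndarray] | None = None) -> dict:
    """JSON-serializable ground truth (stride times, step lengths, labels, drops)."""
    out = {
        "fs_hz": sim.fs_hz,
        "step_times_s": sim.step_times_s.tolist(),
        "step_lengths_m": sim.step_lengths_m.tolist(),
        "labels": sim.labels.tolist() if sim.labels.size else [],
        "profile": {
            "step_frequency_hz": sim.profile.step_frequency_hz,
            "stride_time_cv": sim.profile.stride_time_cv,
            "com_excursion_m": sim.profile.com_excursion_m,
            "leg_length_m": sim.profile.leg_length_m,
            "asymmetry": sim.profile.asymmetry,
            "harmonic_noise_sd": sim.profile.harmonic_noise_sd,
        },
    }
    if dropped is not None:
        out["dropped_indices"] = {k: v.tolist() for k, v in dropped.items()}
    return out
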