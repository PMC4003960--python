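"""Gait descriptors per walking segment.

Sample entropy quantifies signal regularity: the negative log of the
conditional probability that two length-``m`` templates that match under
a Chebyshev tolerance ``r * sd`` still match when extended by one point.
Classic parameters — step frequency, stride length via the inverted
pendulum (step length ``2*sqrt(2*l*h - h**2)`` from the vertical
centre-of-mass excursion ``h``), velocity and stride-to-stride
variability — come from step events detected on the band-passed
cranio-caudal belt channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, signal

from pdgait.synthetic import G0

VELOCITY_CONSISTENCY_TOL = 1e-9


class StepDetectionError(RuntimeError):
    """Segment skipped: not enough step events for gait parameters."""


@dataclass(frozen=True)
class SampEnParams:
    """Template length ``m`` and sd-relative Chebyshev tolerance ``r``."""

    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError("m must be a positive integer")
        if not (self.r > 0):
            raise ValueError("r must be > 0")


@dataclass
class GaitFeatureSet:
    """Per-segment gait descriptors."""

    sample_entropy: float
    step_frequency_hz: float
    stride_length_m: float
    velocity_m_s: float
    stride_time_cv: float
    n_steps: int
    velocity_consistent: bool = True

    def to_dict(self) -> dict:
        return {
            "sample_entropy": self.sample_entropy,
            "step_frequency_hz": self.step_frequency_hz,
            "stride_length_m": self.stride_length_m,
            "velocity_m_s": self.velocity_m_s,
            "stride_time_cv": self.stride_time_cv,
            "n_steps": self.n_steps,
            "velocity_consistent": self.velocity_consistent,
        }


def _template_matches(x: np.ndarray, m: int, tol: float) -> int:
    """Count ordered template pairs (i < j) of length m within Chebyshev tol."""
    n = x.size - m + 1
    templates = np.lib.stride_tricks.sliding_window_view(x, m)
    count = 0
    for i in range(n - 1):
        d = np.max(np.abs(templates[i + 1 :] - templates[i]), axis=1)
        count += int(np.count_nonzero(d <= tol))
    return count


def sample_entropy(series, params: SampEnParams | None = None) -> float:
    """Sample entropy ``-ln(A/B)`` with self-matches excluded.

    ``B`` counts template pairs of length ``m`` whose Chebyshev distance
    is at most ``r * sd(series)``; ``A`` the same at length ``m + 1``.
    A constant series returns 0 (every template matches at both
    lengths); if no length-``m + 1`` pair matches the result is
    ``inf`` (maximal irregularity sentinel), never an exception.
    """
    params = params or SampEnParams()
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size <= params.m + 1:
        raise ValueError(f"series length {x.size} too short for m={params.m}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    tol = params.r * sd
    b = _template_matches(x, params.m, tol)
    a = _template_matches(x, params.m + 1, tol)
    if b == 0 or a == 0:
        return float("inf")
    return float(-np.log(a / b))


def _bandpass(x: np.ndarray, fs_hz: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, x, padlen=min(x.size - 1, int(5 * fs_hz)))


def _highpass(x: np.ndarray, fs_hz: float, cutoff: float = 0.1, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs_hz, output="sos")
    # a 0.1 Hz filter has multi-second transients; pad generously
    return signal.sosfiltfilt(sos, x, padlen=min(x.size - 1, int(10 * fs_hz)))


def dominant_frequency(x: np.ndarray, fs_hz: float, lo: float = 0.5, hi: float = 3.0) -> float:
    """Frequency of the largest spectral peak within [lo, hi] Hz."""
    x = x - np.mean(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs_hz)
    power = np.abs(np.fft.rfft(x)) ** 2
    band = (freqs >= lo) & (freqs <= hi)
    if not np.any(band) or not np.any(power[band] > 0):
        return float("nan")
    return float(freqs[band][np.argmax(power[band])])


def detect_steps(
    x_g: np.ndarray,
    fs_hz: float,
    band: tuple[float, float] = (0.5, 3.0),
    min_steps: int = 4,
) -> np.ndarray:
    """Step-event times (s, relative to the array start) from the vertical channel.

    Peaks of the band-passed signal mark foot contacts; the minimum
    inter-peak distance is a quarter period of the spectral
    step-frequency estimate.  Raises :class:`StepDetectionError` with a
    reason when fewer than ``min_steps`` peaks emerge.
    """
    x = np.asarray(x_g, dtype=float)
    if x.size < int(fs_hz * 2):
        raise StepDetectionError("segment shorter than 2 s")
    ac = x - np.mean(x)
    # a walking signal concentrates its power in the gait band; reject
    # windows whose rhythm is noise-like before hunting for peaks
    freqs = np.fft.rfftfreq(ac.size, d=1.0 / fs_hz)
    power = np.abs(np.fft.rfft(ac)) ** 2
    total = float(np.sum(power[1:]))
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if total == 0.0 or float(np.sum(power[in_band])) / total < 0.2:
        raise StepDetectionError("no dominant gait rhythm in the 0.5-3 Hz band")
    filtered = _bandpass(ac, fs_hz, *band)
    f_est = dominant_frequency(filtered, fs_hz, *band)
    if not np.isfinite(f_est) or f_est <= 0:
        raise StepDetectionError("no dominant frequency in the gait band")
    min_dist = max(1, int(round(0.25 / f_est * fs_hz)))
    prominence = 0.5 * float(np.std(filtered))
    if prominence == 0.0:
        raise StepDetectionError("flat signal")
    peaks, _ = signal.find_peaks(filtered, distance=min_dist, prominence=prominence)
    if peaks.size < min_steps:
        raise StepDetectionError(f"only {peaks.size} peaks found (need {min_steps})")
    return peaks / fs_hz


def step_frequency(step_times: np.ndarray) -> float:
    """Steps per second, ``(n - 1) / (t_n - t_1)``; NaN-flagged below 4 steps."""
    t = np.asarray(step_times, dtype=float)
    if t.size < 4:
        return float("nan")
    return float((t.size - 1) / (t[-1] - t[0]))


def stride_time_cv(step_times: np.ndarray) -> float:
    """CV (population sd / mean) of stride intervals = alternate-step differences."""
    t = np.asarray(step_times, dtype=float)
    if t.size < 4:
        return float("nan")
    strides = t[2:] - t[:-2]
    mean = float(np.mean(strides))
    if mean == 0:
        return float("nan")
    return float(np.std(strides) / mean)


def pendulum_step_length(leg_length_m: float, h_m) -> np.ndarray | float:
    """Inverted-pendulum step length ``2*sqrt(2*l*h - h**2)``; h clipped to [0, l]."""
    h = np.clip(np.asarray(h_m, dtype=float), 0.0, leg_length_m)
    s = 2.0 * np.sqrt(2.0 * leg_length_m * h - h * h)
    return float(s) if s.ndim == 0 else s


def stride_length(
    x_g: np.ndarray,
    fs_hz: float,
    step_times: np.ndarray,
    leg_length_m: float,
    highpass_hz: float | None = None,
) -> tuple[np.ndarray, float, int]:
    """Per-step inverted-pendulum lengths from double-integrated vertical acceleration.

    Drift control: the mean is removed from the acceleration, the
    velocity is linearly detrended after the first integration, and the
    displacement is linearly re-zeroed within each step before the
    peak-to-trough excursion ``h`` is read off.  (A 0.1 Hz Butterworth
    stage is available via ``highpass_hz`` but off by default: at
    62.5 Hz its filtfilt transients bias the excursion far more than the
    drift it removes.)  Steps whose excursion collapses to zero are
    dropped and counted.

    Returns ``(per_step_lengths, mean_length, n_dropped)``.
    """
    if leg_length_m <= 0:
        raise ValueError("leg_length_m must be > 0")
    t_steps = np.asarray(step_times, dtype=float)
    if t_steps.size < 2:
        raise StepDetectionError("need at least 2 step events for stride length")
    a = np.asarray(x_g, dtype=float) * G0
    a = a - np.mean(a)
    if highpass_hz:
        a = _highpass(a, fs_hz, highpass_hz)
    v = integrate.cumulative_trapezoid(a, dx=1.0 / fs_hz, initial=0.0)
    v = signal.detrend(v)
    d = integrate.cumulative_trapezoid(v, dx=1.0 / fs_hz, initial=0.0)

    lengths = []
    dropped = 0
    for t0, t1 in zip(t_steps[:-1], t_steps[1:]):
        i0, i1 = int(round(t0 * fs_hz)), int(round(t1 * fs_hz)) + 1
        seg = d[i0:i1]
        if seg.size < 3:
            dropped += 1
            continue
        seg = signal.detrend(seg)  # per-step re-zeroing
        h = float(np.max(seg) - np.min(seg))
        if h <= 0.0:
            dropped += 1
            continue
        lengths.append(pendulum_step_length(leg_length_m, h))
    if not lengths:
        raise StepDetectionError("no usable steps after integration")
    per_step = np.asarray(lengths)
    return per_step, float(np.mean(per_step)), dropped


def velocity(step_frequency_hz: float, mean_step_length_m: float) -> float:
    """Segment-mean walking speed: step frequency times mean step length."""
    if not (np.isfinite(step_frequency_hz) and np.isfinite(mean_step_length_m)):
        raise ValueError("velocity requires finite inputs")
    return float(step_frequency_hz * mean_step_length_m)


def extract_features(
    x_g: np.ndarray,
    fs_hz: float,
    leg_length_m: float,
    params: SampEnParams | None = None,
) -> GaitFeatureSet:
    """All gait descriptors for one walking-segment slice of the belt x channel."""
    params = params or SampEnParams()
    steps = detect_steps(x_g, fs_hz)
    f = step_frequency(steps)
    cv = stride_time_cv(steps)
    _, mean_len, _ = stride_length(x_g, fs_hz, steps, leg_length_m)
    v = velocity(f, mean_len)
    ent = sample_entropy(np.asarray(x_g, dtype=float) - float(np.mean(x_g)), params)
    return GaitFeatureSet(
        sample_entropy=ent,
        step_frequency_hz=f,
        stride_length_m=mean_len,
        velocity_m_s=v,
        stride_time_cv=cv,
        n_steps=int(steps.size),
        velocity_consistent=abs(v - f * mean_len) <= VELOCITY_CONSISTENCY_TOL,
    )
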