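"""Walking-bout detection from leg-sensor windows.

Overlapping windows (2.56 s = 160 samples at 62.5 Hz, 50% overlap) are
summarized by four features of the leg magnitude signals — variance,
dominant frequency in the 0.5-3 Hz gait band, band power ratio and
inter-leg correlation — and scored by a transparent logistic model.
Two leg sensors suffice; wrist/belt channels are never required.
Positive windows are merged into contiguous walking segments long enough
for entropy estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from pdgait.preprocess import SessionRecording, magnitude

FEATURE_COLUMNS = ("log_variance", "dom_freq_hz", "band_ratio", "leg_corr")

GAIT_BAND_HZ = (0.5, 3.0)

#: Tiny variance floor so the log feature stays finite on constant windows.
_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class WalkingSegment:
    """A contiguous interval classified as walking."""

    start_s: float
    end_s: float
    score: float
    sensors: tuple[str, ...] = ("left_leg", "right_leg")

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("segment must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class WalkingModel:
    """Logistic score on the four window features.

    ``score = sigmoid(coef . features + intercept)``; walking iff
    ``score >= threshold``.  Feature order is :data:`FEATURE_COLUMNS`.
    """

    coef: tuple[float, float, float, float]
    intercept: float
    threshold: float = 0.5

    def score(self, features: np.ndarray) -> np.ndarray:
        z = features @ np.asarray(self.coef) + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


# Fitted once with fit_walking_model(seed=20240618) on a simulated labeled
# session set (profiles spanning 1.4-2.6 Hz, CV 0-0.15, noise 0.01-0.08);
# frozen here so classification is deterministic without sklearn at runtime.
DEFAULT_WALKING_MODEL = WalkingModel(
    coef=(4.4614946, -0.7549106, 3.2052662, 1.7570056),
    intercept=6.8612767,
)


def _window_starts(n_samples: int, window: int, hop: int) -> np.ndarray:
    if n_samples < window:
        return np.array([], dtype=int)
    return np.arange(0, n_samples - window + 1, hop)


def window_features(
    session: SessionRecording,
    window_s: float = 2.56,
    overlap: float = 0.5,
    sensors: Sequence[str] = ("left_leg", "right_leg"),
) -> pd.DataFrame:
    """Per-window leg features for walking classification.

    Columns: window times, mean leg log10-variance of the magnitude,
    mean dominant frequency in the gait band, mean band power ratio
    (gait band power over total AC power), inter-leg correlation, and a
    validity flag (False where gap-masked samples dominate the window).
    Returns an empty flagged frame when the recording is shorter than
    one window.
    """
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    legs = [session.sensors[s] for s in sensors]
    fs = session.fs_hz
    window = int(round(window_s * fs))
    hop = max(1, int(round(window * (1.0 - overlap))))
    n = min(len(r) for r in legs)
    starts = _window_starts(n, window, hop)

    freqs = np.fft.rfftfreq(window, d=1.0 / fs)
    band = (freqs >= GAIT_BAND_HZ[0]) & (freqs <= GAIT_BAND_HZ[1])

    rows = []
    mags = [r.magnitude_g for r in legs]
    masks = [r.gap_mask for r in legs]
    for s0 in starts:
        sl = slice(s0, s0 + window)
        variances, domfreqs, ratios = [], [], []
        segs = []
        for mag in mags:
            seg = mag[sl] - np.mean(mag[sl])
            segs.append(seg)
            variances.append(np.var(seg))
            power = np.abs(np.fft.rfft(seg)) ** 2
            total = np.sum(power[1:])
            if total > 0:
                domfreqs.append(freqs[band][np.argmax(power[band])])
                ratios.append(np.sum(power[band]) / total)
            else:
                domfreqs.append(0.0)
                ratios.append(0.0)
        sd0, sd1 = np.std(segs[0]), np.std(segs[1])
        if sd0 > 0 and sd1 > 0:
            corr = float(np.corrcoef(segs[0], segs[1])[0, 1])
        else:
            corr = 0.0
        masked_frac = max(float(np.mean(m[sl])) for m in masks)
        rows.append(
            {
                "t_start_s": s0 / fs,
                "t_end_s": (s0 + window) / fs,
                "log_variance": np.log10(np.mean(variances) + _VAR_FLOOR),
                "dom_freq_hz": float(np.mean(domfreqs)),
                "band_ratio": float(np.mean(ratios)),
                "leg_corr": corr,
                "valid": masked_frac <= 0.25,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["t_start_s", "t_end_s", *FEATURE_COLUMNS, "valid"],
    )
    df.attrs["window_s"] = window / fs
    df.attrs["hop_s"] = hop / fs
    df.attrs["too_short"] = starts.size == 0
    return df


def classify_walking(features: pd.DataFrame, model: WalkingModel | None = None) -> pd.DataFrame:
    """Score windows and attach boolean ``walking`` plus ``unknown`` flags.

    Windows with non-finite features (or flagged invalid upstream) are
    marked unknown and classified non-walking.
    """
    model = model or DEFAULT_WALKING_MODEL
    out = features.copy()
    if len(out) == 0:
        out["score"] = pd.Series(dtype=float)
        out["walking"] = pd.Series(dtype=bool)
        out["unknown"] = pd.Series(dtype=bool)
        return out
    X = out[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    finite = np.all(np.isfinite(X), axis=1)
    score = np.full(len(out), np.nan)
    score[finite] = model.score(X[finite])
    unknown = ~finite
    if "valid" in out:
        unknown |= ~out["valid"].to_numpy(dtype=bool)
    out["score"] = score
    out["walking"] = np.where(unknown, False, score >= model.threshold)
    out["unknown"] = unknown
    return out


def merge_windows(
    classified: pd.DataFrame,
    min_duration_s: float = 10.0,
    max_gap_windows: int = 1,
) -> list[WalkingSegment]:
    """Merge positive windows into segments.

    Runs of walking windows are joined; interruptions of at most
    ``max_gap_windows`` negative windows inside a run are absorbed;
    segments shorter than ``min_duration_s`` are dropped.
    """
    if len(classified) == 0:
        return []
    walking = classified["walking"].to_numpy(dtype=bool)
    starts = classified["t_start_s"].to_numpy(dtype=float)
    ends = classified["t_end_s"].to_numpy(dtype=float)
    scores = classified["score"].to_numpy(dtype=float)

    segments: list[WalkingSegment] = []
    i = 0
    n = len(walking)
    while i < n:
        if not walking[i]:
            i += 1
            continue
        j = i
        gap = 0
        last_pos = i
        while j + 1 < n:
            if walking[j + 1]:
                j += 1
                last_pos = j
                gap = 0
            elif gap < max_gap_windows:
                j += 1
                gap += 1
            else:
                break
        j = last_pos
        seg_scores = scores[i : j + 1]
        seg = WalkingSegment(
            start_s=float(starts[i]),
            end_s=float(ends[j]),
            score=float(np.nanmean(seg_scores)),
        )
        if seg.duration_s >= min_duration_s:
            segments.append(seg)
        i = j + 1
    return segments


def segments_to_frame(segments: Sequence[WalkingSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"start_s": s.start_s, "end_s": s.end_s, "score": s.score} for s in segments],
        columns=["start_s", "end_s", "score"],
    )


def fit_walking_model(
    seed: int = 20240618,
    n_sessions: int = 12,
    session_s: float = 120.0,
    threshold: float = 0.5,
) -> WalkingModel:
    """Fit the logistic window classifier on a seeded synthetic session set.

    Used once to produce :data:`DEFAULT_WALKING_MODEL`; kept so the fit
    is reproducible.  Requires scikit-learn.
    """
    from sklearn.linear_model import LogisticRegression

    from pdgait.synthetic import ActivitySchedule, GaitProfile, simulate_session
    from pdgait.preprocess import Recording

    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for k in range(n_sessions):
        profile = GaitProfile(
            step_frequency_hz=rng.uniform(1.4, 2.6),
            stride_time_cv=rng.uniform(0.0, 0.15),
            com_excursion_m=rng.uniform(0.02, 0.08),
            leg_length_m=rng.uniform(0.8, 1.1),
            asymmetry=rng.uniform(0.0, 0.3),
            harmonic_noise_sd=rng.uniform(0.01, 0.08),
        )
        third = session_s / 3.0
        schedule = ActivitySchedule.from_pairs(
            [(0, third, "walking"), (third, 2 * third, "resting"), (2 * third, session_s, "arm_task")]
        )
        sim = simulate_session(schedule, profile, seed=int(rng.integers(2**31)))
        session = SessionRecording(fs_hz=sim.fs_hz)
        for name, sig in sim.signals.items():
            session.sensors[name] = Recording(
                sensor_id=name,
                t0_s=0.0,
                fs_hz=sim.fs_hz,
                acc_g=sig,
                gap_mask=np.zeros(sig.shape[0], dtype=bool),
            )
        feats = window_features(session)
        labels = []
        for _, row in feats.iterrows():
            i0 = int(round(row["t_start_s"] * sim.fs_hz))
            i1 = int(round(row["t_end_s"] * sim.fs_hz))
            win = sim.labels[i0:i1]
            labels.append(np.mean(win == "walking") > 0.5)
        X_parts.append(feats[list(FEATURE_COLUMNS)].to_numpy(dtype=float))
        y_parts.append(np.asarray(labels, dtype=bool))
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    clf = LogisticRegression(max_iter=2000)
    clf.fit(X, y)
    return WalkingModel(
        coef=tuple(np.round(clf.coef_[0], 7)),
        intercept=float(np.round(clf.intercept_[0], 7)),
        threshold=threshold,
    )
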