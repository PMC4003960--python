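"""Normalization, 3-axis module and gap handling -> analysis-ready recordings.

Features downstream operate on raw g values; the [0, 1] normalization
(subtract the -6 g minimum, divide by the 12 g range) exists for
plotting/export parity.  Gaps no longer than one minimal reconnect burst
(4 samples) are linearly interpolated and masked; longer gaps split a
recording rather than fabricate data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pdgait.ban_io import FS_HZ, FULL_SCALE_G, PacketStream
from pdgait.qc import detect_gaps


@dataclass
class FillPolicy:
    """Gap repair: interpolate up to ``max_fill_samples``, split beyond."""

    max_fill_samples: int = 4


@dataclass
class Recording:
    """Uniformly gridded tri-axial signal from one sensor.

    ``acc_g`` is ``(n, 3)``; ``gap_mask`` is True at interpolated
    (originally missing) samples; ``t0_s`` is the grid start within the
    session.
    """

    sensor_id: str
    t0_s: float
    fs_hz: float
    acc_g: np.ndarray
    gap_mask: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.acc_g = np.asarray(self.acc_g, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape[0] != self.acc_g.shape[0]:
            raise ValueError("gap mask must align with the sample grid")

    def __len__(self) -> int:
        return self.acc_g.shape[0]

    @property
    def t_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs_hz

    @property
    def x(self) -> np.ndarray:  # cranio-caudal
        return self.acc_g[:, 0]

    @property
    def y(self) -> np.ndarray:  # medio-lateral
        return self.acc_g[:, 1]

    @property
    def z(self) -> np.ndarray:  # anterio-posterior
        return self.acc_g[:, 2]

    @property
    def magnitude_g(self) -> np.ndarray:
        return magnitude(self.x, self.y, self.z)

    def normalize(self) -> "Recording":
        """Return a copy with all channels mapped to [0, 1]."""
        if self.normalized:
            return self
        return Recording(
            self.sensor_id, self.t0_s, self.fs_hz, normalize(self.acc_g), self.gap_mask.copy(), True
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "ax_g": self.x,
                "ay_g": self.y,
                "az_g": self.z,
                "magnitude_g": self.magnitude_g,
                "gap": self.gap_mask.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def normalize(a_g, return_clipped: bool = False):
    """Map acceleration in g to [0, 1]: ``(a + 6) / 12``, clipped.

    Values outside the +/-6 g full scale are clipped; with
    ``return_clipped`` the count of clipped entries is also returned.
    Non-finite input is rejected.
    """
    a = np.asarray(a_g, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("normalize: non-finite input")
    out = (a + FULL_SCALE_G) / (2.0 * FULL_SCALE_G)
    clipped = int(np.sum((out < 0.0) | (out > 1.0)))
    out = np.clip(out, 0.0, 1.0)
    if np.isscalar(a_g):
        out = float(out)
    if return_clipped:
        return out, clipped
    return out


def magnitude(x, y, z):
    """Module of the 3-axis signal, ``sqrt(x^2 + y^2 + z^2)``, on raw g values."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise ValueError("magnitude: non-finite input")
    out = np.sqrt(x * x + y * y + z * z)
    return float(out) if out.ndim == 0 else out


def fill_gaps(stream: PacketStream, policy: FillPolicy | None = None) -> list[Recording]:
    """Grid a stream, interpolating short gaps and splitting at long ones.

    Gaps of at most ``policy.max_fill_samples`` missing samples are
    linearly interpolated between the bracketing observed values and
    masked; longer gaps end the current recording and start a new one.
    Observed samples are never altered.
    """
    policy = policy or FillPolicy()
    stream.validate()
    dt = stream.nominal_interval_ms
    ts = stream.timestamps_ms
    if ts.size == 0:
        return []

    # interior gaps only decide splits; leading/trailing loss just shifts t0
    bursts = detect_gaps(stream, include_edges=False)
    split_at = [b for b in bursts if b.missing_samples > policy.max_fill_samples]

    boundaries_ms = (
        [int(ts[0])]
        + [m for b in split_at for m in (b.start_ms, b.end_ms)]
        + [int(ts[-1]) + dt]
    )
    recordings: list[Recording] = []
    for seg_start, seg_end in zip(boundaries_ms[::2], boundaries_ms[1::2]):
        grid = np.arange(seg_start, seg_end, dt)
        idx = np.searchsorted(ts, grid)
        present = (idx < ts.size) & (ts[np.minimum(idx, ts.size - 1)] == grid)
        acc = np.empty((grid.size, 3))
        obs_idx = idx[present]
        acc[present] = stream.acc_g[obs_idx]
        if np.any(~present):
            t_obs = ts[obs_idx].astype(float)
            for c in range(3):
                acc[~present, c] = np.interp(grid[~present], t_obs, stream.acc_g[obs_idx, c])
        recordings.append(
            Recording(
                sensor_id=stream.sensor_id,
                t0_s=seg_start / 1000.0,
                fs_hz=1000.0 / dt,
                acc_g=acc,
                gap_mask=~present,
            )
        )
    return recordings


@dataclass
class SessionRecording:
    """All sensors aligned on one common grid spanning the whole session.

    Unlike :func:`fill_gaps`, long gaps are kept in place and masked
    (``valid_mask`` False) so sensors stay sample-aligned for windowed
    multi-sensor features; windows touching invalid samples are skipped
    downstream.
    """

    fs_hz: float
    sensors: dict[str, Recording] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return max((len(r) for r in self.sensors.values()), default=0)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def assemble_session(
    streams: Mapping[str, PacketStream] | Sequence[PacketStream],
    policy: FillPolicy | None = None,
) -> SessionRecording:
    """Grid every stream over its full expected span on a shared timebase.

    Short gaps are interpolated; samples inside longer gaps (and any
    leading/trailing loss) hold the nearest observed value but are
    flagged in the gap mask, keeping all sensors index-aligned.
    """
    policy = policy or FillPolicy()
    if not isinstance(streams, Mapping):
        streams = {s.sensor_id: s for s in streams}
    intervals = {s.nominal_interval_ms for s in streams.values()}
    interval_ms = intervals.pop() if len(intervals) == 1 else 16
    session = SessionRecording(fs_hz=1000.0 / interval_ms)
    span = max((s.span_ms for s in streams.values()), default=0)
    for name in sorted(streams):
        stream = streams[name]
        stream.validate()
        dt = stream.nominal_interval_ms
        grid = np.arange(0, span, dt)
        ts = stream.timestamps_ms
        acc = np.zeros((grid.size, 3))
        mask = np.ones(grid.size, dtype=bool)
        if ts.size:
            idx = np.searchsorted(ts, grid)
            present = (idx < ts.size) & (ts[np.minimum(idx, ts.size - 1)] == grid)
            acc[present] = stream.acc_g[idx[present]]
            if np.any(~present):
                for c in range(3):
                    acc[~present, c] = np.interp(
                        grid[~present].astype(float), ts.astype(float), stream.acc_g[:, c]
                    )
            mask = ~present
        session.sensors[name] = Recording(
            sensor_id=name,
            t0_s=0.0,
            fs_hz=1000.0 / dt,
            acc_g=acc,
            gap_mask=mask,
        )
    return session


def plot_session(session: SessionRecording, sensor: str = "belt", normalized: bool = True, ax=None):
    """Three-panel per-axis plot of one sensor (import-light matplotlib helper)."""
    import matplotlib.pyplot as plt

    rec = session.sensors[sensor]
    if normalized:
        rec = rec.normalize()
    if ax is None:
        _, ax = plt.subplots(3, 1, sharex=True, figsize=(10, 6))
    for i, name in enumerate(("x (cranio-caudal)", "y (medio-lateral)", "z (anterio-posterior)")):
        ax[i].plot(rec.t_s, rec.acc_g[:, i], lw=0.5)
        ax[i].set_ylabel(name)
    ax[-1].set_xlabel("time (s)")
    return ax
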