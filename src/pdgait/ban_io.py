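"""Packet-stream I/O and validation for the body-area-network data model.

A session is recorded by five tri-axial accelerometers (belt, both wrists,
both legs) sampled at 62.5 Hz, i.e. one packet every 16 ms.  Every packet
carries a unique integer-millisecond timestamp on the 16 ms grid; missing
timestamps are the only evidence of transmission loss, so stream validity
(strict ordering, grid alignment, uniqueness) is enforced here before any
downstream stage runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Nominal sampling rate of every sensor (Hz).
FS_HZ = 62.5
#: Nominal inter-sample interval (ms); the timestamp grid.
NOMINAL_INTERVAL_MS = 16
#: Accelerometer full scale: each axis is within [-6, +6] g.
FULL_SCALE_G = 6.0
#: Sensor placements, in canonical order.
SENSOR_IDS = ("belt", "left_wrist", "right_wrist", "left_leg", "right_leg")

CSV_COLUMNS = ("sensor_id", "timestamp_ms", "ax_g", "ay_g", "az_g")


class FormatError(ValueError):
    """Raised when a packet file does not conform to the CSV dialect."""


class IntegrityError(ValueError):
    """Raised when packet content violates the data-model invariants."""


@dataclass(frozen=True)
class Packet:
    """A single transmitted sample from one sensor."""

    sensor_id: str
    timestamp_ms: int
    ax_g: float
    ay_g: float
    az_g: float


@dataclass
class PacketStream:
    """Time-ordered packets from one sensor.

    Parameters
    ----------
    sensor_id:
        One of :data:`SENSOR_IDS`.
    timestamps_ms:
        Strictly increasing integer timestamps, each a multiple of
        ``nominal_interval_ms``.
    acc_g:
        ``(n, 3)`` float array of (x, y, z) acceleration in g.
    session_expected_span_ms:
        Expected session duration in ms.  The nominal grid covers
        timestamps ``0, 16, ..., span - 16``; leading/trailing loss is
        measurable only against this span.  ``None`` means "infer from
        the data" (grid from 0 to the last timestamp).
    """

    sensor_id: str
    timestamps_ms: np.ndarray
    acc_g: np.ndarray
    nominal_interval_ms: int = NOMINAL_INTERVAL_MS
    session_expected_span_ms: int | None = None

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=np.int64)
        self.acc_g = np.atleast_2d(np.asarray(self.acc_g, dtype=float))
        if self.acc_g.size == 0:
            self.acc_g = self.acc_g.reshape(0, 3)
        if self.acc_g.shape != (self.timestamps_ms.size, 3):
            raise IntegrityError(
                f"{self.sensor_id}: acc_g shape {self.acc_g.shape} does not match "
                f"{self.timestamps_ms.size} timestamps"
            )

    def __len__(self) -> int:
        return int(self.timestamps_ms.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PacketStream):
            return NotImplemented
        return (
            self.sensor_id == other.sensor_id
            and self.nominal_interval_ms == other.nominal_interval_ms
            and self.session_expected_span_ms == other.session_expected_span_ms
            and np.array_equal(self.timestamps_ms, other.timestamps_ms)
            and np.array_equal(self.acc_g, other.acc_g)
        )

    @property
    def span_ms(self) -> int:
        """Session span covered by the nominal grid (ms)."""
        if self.session_expected_span_ms is not None:
            return int(self.session_expected_span_ms)
        if len(self) == 0:
            return 0
        return int(self.timestamps_ms[-1]) + self.nominal_interval_ms

    @property
    def expected_samples(self) -> int:
        """Number of samples the nominal grid would hold over the span."""
        return self.span_ms // self.nominal_interval_ms

    def validate(self) -> None:
        """Raise :class:`IntegrityError` on any data-model violation."""
        ts = self.timestamps_ms
        if ts.size and ts[0] < 0:
            raise IntegrityError(f"{self.sensor_id}: negative timestamp {ts[0]}")
        if ts.size > 1:
            d = np.diff(ts)
            if np.any(d <= 0):
                bad = int(np.argmax(d <= 0))
                raise IntegrityError(
                    f"{self.sensor_id}: timestamps not strictly increasing at index {bad + 1} "
                    f"({ts[bad]} -> {ts[bad + 1]})"
                )
        off = ts % self.nominal_interval_ms != 0
        if np.any(off):
            bad_ts = ts[off][:5].tolist()
            raise IntegrityError(
                f"{self.sensor_id}: timestamps not on the {self.nominal_interval_ms} ms "
                f"grid: {bad_ts}"
            )
        if not np.all(np.isfinite(self.acc_g)):
            raise IntegrityError(f"{self.sensor_id}: non-finite acceleration values")
        if np.any(np.abs(self.acc_g) > FULL_SCALE_G):
            raise IntegrityError(
                f"{self.sensor_id}: acceleration outside +/-{FULL_SCALE_G} g full scale"
            )
        if self.session_expected_span_ms is not None and ts.size:
            if ts[-1] >= self.session_expected_span_ms:
                raise IntegrityError(
                    f"{self.sensor_id}: timestamp {ts[-1]} beyond expected span "
                    f"{self.session_expected_span_ms}"
                )

    def packets(self) -> Iterable[Packet]:
        for i in range(len(self)):
            yield Packet(
                self.sensor_id,
                int(self.timestamps_ms[i]),
                float(self.acc_g[i, 0]),
                float(self.acc_g[i, 1]),
                float(self.acc_g[i, 2]),
            )

    def copy(self) -> "PacketStream":
        return replace(self, timestamps_ms=self.timestamps_ms.copy(), acc_g=self.acc_g.copy())


def read_packet_csv(
    path: str | Path,
    *,
    strict: bool = True,
    session_expected_span_ms: int | None = None,
) -> dict[str, PacketStream]:
    """Read a packet CSV into one :class:`PacketStream` per sensor.

    The dialect is one row per packet with header
    ``sensor_id,timestamp_ms,ax_g,ay_g,az_g``; gzip is transparent by
    ``.gz`` extension.  Rows are sorted by timestamp per sensor before
    validation.

    With ``strict=True`` (default) any row violating a packet invariant
    aborts the read with a row-numbered :class:`IntegrityError`; with
    ``strict=False`` offending rows are dropped and reported via the
    returned streams' diagnostics attribute.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    diagnostics: list[str] = []
    # +2: header line plus 1-based numbering, so messages match editors.
    row_no = df.index.to_numpy() + 2

    bad = pd.Series(False, index=df.index)
    with np.errstate(invalid="ignore"):
        ts_ok = np.isfinite(df["timestamp_ms"].to_numpy(dtype=float))
        ts_int = df["timestamp_ms"].to_numpy(dtype=float)
        grid_ok = ts_ok & (np.mod(ts_int, NOMINAL_INTERVAL_MS) == 0) & (ts_int >= 0)
        acc = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
        acc_ok = np.all(np.isfinite(acc), axis=1) & np.all(np.abs(acc) <= FULL_SCALE_G, axis=1)
    bad |= ~grid_ok
    bad |= ~acc_ok
    for i in np.flatnonzero(bad.to_numpy()):
        diagnostics.append(f"row {row_no[i]}: invalid packet {df.iloc[i].to_dict()}")
    if strict and diagnostics:
        raise IntegrityError("; ".join(diagnostics[:10]))
    df = df[~bad]

    dup = df.duplicated(subset=["sensor_id", "timestamp_ms"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["sensor_id", "timestamp_ms"]].drop_duplicates()
        listing = ", ".join(f"({r.sensor_id}, {int(r.timestamp_ms)})" for r in pairs.itertuples())
        raise IntegrityError(f"{path}: duplicate (sensor, timestamp) pairs: {listing}")

    streams: dict[str, PacketStream] = {}
    for sensor_id, grp in df.groupby("sensor_id", sort=True):
        grp = grp.sort_values("timestamp_ms")
        stream = PacketStream(
            sensor_id=str(sensor_id),
            timestamps_ms=grp["timestamp_ms"].to_numpy(dtype=np.int64),
            acc_g=grp[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
            session_expected_span_ms=session_expected_span_ms,
        )
        stream.validate()
        stream.diagnostics = list(diagnostics)  # type: ignore[attr-defined]
        streams[str(sensor_id)] = stream
    return streams


def write_packet_csv(streams: Mapping[str, PacketStream] | Iterable[PacketStream], path: str | Path) -> None:
    """Write streams to the packet CSV dialect (inverse of :func:`read_packet_csv`).

    Streams are validated first; a stream with off-grid timestamps is
    refused.  Output order is deterministic: sensors sorted by id, rows
    by timestamp.  Float formatting uses ``repr`` round-tripping so a
    write/read cycle preserves values exactly.
    """
    if isinstance(streams, Mapping):
        stream_list = [streams[k] for k in sorted(streams)]
    else:
        stream_list = sorted(streams, key=lambda s: s.sensor_id)
    frames = []
    for s in stream_list:
        s.validate()
        frames.append(
            pd.DataFrame(
                {
                    "sensor_id": s.sensor_id,
                    "timestamp_ms": s.timestamps_ms,
                    "ax_g": s.acc_g[:, 0],
                    "ay_g": s.acc_g[:, 1],
                    "az_g": s.acc_g[:, 2],
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(CSV_COLUMNS))
    out.to_csv(path, index=False)
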