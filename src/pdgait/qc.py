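"""Transmission quality control from packet timestamps.

Because the sensors have no retransmission protocol, the only evidence of
loss is a hole in the 16 ms timestamp grid.  This module turns those
holes into burst records, per-window loss percentages and burst-length
statistics (mean +/- sd, mode), and implements the startup-trimming rule:
discard everything before the first sustained gap-free window, since the
longest bursts cluster at the start of a session while the sensors
connect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pdgait.ban_io import FS_HZ, IntegrityError, PacketStream


@dataclass(frozen=True)
class Burst:
    """A run of consecutive lost packets.

    ``start_ms`` is the timestamp of the first missing sample and
    ``end_ms`` the first present timestamp after the gap (exclusive), so
    ``duration_ms = end_ms - start_ms = missing_samples * 16``.
    """

    start_ms: int
    end_ms: int
    missing_samples: int

    def __post_init__(self) -> None:
        if self.missing_samples < 1:
            raise ValueError("a burst must miss at least one sample")
        if self.end_ms - self.start_ms != self.duration_ms:
            raise ValueError("burst boundaries inconsistent with missing_samples")

    @property
    def duration_ms(self) -> int:
        return self.missing_samples * 16


@dataclass
class BurstStats:
    """Mean +/- sd and mode of burst durations; ``n = 0`` is the empty sentinel."""

    n: int = 0
    mean_ms: float = float("nan")
    sd_ms: float = float("nan")
    modal_ms: int | None = None


@dataclass
class LossStats:
    """Per-window loss percentage summary; sd is NaN (flagged) for a single window."""

    mean_percent: float
    sd_percent: float
    n_windows: int
    per_window_percent: np.ndarray
    single_window: bool = False


@dataclass
class TrimResult:
    stream: PacketStream | None
    startup_trimmed_ms: int
    passed: bool
    reason: str = ""


@dataclass
class TrimPolicy:
    """Startup trimming: drop everything before ``stable_s`` gap-free seconds."""

    stable_s: float = 10.0


@dataclass
class LossReport:
    """One sensor's quality row: loss %, burst stats, startup trim."""

    sensor_id: str
    loss: LossStats
    bursts: list[Burst]
    burst_stats: BurstStats
    startup_trimmed_ms: int = 0
    qc_passed: bool = True

    def to_dict(self) -> dict:
        return {
            "sensor_id": self.sensor_id,
            "loss_percent_mean": self.loss.mean_percent,
            "loss_percent_sd": self.loss.sd_percent,
            "n_windows": self.loss.n_windows,
            "n_bursts": len(self.bursts),
            "mean_burst_ms": self.burst_stats.mean_ms,
            "sd_burst_ms": self.burst_stats.sd_ms,
            "modal_burst_ms": self.burst_stats.modal_ms,
            "startup_trimmed_ms": self.startup_trimmed_ms,
            "qc_passed": self.qc_passed,
        }


def detect_gaps(stream: PacketStream, include_edges: bool = True) -> list[Burst]:
    """Find bursts of missing samples from timestamp gaps.

    Between consecutive timestamps ``t_i < t_{i+1}`` a burst is emitted
    iff the gap exceeds one nominal interval, with
    ``missing_samples = (t_{i+1} - t_i)/16 - 1``.  With ``include_edges``
    (default) loss before the first packet and — when the stream carries
    an expected session span — after the last packet is also counted, so
    that received + missing always equals the expected sample count.
    """
    stream.validate()
    dt = stream.nominal_interval_ms
    ts = stream.timestamps_ms
    if ts.size == 0:
        if include_edges and stream.span_ms > 0:
            n = stream.span_ms // dt
            return [Burst(0, stream.span_ms, n)]
        return []

    bursts: list[Burst] = []
    if include_edges and ts[0] > 0:
        bursts.append(Burst(0, int(ts[0]), int(ts[0]) // dt))
    gaps = np.diff(ts)
    for i in np.flatnonzero(gaps > dt):
        missing = int(gaps[i]) // dt - 1
        start = int(ts[i]) + dt
        bursts.append(Burst(start, start + missing * dt, missing))
    if include_edges and stream.session_expected_span_ms is not None:
        tail_start = int(ts[-1]) + dt
        if tail_start < stream.span_ms:
            missing = (stream.span_ms - tail_start) // dt
            bursts.append(Burst(tail_start, stream.span_ms, missing))
    return bursts


def loss_percentage(stream: PacketStream, window_s: float = 60.0) -> LossStats:
    """Mean +/- sd of per-window loss percent across fixed-length windows.

    Per window, ``loss = 100 * missing / expected`` with
    ``expected = window_s * 62.5``.  Windows tile the expected session
    span; if the span is shorter than one window a single-window report
    is returned with sd flagged as undefined (NaN).
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    stream.validate()
    dt = stream.nominal_interval_ms
    span = stream.span_ms
    window_ms = window_s * 1000.0
    n_windows = int(span // window_ms)
    single = n_windows < 2
    if n_windows == 0:
        n_windows = 1
        window_ms = float(max(span, dt))

    edges_ms = np.arange(n_windows + 1) * window_ms
    # expected = grid slots per window (equals window_s * 62.5 when aligned)
    expected = np.diff(np.ceil(edges_ms / dt))
    ts = stream.timestamps_ms
    received = np.histogram(ts[ts < edges_ms[-1]], bins=edges_ms)[0]
    per_window = 100.0 * (expected - received) / expected
    return LossStats(
        mean_percent=float(np.mean(per_window)),
        sd_percent=float("nan") if single else float(np.std(per_window)),
        n_windows=n_windows,
        per_window_percent=per_window,
        single_window=single,
    )


def burst_statistics(bursts: Sequence[Burst]) -> BurstStats:
    """Arithmetic mean, population sd and mode of burst durations (ms).

    Mode ties break toward the smallest duration; the 16 ms grid makes
    durations discrete so no binning is needed.  An empty list returns
    the ``n = 0`` sentinel rather than raising.
    """
    if not bursts:
        return BurstStats()
    durations = np.array([b.duration_ms for b in bursts], dtype=float)
    values, counts = np.unique(durations, return_counts=True)
    modal = int(values[np.argmax(counts)])  # np.unique sorts ascending -> ties pick smallest
    return BurstStats(
        n=len(bursts),
        mean_ms=float(np.mean(durations)),
        sd_ms=float(np.std(durations)),
        modal_ms=modal,
    )


def trim_startup(stream: PacketStream, policy: TrimPolicy | None = None) -> TrimResult:
    """Discard all samples before the first ``stable_s`` seconds with zero gaps.

    Timestamps are rebased so the retained stream starts at 0 (the trim
    offset is a grid multiple, so grid alignment is preserved) and the
    expected span is shortened accordingly.  If no stable window exists
    the whole stream is rejected with a QC-fail status instead of an
    exception.
    """
    policy = policy or TrimPolicy()
    stream.validate()
    dt = stream.nominal_interval_ms
    ts = stream.timestamps_ms
    need = int(round(policy.stable_s * 1000.0 / dt))  # consecutive samples required

    if ts.size == 0:
        return TrimResult(None, stream.span_ms, False, "empty stream")

    # run-lengths of consecutive (gap-free) packets
    breaks = np.flatnonzero(np.diff(ts) != dt)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [ts.size - 1]])
    run_lengths = run_ends - run_starts + 1

    ok = np.flatnonzero(run_lengths >= need)
    if ok.size == 0:
        return TrimResult(None, stream.span_ms, False, f"no gap-free {policy.stable_s} s window")

    first = int(run_starts[ok[0]])
    t0 = int(ts[first])
    trimmed = PacketStream(
        sensor_id=stream.sensor_id,
        timestamps_ms=ts[first:] - t0,
        acc_g=stream.acc_g[first:],
        nominal_interval_ms=dt,
        session_expected_span_ms=(stream.span_ms - t0) if stream.session_expected_span_ms is not None else None,
    )
    return TrimResult(trimmed, t0, True)


def trim_session(
    streams: dict[str, PacketStream], policy: TrimPolicy | None = None
) -> tuple[dict[str, PacketStream], int, dict[str, TrimResult]]:
    """Trim all streams at a common point: wait for every sensor to stabilize.

    The session trim offset is the latest per-sensor stable start, so
    sensors stay sample-aligned afterwards.  Streams with no stable
    window are excluded (their :class:`TrimResult` reports the reason).
    Returns ``(trimmed streams, common offset ms, per-sensor results)``.
    """
    policy = policy or TrimPolicy()
    results = {name: trim_startup(s, policy) for name, s in streams.items()}
    offsets = [r.startup_trimmed_ms for r in results.values() if r.passed]
    if not offsets:
        return {}, 0, results
    common = max(offsets)
    trimmed: dict[str, PacketStream] = {}
    for name, stream in streams.items():
        if not results[name].passed:
            continue
        keep = stream.timestamps_ms >= common
        trimmed[name] = PacketStream(
            sensor_id=name,
            timestamps_ms=stream.timestamps_ms[keep] - common,
            acc_g=stream.acc_g[keep],
            nominal_interval_ms=stream.nominal_interval_ms,
            session_expected_span_ms=(
                stream.span_ms - common if stream.session_expected_span_ms is not None else None
            ),
        )
    return trimmed, common, results


def conservation_check(stream: PacketStream) -> bool:
    """Expected = received + sum of missing samples over all detected bursts."""
    missing = sum(b.missing_samples for b in detect_gaps(stream, include_edges=True))
    return stream.expected_samples == len(stream) + missing


def build_loss_report(
    stream: PacketStream,
    window_s: float = 60.0,
    trim: TrimPolicy | None = None,
) -> LossReport:
    """Full QC row for one stream: untrimmed loss/burst stats + trim outcome."""
    bursts = detect_gaps(stream)
    report = LossReport(
        sensor_id=stream.sensor_id,
        loss=loss_percentage(stream, window_s),
        bursts=bursts,
        burst_stats=burst_statistics(bursts),
    )
    result = trim_startup(stream, trim)
    report.startup_trimmed_ms = result.startup_trimmed_ms
    report.qc_passed = result.passed
    return report


def format_report_table(reports: Sequence[LossReport]) -> str:
    """Human-readable table: loss % / average burst length / most frequent burst."""
    header = (
        f"{'Sensor':<12} {'Data loss (%)':>18} {'Avg burst (ms)':>22} {'Modal burst (ms)':>18}"
    )
    lines = [header, "-" * len(header)]
    for r in reports:
        loss = f"{r.loss.mean_percent:.2f} +/- " + (
            "n/a" if np.isnan(r.loss.sd_percent) else f"{r.loss.sd_percent:.2f}"
        )
        if r.burst_stats.n:
            burst = f"{r.burst_stats.mean_ms:.2f} +/- {r.burst_stats.sd_ms:.2f}"
            modal = str(r.burst_stats.modal_ms)
        else:
            burst, modal = "no bursts", "-"
        lines.append(f"{r.sensor_id:<12} {loss:>18} {burst:>22} {modal:>18}")
    return "\n".join(lines)
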