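"""Per-sample time reconstruction (DerivedTime) for one packetized stream.

None of the device's per-packet time variables can serve alone as a
sample clock: the firmware timestamp has 1 s resolution, the hardware
tick counter rolls over every ~6.5535 s and drifts against the
timestamp, and the API-side PacketGenTime jitters between packets.  The
reconstruction therefore combines them:

1.  received packets are restored to creation order and cleaned by four
    rejection rules (timestamp outlier, negative PacketGenTime, backward
    PacketGenTime, PacketGenTime/timestamp disagreement);
2.  maximal runs of packets with no loss ("chunks") are identified from
    the sequence counter, the tick counter and the timestamp, given the
    sampling rate and per-packet sample counts;
3.  each chunk is anchored to unix time through the jitter-averaged
    Adjusted PacketGenTime of its first packet (or, optionally for short
    gaps, by bridging the gap with the tick counter), then every sample
    receives a time on the 1/Fs grid of the first chunk.

Within a chunk, sampling is exactly regular: the device samples
continuously and only whole packets go missing, never individual
samples.  Gaps between chunks remain empty here and are filled with
NaNs during harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyStreamError, UsageError
from .ingestion import Packet

__all__ = [
    "ClockConstants",
    "Chunk",
    "DerivedTimeSeries",
    "restore_packet_order",
    "reject_invalid_packets",
    "identify_chunks",
    "classify_gap",
    "adjusted_anchor",
    "derive_times_for_chunk",
    "derive_times_gap_method",
    "snap_to_grid",
    "reconstruct_stream",
]


@dataclass(frozen=True)
class ClockConstants:
    """Clock geometry and cleaning thresholds.

    ``tick_tolerance_ticks`` is the slack allowed between the tick-counter
    elapsed time and the sample-count elapsed time in the chunk continuity
    test: 10 ticks = 1 ms, far below one sample period at any supported
    rate but well above float rounding.
    """

    tick_seconds: float = 1e-4
    tick_modulus: int = 1 << 16
    timestamp_epoch_unix_s: int = 951_868_800  # 2000-03-01T00:00:00Z
    seq_modulus: int = 256
    short_gap_threshold_s: float = 6.0
    outlier_window_s: float = 24 * 3600.0
    backward_limit_ms: float = 500.0
    disagreement_limit_s: float = 2.0
    tick_tolerance_ticks: int = 10

    @property
    def tick_cycle_s(self) -> float:
        """Maximum elapsed time representable in one tick-counter cycle."""
        return (self.tick_modulus - 1) * self.tick_seconds  # 6.5535 s

    def timestamp_to_unix_ms(self, timestamp: int) -> float:
        return (timestamp + self.timestamp_epoch_unix_s) * 1000.0


@dataclass
class Chunk:
    """A maximal run of packets judged continuous (no loss, constant fs)."""

    start: int  # first packet index (into the cleaned list), inclusive
    stop: int  # last packet index, exclusive
    fs: float
    n_samples: int
    gap_class: str = "first"  # {"first", "short", "long"}
    anchor_time: float | None = None  # unix ms of the first packet's last sample

    @property
    def n_packets(self) -> int:
        return self.stop - self.start


@dataclass
class DerivedTimeSeries:
    """One stream on its reconstructed per-sample time base.

    ``derived_time`` = ``t_ref + grid_index * (1000 / fs)`` ms; the
    integer grid indices are kept so that downstream grid arithmetic is
    exact.  ``provenance`` maps each sample to the chunk that produced
    it; chunk/rejection reports ride along for gap attribution.
    """

    derived_time: np.ndarray
    samples: dict[str, np.ndarray]
    fs: float
    t_ref: float  # unix ms of grid index 0
    grid_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    provenance: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    chunks: list[Chunk] = field(default_factory=list)
    rejection_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    warnings: list[str] = field(default_factory=list)

    @property
    def step_ms(self) -> float:
        return 1000.0 / self.fs

    def __len__(self) -> int:
        return len(self.derived_time)


def restore_packet_order(packets: list[Packet]) -> list[Packet]:
    """Undo local transport reordering using the sequence counter.

    The transport may deliver adjacent packets swapped (possibly across
    a drop, so the two sequence numbers need not be consecutive).  A
    received pair (i, i+1) where packet i sits *ahead* of packet i+1 in
    mod-256 order — their difference is small and positive — is in
    swapped order; bubble passes swap such pairs back until stable.
    The half-modulus threshold distinguishes a swap from the counter
    rolling over, which would need >127 consecutive losses to confuse.
    """
    pkts = list(packets)
    for _ in range(len(pkts)):
        changed = False
        for i in range(len(pkts) - 1):
            a, b = pkts[i], pkts[i + 1]
            diff = (a.data_type_sequence - b.data_type_sequence) % 256
            if 0 < diff < 128:
                pkts[i], pkts[i + 1] = b, a
                changed = True
        if not changed:
            break
    return pkts


def reject_invalid_packets(
    packets: list[Packet], constants: ClockConstants = ClockConstants()
) -> tuple[list[Packet], pd.DataFrame]:
    """Remove packets whose timing metadata is faulty.

    Rules, in order; the backward and disagreement comparisons are made
    against the previous *kept* packet:

    1. timestamp more than 24 h away from the stream's median timestamp;
    2. negative PacketGenTime;
    3. PacketGenTime goes backward in time by more than 500 ms;
    4. elapsed PacketGenTime disagrees with elapsed timestamp by more
       than 2 s.
    """
    rows = []
    if not packets:
        return [], pd.DataFrame(columns=["index", "rule", "detail", "packet_gen_time"])
    median_ts = float(np.median([p.timestamp for p in packets]))
    kept: list[Packet] = []
    prev: Packet | None = None
    for i, p in enumerate(packets):
        if abs(p.timestamp - median_ts) > constants.outlier_window_s:
            rows.append(
                (i, "timestamp_outlier", f"timestamp {p.timestamp} vs median {median_ts}",
                 p.packet_gen_time)
            )
            continue
        if p.packet_gen_time < 0:
            rows.append((i, "negative_packet_gen_time", str(p.packet_gen_time), p.packet_gen_time))
            continue
        if prev is not None:
            back = prev.packet_gen_time - p.packet_gen_time
            if back > constants.backward_limit_ms:
                rows.append((i, "backward_packet_gen_time", f"went back {back} ms",
                             p.packet_gen_time))
                continue
            dis = abs(
                (p.packet_gen_time - prev.packet_gen_time) / 1000.0
                - (p.timestamp - prev.timestamp)
            )
            if dis > constants.disagreement_limit_s:
                rows.append((i, "pgt_timestamp_disagreement", f"disagree {dis:.3f} s",
                             p.packet_gen_time))
                continue
        kept.append(p)
        prev = p
    log = pd.DataFrame(rows, columns=["index", "rule", "detail", "packet_gen_time"])
    return kept, log


def _continuous(
    a: Packet, b: Packet, constants: ClockConstants
) -> bool:
    """True iff packet b directly continues packet a with no loss."""
    if a.sample_rate != b.sample_rate or b.sample_rate is None:
        return False
    if (b.data_type_sequence - a.data_type_sequence) % constants.seq_modulus != 1:
        return False
    expected_s = b.n_samples / b.sample_rate
    tick_s = (
        (b.system_tick - a.system_tick) % constants.tick_modulus
    ) * constants.tick_seconds
    if abs(tick_s - expected_s) > constants.tick_tolerance_ticks * constants.tick_seconds:
        return False
    if abs((b.timestamp - a.timestamp) - expected_s) > 1.0:
        return False
    return True


def identify_chunks(
    packets: list[Packet], constants: ClockConstants = ClockConstants()
) -> list[Chunk]:
    """Partition cleaned packets into maximal continuous chunks.

    Adjacent packets stay in one chunk iff the sequence counter advances
    by one (mod 256), the sampling rate is unchanged, the tick-counter
    elapsed time matches the sample-count elapsed time within tolerance,
    and the timestamp elapsed matches within its 1 s resolution.  A
    sampling-rate change always forces a new chunk.
    """
    chunks: list[Chunk] = []
    if not packets:
        return chunks
    start = 0
    for i in range(1, len(packets) + 1):
        if i == len(packets) or not _continuous(packets[i - 1], packets[i], constants):
            fs = packets[start].sample_rate
            n = sum(p.n_samples for p in packets[start:i])
            chunks.append(Chunk(start=start, stop=i, fs=fs, n_samples=n))
            start = i
    return chunks


def classify_gap(
    prev_chunk: Chunk, next_chunk: Chunk, packets: list[Packet],
    constants: ClockConstants = ClockConstants(),
) -> str:
    """"short" if the inter-chunk gap is under 6 s by timestamp, else "long".

    Short gaps are guaranteed to fit inside one tick-counter cycle, so
    the tick counter can bridge them unambiguously; at or beyond 6 s a
    full cycle may have elapsed.
    """
    ts_prev = packets[prev_chunk.stop - 1].timestamp
    ts_next = packets[next_chunk.start].timestamp
    return "short" if (ts_next - ts_prev) < constants.short_gap_threshold_s else "long"


def adjusted_anchor(chunk: Chunk, packets: list[Packet]) -> float:
    """Adjusted PacketGenTime of a chunk's first packet, in unix ms.

    Within a chunk the sample clock is exact, so each packet's expected
    time is the first packet's PacketGenTime plus the elapsed
    sample-count time; the observed deviations (PacketGenTime jitter)
    are averaged and applied as one correction to the first packet's
    PacketGenTime.  A single-packet chunk has no deviations to average
    and anchors on its own PacketGenTime.
    """
    pkts = packets[chunk.start : chunk.stop]
    first = pkts[0]
    if len(pkts) == 1:
        return float(first.packet_gen_time)
    fs = chunk.fs
    offsets = []
    cum = 0
    for p in pkts[1:]:
        cum += p.n_samples
        expected_ms = cum / fs * 1000.0
        offsets.append(p.packet_gen_time - (first.packet_gen_time + expected_ms))
    return float(first.packet_gen_time + np.mean(offsets))


def derive_times_for_chunk(chunk: Chunk, anchor: float, fs: float,
                           packets: list[Packet] | None = None,
                           c1: int | None = None) -> np.ndarray:
    """Unix ms for every sample of a chunk, given its anchor.

    The anchor is the time of the *last sample of the first packet*;
    sample m of the chunk (1-indexed, the first packet holding c1
    samples) falls at ``anchor + (m - c1) * 1000 / fs``.
    """
    if c1 is None:
        c1 = packets[chunk.start].n_samples
    m = np.arange(1, chunk.n_samples + 1)
    return anchor + (m - c1) * (1000.0 / fs)


def derive_times_gap_method(
    prev_last_derived_ms: float,
    prev_last_tick: int,
    next_chunk: Chunk,
    packets: list[Packet],
    gap_class: str,
    constants: ClockConstants = ClockConstants(),
) -> np.ndarray:
    """Anchor a short-gap chunk by bridging the gap with the tick counter.

    elapsed = ((tick_next - tick_prev) mod 2^16) * 1e-4 s, valid only
    when the gap stayed inside one tick cycle (gap classified short).
    Use only when the tick clock is known to be accurate: its rate error
    accumulates across every bridged gap, unlike the default anchoring.
    """
    if gap_class != "short":
        raise UsageError("tick-bridging applies only to short gaps")
    first = packets[next_chunk.start]
    elapsed_s = (
        (first.system_tick - prev_last_tick) % constants.tick_modulus
    ) * constants.tick_seconds
    anchor = prev_last_derived_ms + elapsed_s * 1000.0
    return derive_times_for_chunk(next_chunk, anchor, next_chunk.fs, packets)


def snap_to_grid(chunk_times: np.ndarray, t_ref: float, fs: float) -> np.ndarray:
    """Shift a chunk's times onto the grid {t_ref + k * 1000/fs}.

    One shift is applied to the whole chunk, chosen so its first time
    lands on the nearest grid point (|shift| <= half a sample period);
    within-chunk spacing is untouched.  An exact half-interval tie
    rounds toward the earlier grid point.
    """
    step = 1000.0 / fs
    x = (chunk_times[0] - t_ref) / step
    k = np.floor(x + 0.5)
    if x + 0.5 == k:  # exact tie: prefer the earlier grid point
        k -= 1
    delta = (t_ref + k * step) - chunk_times[0]
    return chunk_times + delta


def _grid_round(x: float) -> int:
    """Nearest integer with exact-half ties toward the smaller value."""
    k = np.floor(x + 0.5)
    if x + 0.5 == k:
        k -= 1
    return int(k)


def reconstruct_stream(
    packets: list[Packet],
    constants: ClockConstants = ClockConstants(),
    method: str = "default",
) -> DerivedTimeSeries:
    """Full reconstruction of one stream: clean, chunk, anchor, grid.

    ``method`` selects short-gap handling: ``"default"`` anchors every
    chunk by its Adjusted PacketGenTime; ``"gap"`` bridges short gaps
    with the tick counter (long gaps always use the default).  Returns
    an empty series with a warning when no packet survives cleaning.
    """
    if method not in ("default", "gap"):
        raise UsageError(f"method must be 'default' or 'gap', got {method!r}")
    ordered = restore_packet_order(packets)
    kept, rejection_log = reject_invalid_packets(ordered, constants)
    if not kept:
        return DerivedTimeSeries(
            derived_time=np.empty(0),
            samples={},
            fs=float("nan"),
            t_ref=float("nan"),
            rejection_log=rejection_log,
            warnings=["no usable packets in stream"],
        )
    chunks = identify_chunks(kept, constants)
    warnings: list[str] = []
    channel_names = list(kept[0].samples.keys())

    fs0 = chunks[0].fs
    step0 = 1000.0 / fs0
    anchor0 = adjusted_anchor(chunks[0], kept)
    chunks[0].anchor_time = anchor0
    chunks[0].gap_class = "first"
    times0 = derive_times_for_chunk(chunks[0], anchor0, fs0, kept)
    t_ref = float(times0[0])

    all_times: list[np.ndarray] = [t_ref + np.arange(chunks[0].n_samples) * step0]
    grid_idx: list[np.ndarray] = [np.arange(chunks[0].n_samples, dtype=np.int64)]
    prov: list[np.ndarray] = [np.zeros(chunks[0].n_samples, dtype=np.int64)]
    prev_last_time = float(all_times[0][-1])
    prev_last_k = int(grid_idx[0][-1])
    prev_last_tick = kept[chunks[0].stop - 1].system_tick

    for ci in range(1, len(chunks)):
        ch = chunks[ci]
        step = 1000.0 / ch.fs
        ch.gap_class = classify_gap(chunks[ci - 1], ch, kept, constants)
        if method == "gap" and ch.gap_class == "short":
            # tick-bridged chunks are NOT snapped to the grid: the bridge
            # itself sets the time base, and its rate error accumulates —
            # exactly the documented caveat of this method
            times = derive_times_gap_method(
                prev_last_time, prev_last_tick, ch, kept, ch.gap_class, constants
            )
            if times[0] <= prev_last_time:
                shift = prev_last_time + step - times[0]
                times = times + shift
                warnings.append(
                    f"chunk {ci}: tick-bridged anchor collided; shifted {shift:.3f} ms"
                )
            ch.anchor_time = float(times[kept[ch.start].n_samples - 1])
        else:
            anchor = adjusted_anchor(ch, kept)
            times = derive_times_for_chunk(ch, anchor, ch.fs, kept)
            times = snap_to_grid(times, t_ref, ch.fs)
            k0 = _grid_round((times[0] - t_ref) / step)
            if ch.fs == fs0 and k0 <= prev_last_k:
                shift = prev_last_k + 1 - k0
                times = times + shift * step
                warnings.append(
                    f"chunk {ci}: anchor collided with previous chunk; shifted "
                    f"{shift} grid step(s) forward"
                )
            elif times[0] <= prev_last_time:
                times = times + (prev_last_time + step - times[0])
                warnings.append(f"chunk {ci}: anchor pushed after previous chunk end")
            ch.anchor_time = float(times[kept[ch.start].n_samples - 1])
        idx = _grid_round((times[0] - t_ref) / step0) + np.round(
            np.arange(ch.n_samples) * (step / step0)
        ).astype(np.int64)
        all_times.append(times)
        grid_idx.append(idx)
        prov.append(np.full(ch.n_samples, ci, dtype=np.int64))
        prev_last_time = float(times[-1])
        prev_last_k = int(idx[-1])
        prev_last_tick = kept[ch.stop - 1].system_tick

    all_idx = np.concatenate(grid_idx)
    provenance = np.concatenate(prov)
    derived = np.concatenate(all_times)

    samples: dict[str, np.ndarray] = {}
    for name in channel_names:
        samples[name] = np.concatenate([p.samples[name] for p in kept])

    return DerivedTimeSeries(
        derived_time=derived,
        samples=samples,
        fs=fs0,
        t_ref=t_ref,
        grid_index=all_idx,
        provenance=provenance,
        chunks=chunks,
        rejection_log=rejection_log,
        warnings=warnings,
    )
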