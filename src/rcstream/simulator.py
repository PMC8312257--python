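"""Synthetic RC+S-style session generator with ground truth.

Real sessions from the implanted neurostimulator arrive as 11 JSON files
of packetized telemetry with unreliable timing metadata: a 16-bit
hardware tick counter (1e-4 s units, rolling over every ~6.5535 s), a
1-second-resolution firmware timestamp, a jittery API-side packet
generation time, and a mod-256 packet sequence counter.  Packets are
dropped and reordered by the UDP transport.  This module generates
sessions in a documented JSON dialect that reproduces exactly those
pathologies under configurable control, while retaining the true unix
time of every emitted sample — the ground truth against which the time
reconstruction and harmonization stages are validated.

The simulator also runs the device band-power engine stream-side (the
same arithmetic as :mod:`rcstream.power`) to produce a RawDataPower
stream, giving the off-device power recomputation an on-device reference
to be compared against.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import power as pw
from .errors import ConfigurationError, EmptyStreamError

__all__ = [
    "SimulationConfig",
    "SignalSpec",
    "SimPacket",
    "GroundTruth",
    "simulate_session",
    "schedule_packets",
    "apply_transport_impairments",
    "emulate_fft_power_stream",
    "write_session",
    "SESSION_FILES",
    "DIALECT_VERSION",
    "TIMESTAMP_EPOCH_UNIX_S",
    "SAMPLE_RATE_CODES",
]

DIALECT_VERSION = "1.0"

#: The 11 per-session files of the documented dialect.
SESSION_FILES = (
    "RawDataTD.json",
    "RawDataAccel.json",
    "RawDataPower.json",
    "RawDataFFT.json",
    "AdaptiveLog.json",
    "DeviceSettings.json",
    "StimLog.json",
    "TimeSync.json",
    "EventLog.json",
    "ErrorLog.json",
    "DiagnosticsLog.json",
)

#: Unix seconds of 2000-03-01T00:00:00Z, the epoch of the firmware timestamp.
TIMESTAMP_EPOCH_UNIX_S = 951_868_800

#: Codebook for the coded time-domain sample rate (dialect-defined).
SAMPLE_RATE_CODES = {0: 250, 1: 500, 2: 1000, 240: None}
_HZ_TO_CODE = {250: 0, 500: 1, 1000: 2}

_VALID_ACCEL_FS = (4, 8, 16, 32, 64)
TICKS_PER_SECOND = 10_000
TICK_MODULUS = 1 << 16
SEQ_MODULUS = 256


@dataclass(frozen=True)
class SignalSpec:
    """One additive component of a simulated channel.

    kind:
      ``sine``            continuous sinusoid (amplitude in mV)
      ``am_sine``         sinusoid with slow sinusoidal amplitude
                          modulation at ``mod_frequency`` Hz
      ``burst_sine``      sinusoid gated on for ``burst_on`` s, off for
                          ``burst_off`` s, repeating
      ``one_over_f_noise`` pink noise, amplitude = RMS in mV
      ``accel_motion``    band-limited random walk emulating wearer
                          movement (amplitude in g)
    """

    kind: str
    amplitude: float
    frequency: float = 0.0
    burst_on: float = 5.0
    burst_off: float = 5.0
    mod_frequency: float = 0.1
    channel: int = 0

    def __post_init__(self):
        if self.kind not in ("sine", "am_sine", "burst_sine", "one_over_f_noise", "accel_motion"):
            raise ConfigurationError(f"unknown signal kind {self.kind!r}")
        if self.amplitude < 0:
            raise ConfigurationError(f"amplitude must be >= 0, got {self.amplitude}")


def _default_td_signals() -> list[SignalSpec]:
    return [
        SignalSpec("one_over_f_noise", amplitude=0.02, channel=0),
        SignalSpec("sine", amplitude=0.01, frequency=10.0, channel=0),
        SignalSpec("one_over_f_noise", amplitude=0.02, channel=1),
    ]


def _default_accel_signals() -> list[SignalSpec]:
    return [SignalSpec("accel_motion", amplitude=0.3, channel=0)]


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated session.

    Transport defaults emulate a session with moderate telemetry trouble:
    5% packet loss, occasional adjacent reordering, 50 ms SD jitter on the
    API packet-generation time, and a 50 ppm rate error of the hardware
    tick counter relative to true time (empirical recordings show the
    tick clock and the firmware 1 s timestamp drifting apart by seconds
    over hours).
    """

    duration: float = 60.0
    td_fs: int = 250
    td_channels: int = 2
    accel_fs: int = 64
    packet_size_range: tuple[int, int] = (30, 120)
    drop_probability: float = 0.05
    reorder_probability: float = 0.01
    pgt_jitter_sd: float = 50.0
    systemtick_drift_ppm: float = 50.0
    session_start: int = 1_589_544_000_000  # unix ms
    utc_offset: int = -420  # minutes
    seed: int = 0
    signal_seed: int | None = None  # share signals across devices; default = seed
    signal_specs: tuple[SignalSpec, ...] | None = None
    accel_specs: tuple[SignalSpec, ...] | None = None
    fft_config: pw.FFTConfig | None = None
    power_bands: tuple[pw.PowerBand, ...] = (pw.PowerBand(8.05, 12.20),)
    stream_enable_flags: dict | None = None
    gain_code: int = 250
    quantize_power: bool = True
    events: tuple[tuple[float, str, str], ...] = (
        (5.0, "task", "task start"),
        (30.0, "symptom", "tremor reported"),
    )
    stim_change_at: float | None = 0.5  # fraction of session; None = no change
    initial_seq: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigurationError(f"duration must be positive, got {self.duration}")
        if self.td_fs not in (250, 500, 1000):
            raise ConfigurationError(f"td_fs must be 250, 500 or 1000, got {self.td_fs}")
        if not (1 <= self.td_channels <= 4):
            raise ConfigurationError(f"td_channels must be 1-4, got {self.td_channels}")
        if self.td_fs == 1000 and self.td_channels > 2:
            raise ConfigurationError(
                f"at most two channels at 1000 Hz, got td_channels={self.td_channels}"
            )
        if self.accel_fs not in _VALID_ACCEL_FS:
            raise ConfigurationError(
                f"accel_fs must be one of {_VALID_ACCEL_FS}, got {self.accel_fs}"
            )
        lo, hi = self.packet_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(
                f"packet_size_range must satisfy 1 <= min <= max, got {self.packet_size_range}"
            )
        for name in ("drop_probability", "reorder_probability"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.pgt_jitter_sd < 0:
            raise ConfigurationError(f"pgt_jitter_sd must be >= 0, got {self.pgt_jitter_sd}")
        if len(self.power_bands) > 8:
            raise ConfigurationError(
                f"at most eight power bands may be streamed, got {len(self.power_bands)}"
            )
        for band in self.power_bands:
            if band.f_hi > self.td_fs / 2:
                raise ConfigurationError(
                    f"power band [{band.f_lo}, {band.f_hi}] exceeds Nyquist {self.td_fs / 2} Hz"
                )
        for spec in self.signal_specs or ():
            if spec.frequency >= self.td_fs / 2:
                raise ConfigurationError(
                    f"signal frequency {spec.frequency} Hz >= Nyquist {self.td_fs / 2} Hz"
                )

    def resolved_fft_config(self) -> pw.FFTConfig:
        if self.fft_config is not None:
            return replace(self.fft_config, fs=float(self.td_fs))
        return pw.FFTConfig(fft_size=256, interval=0.1, window_load=100, fs=float(self.td_fs))

    def resolved_streams(self) -> dict[str, bool]:
        flags = {name: True for name in SESSION_FILES}
        if self.stream_enable_flags:
            for key, val in self.stream_enable_flags.items():
                fname = key if key.endswith(".json") else key + ".json"
                if fname not in flags:
                    raise ConfigurationError(f"unknown stream {key!r} in stream_enable_flags")
                flags[fname] = bool(val)
        return flags


@dataclass
class SimPacket:
    """One scheduled packet before/after transport impairment."""

    index: int  # creation order
    start: int  # first sample index in the stream
    n_samples: int
    true_last_time: float  # unix ms of the packet's last sample
    system_tick: int
    timestamp: int
    data_type_sequence: int
    packet_gen_time: int | None = None  # unix ms, set at transport
    packet_rx_unix_time: int | None = None
    dropped: bool = False
    reordered: bool = False

    @property
    def stop(self) -> int:
        return self.start + self.n_samples


@dataclass
class GroundTruth:
    """Simulator-held truth: never available from a real device.

    ``sample_times`` maps stream name to the true unix ms of *every*
    generated sample (dropped ones included); ``signals`` holds the clean
    per-channel data; ``packet_log`` records each packet's true creation
    time and its drop/reorder fate.
    """

    sample_times: dict[str, np.ndarray] = field(default_factory=dict)
    signals: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    packet_log: dict[str, list[dict]] = field(default_factory=dict)
    power_unquantized: dict[str, np.ndarray] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "note": "SYNTHETIC ground truth written by the rcstream simulator; not device data",
            "sample_times": {k: v.tolist() for k, v in self.sample_times.items()},
            "signals": {
                s: {c: v.tolist() for c, v in chans.items()}
                for s, chans in self.signals.items()
            },
            "packet_log": self.packet_log,
            "power_unquantized": {k: v.tolist() for k, v in self.power_unquantized.items()},
        }


# ---------------------------------------------------------------------------
# signal synthesis


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    shaped = np.fft.irfft(spec * scale, n=n)
    rms = shaped.std()
    return shaped / rms if rms > 0 else shaped


def _render_signal(spec: SignalSpec, t_s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "sine":
        return spec.amplitude * np.sin(2 * np.pi * spec.frequency * t_s)
    if spec.kind == "am_sine":
        envelope = 0.5 * (1.0 + np.sin(2 * np.pi * spec.mod_frequency * t_s))
        return spec.amplitude * envelope * np.sin(2 * np.pi * spec.frequency * t_s)
    if spec.kind == "burst_sine":
        period = spec.burst_on + spec.burst_off
        gate = (np.mod(t_s - t_s[0], period) < spec.burst_on).astype(float)
        return spec.amplitude * gate * np.sin(2 * np.pi * spec.frequency * t_s)
    if spec.kind == "one_over_f_noise":
        return spec.amplitude * _pink_noise(t_s.size, rng)
    if spec.kind == "accel_motion":
        # slow postural drift (smoothed random walk) plus broadband
        # movement transients, so the signal has both the low-frequency
        # bulk and the sharp autocorrelation of real actigraphy
        steps = rng.standard_normal(t_s.size)
        walk = np.cumsum(steps)
        kernel = np.ones(16) / 16.0
        smooth = np.convolve(walk, kernel, mode="same")
        smooth -= smooth.mean()
        rms = smooth.std()
        slow = smooth / rms if rms > 0 else smooth
        fast = np.convolve(rng.standard_normal(t_s.size), np.ones(2) / 2.0, mode="same")
        return spec.amplitude * (0.8 * slow + 0.35 * fast)
    raise ConfigurationError(f"unknown signal kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# packet scheduling and transport


def schedule_packets(
    sample_times: np.ndarray,
    packet_size_range: tuple[int, int],
    seed: int | np.random.Generator,
    *,
    t0: float | None = None,
    drift_ppm: float = 0.0,
    initial_seq: int = 0,
) -> list[SimPacket]:
    """Partition a uniformly sampled stream into variable-size packets.

    Every sample belongs to exactly one packet.  All timing metadata is
    derived from the true time of the packet's *last* sample (the device
    reports timing only for the last sample in each packet):

    - ``system_tick`` = floor(elapsed_s * 1e4 * (1 + drift)) mod 2^16,
      elapsed measured from ``t0`` (default: first sample time);
    - ``timestamp`` = floor(unix seconds - epoch(2000-03-01));
    - ``data_type_sequence`` increments by one per packet, mod 256.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.size == 0:
        raise EmptyStreamError("cannot packetize an empty stream")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = packet_size_range
    if t0 is None:
        t0 = float(sample_times[0])
    drift = drift_ppm * 1e-6

    packets: list[SimPacket] = []
    pos = 0
    idx = 0
    n = sample_times.size
    while pos < n:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, n - pos)
        t_last = float(sample_times[pos + size - 1])
        elapsed_s = (t_last - t0) / 1000.0
        tick = int(math.floor(elapsed_s * TICKS_PER_SECOND * (1.0 + drift))) % TICK_MODULUS
        ts = int(math.floor(t_last / 1000.0)) - TIMESTAMP_EPOCH_UNIX_S
        packets.append(
            SimPacket(
                index=idx,
                start=pos,
                n_samples=size,
                true_last_time=t_last,
                system_tick=tick,
                timestamp=ts,
                data_type_sequence=(initial_seq + idx) % SEQ_MODULUS,
            )
        )
        pos += size
        idx += 1
    return packets


def apply_transport_impairments(
    packets: list[SimPacket],
    drop_probability: float,
    reorder_probability: float,
    pgt_jitter_sd: float,
    seed: int | np.random.Generator,
) -> tuple[list[SimPacket], list[dict]]:
    """Drop, locally reorder and time-jitter packets.

    Packets must arrive in creation order.  Each packet is dropped
    independently with ``drop_probability``; surviving adjacent pairs are
    swapped with ``reorder_probability``; PacketGenTime is the true
    creation time plus Gaussian(0, ``pgt_jitter_sd`` ms) rounded to the
    API's millisecond resolution, and PacketRxUnixTime adds a
    non-negative transmission delay on top of the true time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log: list[dict] = []
    survivors: list[SimPacket] = []
    for p in packets:
        jitter = rng.normal(0.0, pgt_jitter_sd) if pgt_jitter_sd > 0 else 0.0
        delay = 50.0 + rng.exponential(20.0)
        p.packet_gen_time = int(round(p.true_last_time + jitter))
        p.packet_rx_unix_time = int(round(p.true_last_time + delay))
        if drop_probability > 0 and rng.random() < drop_probability:
            p.dropped = True
            log.append({"event": "drop", "index": p.index})
        else:
            survivors.append(p)
    i = 0
    while i < len(survivors) - 1:
        if reorder_probability > 0 and rng.random() < reorder_probability:
            survivors[i], survivors[i + 1] = survivors[i + 1], survivors[i]
            survivors[i].reordered = survivors[i + 1].reordered = True
            log.append(
                {"event": "swap", "indices": [survivors[i + 1].index, survivors[i].index]}
            )
            i += 2  # swaps are local and non-overlapping
        else:
            i += 1
    return survivors, log


# ---------------------------------------------------------------------------
# on-device computation emulation


def emulate_fft_power_stream(
    td_signal_mv: np.ndarray,
    times_ms: np.ndarray,
    cfg: pw.FFTConfig,
    bands: tuple[pw.PowerBand, ...],
    cal: pw.AmplifierCalibration,
    quantize: bool = True,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Run the device band-power engine stream-side.

    Identical arithmetic to :func:`rcstream.power.calculate_new_power`,
    applied windows-forward over the clean signal; one power sample per
    FFT interval per band, stamped at the window's last sample.  Returns
    ``(window_times, quantized_or_raw, unquantized)`` keyed by band label.
    """
    t = None
    raw: dict[str, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for band in bands:
        series = pw.calculate_new_power(
            td_signal_mv, cfg, band, cal, times=times_ms, quantize=False
        )
        t = series.time
        raw[band.label] = series.power
        out[band.label] = np.rint(series.power) if quantize else series.power
    if t is None:
        raise ConfigurationError("at least one power band is required")
    return t, out, raw


# ---------------------------------------------------------------------------
# session assembly


def _packets_to_json(
    packets: list[SimPacket],
    channels: dict[str, np.ndarray],
    sample_rate_field,
) -> list[dict]:
    docs = []
    for p in packets:
        if p.dropped:
            continue
        rec = {
            "SystemTick": p.system_tick,
            "Timestamp": p.timestamp,
            "PacketGenTime": p.packet_gen_time,
            "PacketRxUnixTime": p.packet_rx_unix_time,
            "DataTypeSequence": p.data_type_sequence,
            "ChannelSamples": {
                name: [float(v) for v in data[p.start : p.stop]]
                for name, data in channels.items()
            },
        }
        rec.update(sample_rate_field)
        docs.append(rec)
    return docs


def simulate_session(config: SimulationConfig) -> tuple[dict[str, object], GroundTruth]:
    """Generate a full session: JSON documents per file, plus ground truth.

    Streams are generated, packetized and impaired independently, as on
    the real transport.  The returned ``contents`` maps each of the 11
    dialect file names to its (JSON-serialisable) document; ``truth``
    records every generated sample's true unix time, the clean signals,
    and the packet drop/reorder log.
    """
    flags = config.resolved_streams()
    seed_root = np.random.SeedSequence(config.seed)
    transport_seeds = seed_root.spawn(4)
    signal_root = np.random.SeedSequence(
        config.seed if config.signal_seed is None else config.signal_seed
    )
    sig_seeds = signal_root.spawn(2)

    truth = GroundTruth()
    contents: dict[str, object] = {}
    fftcfg = config.resolved_fft_config()
    cal = pw.AmplifierCalibration(gain_code=config.gain_code)
    start = float(config.session_start)

    def header(stream: str) -> dict:
        return {"DialectVersion": DIALECT_VERSION, "Stream": stream}

    # --- time-domain stream -------------------------------------------------
    n_td = int(round(config.duration * config.td_fs))
    td_times = start + np.arange(n_td) * (1000.0 / config.td_fs)
    td_rel_s = (td_times - start) / 1000.0
    sig_rng = np.random.default_rng(sig_seeds[0])
    specs = (
        tuple(config.signal_specs) if config.signal_specs is not None else tuple(_default_td_signals())
    )
    td_channels: dict[str, np.ndarray] = {}
    for ch in range(config.td_channels):
        s = np.zeros(n_td)
        for spec in specs:
            if spec.channel == ch:
                s = s + _render_signal(spec, td_rel_s, sig_rng)
        td_channels[str(ch)] = s
    truth.sample_times["RawDataTD"] = td_times
    truth.signals["RawDataTD"] = dict(td_channels)

    td_packets = schedule_packets(
        td_times,
        config.packet_size_range,
        np.random.default_rng(transport_seeds[0]),
        t0=start,
        drift_ppm=config.systemtick_drift_ppm,
        initial_seq=config.initial_seq,
    )
    td_survivors, td_log = apply_transport_impairments(
        td_packets,
        config.drop_probability,
        config.reorder_probability,
        config.pgt_jitter_sd,
        np.random.default_rng(transport_seeds[0].spawn(1)[0]),
    )
    truth.packet_log["RawDataTD"] = [
        {
            "index": p.index,
            "start": p.start,
            "n_samples": p.n_samples,
            "true_last_time": p.true_last_time,
            "dropped": p.dropped,
            "reordered": p.reordered,
        }
        for p in td_packets
    ]
    if flags["RawDataTD.json"]:
        contents["RawDataTD.json"] = {
            **header("RawDataTD"),
            "Packets": _packets_to_json(
                td_survivors, td_channels, {"SampleRate": _HZ_TO_CODE[config.td_fs]}
            ),
        }
    else:
        contents["RawDataTD.json"] = {**header("RawDataTD"), "Packets": []}

    # --- accelerometry ------------------------------------------------------
    n_ac = int(round(config.duration * config.accel_fs))
    ac_times = start + np.arange(n_ac) * (1000.0 / config.accel_fs)
    ac_rel_s = (ac_times - start) / 1000.0
    ac_rng = np.random.default_rng(sig_seeds[1])
    ac_specs = (
        tuple(config.accel_specs) if config.accel_specs is not None else tuple(_default_accel_signals())
    )
    motion = np.zeros(n_ac)
    for spec in ac_specs:
        motion = motion + _render_signal(spec, ac_rel_s, ac_rng)
    ac_channels = {
        "X": motion,
        "Y": 0.3 * motion + 0.02 * ac_rng.standard_normal(n_ac),
        "Z": 1.0 + 0.02 * ac_rng.standard_normal(n_ac),
    }
    truth.sample_times["RawDataAccel"] = ac_times
    truth.signals["RawDataAccel"] = dict(ac_channels)

    ac_size_range = (
        max(1, config.packet_size_range[0] // 4),
        max(1, config.packet_size_range[1] // 4),
    )
    ac_packets = schedule_packets(
        ac_times,
        ac_size_range,
        np.random.default_rng(transport_seeds[1]),
        t0=start,
        drift_ppm=config.systemtick_drift_ppm,
        initial_seq=config.initial_seq,
    )
    ac_survivors, ac_log = apply_transport_impairments(
        ac_packets,
        config.drop_probability,
        config.reorder_probability,
        config.pgt_jitter_sd,
        np.random.default_rng(transport_seeds[1].spawn(1)[0]),
    )
    truth.packet_log["RawDataAccel"] = [
        {
            "index": p.index,
            "start": p.start,
            "n_samples": p.n_samples,
            "true_last_time": p.true_last_time,
            "dropped": p.dropped,
            "reordered": p.reordered,
        }
        for p in ac_packets
    ]
    if flags["RawDataAccel.json"]:
        contents["RawDataAccel.json"] = {
            **header("RawDataAccel"),
            "Packets": _packets_to_json(
                ac_survivors, ac_channels, {"SampleRateHz": config.accel_fs}
            ),
        }
    else:
        contents["RawDataAccel.json"] = {**header("RawDataAccel"), "Packets": []}

    # --- on-device power stream --------------------------------------------
    pwr_doc: dict[str, object] = {**header("RawDataPower"), "Packets": []}
    if flags["RawDataPower.json"] and n_td >= fftcfg.fft_size_actual:
        pt, pq, praw = emulate_fft_power_stream(
            td_channels[str(config.power_bands[0].channel)]
            if str(config.power_bands[0].channel) in td_channels
            else td_channels["0"],
            td_times,
            fftcfg,
            config.power_bands,
            cal,
            quantize=config.quantize_power,
        )
        band_labels = [b.label for b in config.power_bands]
        pw_channels = {f"Band{i}": pq[lab] for i, lab in enumerate(band_labels)}
        truth.sample_times["RawDataPower"] = pt
        truth.signals["RawDataPower"] = dict(pw_channels)
        for i, lab in enumerate(band_labels):
            truth.power_unquantized[f"Band{i}"] = praw[lab]
        pw_fs = 1.0 / fftcfg.interval
        pw_size_range = (1, max(1, min(30, len(pt))))
        pw_packets = schedule_packets(
            pt,
            pw_size_range,
            np.random.default_rng(transport_seeds[2]),
            t0=start,
            drift_ppm=config.systemtick_drift_ppm,
            initial_seq=config.initial_seq,
        )
        pw_survivors, _ = apply_transport_impairments(
            pw_packets,
            config.drop_probability,
            config.reorder_probability,
            config.pgt_jitter_sd,
            np.random.default_rng(transport_seeds[2].spawn(1)[0]),
        )
        truth.packet_log["RawDataPower"] = [
            {
                "index": p.index,
                "start": p.start,
                "n_samples": p.n_samples,
                "true_last_time": p.true_last_time,
                "dropped": p.dropped,
                "reordered": p.reordered,
            }
            for p in pw_packets
        ]
        pwr_doc = {
            **header("RawDataPower"),
            "Packets": _packets_to_json(
                pw_survivors, pw_channels, {"SampleRateHz": pw_fs}
            ),
            "Bands": [
                {"Lo": b.f_lo, "Hi": b.f_hi, "GainG": b.gain, "Channel": b.channel}
                for b in config.power_bands
            ],
        }
    contents["RawDataPower.json"] = pwr_doc

    # --- FFT amplitude frames (decimated record stream) ----------------------
    fft_doc: dict[str, object] = {**header("RawDataFFT"), "Records": []}
    if flags["RawDataFFT.json"] and n_td >= fftcfg.fft_size_actual:
        rcs = pw.mv_to_device_units(td_channels["0"], cal)
        wt, amp = pw.short_time_fft_amplitude(rcs, fftcfg, times=td_times)
        stride = max(1, int(round(1.0 / fftcfg.interval)))  # about one frame per second
        fft_doc["Records"] = [
            {"Time": float(wt[i]), "Amplitude": [float(v) for v in amp[i]]}
            for i in range(0, len(wt), stride)
        ]
    contents["RawDataFFT.json"] = fft_doc

    # --- adaptive log --------------------------------------------------------
    ad_doc: dict[str, object] = {**header("AdaptiveLog"), "Records": []}
    if flags["AdaptiveLog.json"] and "RawDataPower" in truth.sample_times:
        pt = truth.sample_times["RawDataPower"]
        p0 = truth.signals["RawDataPower"]["Band0"]
        thresh = float(np.median(p0))
        stride = max(1, int(round(0.5 / fftcfg.interval)))  # ~2 Hz state updates
        recs = []
        for i in range(0, len(pt), stride):
            state = int(p0[i] > thresh)
            recs.append(
                {
                    "Time": float(pt[i]),
                    "State": state,
                    "Output": float(p0[i]),
                    "CurrentMa": 2.0 if state else 1.0,
                }
            )
        ad_doc["Records"] = recs
        ad_doc["Threshold"] = thresh
    contents["AdaptiveLog.json"] = ad_doc

    # --- settings, stim, sync, events, errors, diagnostics -------------------
    td_settings = {
        str(ch): {
            "SampleRate": _HZ_TO_CODE[config.td_fs],
            "GainCode": config.gain_code,
            "Hpf": 0.85,
            "Lpf": 100.0,
            "Contacts": f"+{2 * ch + 1}-{2 * ch}",
        }
        for ch in range(config.td_channels)
    }
    contents["DeviceSettings.json"] = {
        **header("DeviceSettings"),
        "Records": [
            {
                "Time": config.session_start,
                "TDSettings": td_settings,
                "FFTConfig": {
                    "Size": fftcfg.fft_size,
                    "IntervalMs": fftcfg.interval * 1000.0,
                    "WindowLoad": fftcfg.window_load,
                },
                "PowerBands": [
                    {"Lo": b.f_lo, "Hi": b.f_hi, "GainG": b.gain, "Channel": b.channel}
                    for b in config.power_bands
                ],
                "Adaptive": {"Enabled": flags["AdaptiveLog.json"], "Detector": "LD0"},
                "Metadata": {
                    "UtcOffsetMinutes": config.utc_offset,
                    "DeviceId": "SIM-RCS-001",
                    "SessionId": f"sim-{config.seed}",
                },
            }
        ],
    }

    stim_records = [
        {
            "Time": config.session_start,
            "Group": "A",
            "Contacts": "+1-2",
            "AmplitudeMa": 1.0,
            "PulseWidthUs": 60,
            "RateHz": 130.0,
        }
    ]
    if config.stim_change_at is not None:
        stim_records.append(
            {
                "Time": int(config.session_start + config.stim_change_at * config.duration * 1000),
                "Group": "A",
                "Contacts": "+1-2",
                "AmplitudeMa": 2.0,
                "PulseWidthUs": 60,
                "RateHz": 130.0,
            }
        )
    contents["StimLog.json"] = {**header("StimLog"), "Records": stim_records}

    contents["TimeSync.json"] = {
        **header("TimeSync"),
        "Records": [
            {
                "Time": config.session_start,
                "TimestampEpochUnixSeconds": TIMESTAMP_EPOCH_UNIX_S,
                "UtcOffsetMinutes": config.utc_offset,
            }
        ],
    }
    contents["EventLog.json"] = {
        **header("EventLog"),
        "Records": [
            {
                "Time": int(config.session_start + off * 1000),
                "EventType": etype,
                "Payload": payload,
            }
            for off, etype, payload in config.events
        ],
    }
    contents["ErrorLog.json"] = {**header("ErrorLog"), "Records": []}
    contents["DiagnosticsLog.json"] = {
        **header("DiagnosticsLog"),
        "Records": [
            {"Time": config.session_start, "BatteryPct": 87, "TelemetryQuality": "ok"}
        ],
    }

    for fname in SESSION_FILES:
        if not flags[fname]:
            doc = contents.get(fname, {})
            key = "Packets" if "Packets" in doc else "Records"
            stream = fname[: -len(".json")]
            contents[fname] = {**header(stream), key: []}
    return contents, truth


def _dumps(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def write_session(
    folder_path: str | Path,
    contents: dict[str, object],
    truth: GroundTruth | None = None,
    malform: bool = False,
    malform_files: tuple[str, ...] = ("RawDataTD.json",),
) -> Path:
    """Write the 11 dialect files (plus ground-truth sidecar) to disk.

    With ``malform=True`` the final closing brackets of the selected
    files are omitted, emulating the truncation seen in real recordings,
    so the ingestion repair path can be exercised.
    """
    folder = Path(folder_path)
    folder.mkdir(parents=True, exist_ok=True)
    for fname in SESSION_FILES:
        text = _dumps(contents[fname])
        if malform and fname in malform_files:
            text = text.rstrip()
            n_cut = 0
            while n_cut < 2 and text and text[-1] in "]}":
                text = text[:-1]
                n_cut += 1
        (folder / fname).write_text(text)
    if truth is not None:
        (folder / "_groundtruth.json").write_text(_dumps(truth.to_jsonable()))
    return folder
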