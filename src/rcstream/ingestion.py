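"""Session-folder loading: JSON repair, packet parsing, settings decoding.

A session is a folder of 11 JSON files in the rcstream dialect (see
``dialect_schema.json``).  Files are read independently: a missing,
empty or unparseable file removes only its own stream from processing,
never the whole session.  Truncated files — real recordings are
"typically" cut off with closing brackets omitted — are repaired by
appending the minimal balancing suffix before parsing.

Packets are returned in file order, i.e. received order; out-of-order
arrival is corrected later by the time-reconstruction logic, not here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DecodeError, EmptySessionError, JSONRepairError, ConfigurationError
from .power import FFTConfig, PowerBand
from .simulator import SAMPLE_RATE_CODES, SESSION_FILES

logger = logging.getLogger(__name__)

__all__ = [
    "Packet",
    "SessionSettings",
    "EventRecord",
    "SessionData",
    "load_session",
    "repair_malformed_json",
    "decode_sample_rate",
    "decode_td_settings",
    "decode_contacts",
    "extract_events",
]

#: Streams whose files hold a "Packets" list (the others hold "Records").
PACKETIZED_STREAMS = ("RawDataTD", "RawDataAccel", "RawDataPower")


@dataclass
class Packet:
    """One received telemetry packet with its five timing/count variables."""

    system_tick: int
    timestamp: int
    packet_gen_time: int
    packet_rx_unix_time: int
    data_type_sequence: int
    sample_rate: float | None  # Hz, decoded; None if the channel is disabled
    samples: dict[str, np.ndarray]

    def __post_init__(self):
        lengths = {len(v) for v in self.samples.values()}
        if len(lengths) != 1 or min(lengths) < 1:
            raise ConfigurationError(
                f"packet sample vectors must share one length >= 1, got {sorted(lengths)}"
            )
        if not (0 <= self.system_tick < (1 << 16)):
            raise ConfigurationError(f"systemTick out of range: {self.system_tick}")
        if not (0 <= self.data_type_sequence < 256):
            raise ConfigurationError(
                f"dataTypeSequence out of range: {self.data_type_sequence}"
            )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.samples.values())))


@dataclass
class EventRecord:
    time: float  # unix ms
    type: str
    payload: str


@dataclass
class SessionSettings:
    """Decoded device settings for one session."""

    td_settings: list[dict] = field(default_factory=list)  # timeline of decoded records
    stim_settings: pd.DataFrame = field(default_factory=pd.DataFrame)
    fft_config: FFTConfig | None = None
    power_bands: list[PowerBand] = field(default_factory=list)
    adaptive_config: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


@dataclass
class SessionData:
    """Everything load_session recovers from one folder."""

    streams: dict[str, list[Packet]]
    records: dict[str, list[dict]]
    settings: SessionSettings
    events: list[EventRecord]
    load_report: pd.DataFrame


def repair_malformed_json(text: str) -> str:
    """Balance prefix-valid JSON by appending the minimal closing suffix.

    Scans the document tracking open brackets/braces and string state.
    Valid text is returned unchanged.  Text whose existing delimiters
    mismatch (e.g. ``[{"a":[1,2}``) cannot be balanced by appending and
    raises :class:`JSONRepairError` with the byte offset of the offender.
    """
    stack: list[str] = []
    in_string = False
    escape = False
    for i, ch in enumerate(text):
        if in_string:
            if escape:
                escape = False
            elif ch == "\\":
                escape = True
            elif ch == '"':
                in_string = False
            continue
        if ch == '"':
            in_string = True
        elif ch in "[{":
            stack.append(ch)
        elif ch in "]}":
            if not stack or {"]": "[", "}": "{"}[ch] != stack[-1]:
                raise JSONRepairError(
                    f"mismatched closing delimiter {ch!r} at byte {i}", offset=i
                )
            stack.pop()
    if in_string:
        raise JSONRepairError("document ends inside a string", offset=len(text))
    if not stack:
        json.loads(text)  # confirm; raises ValueError if the prefix itself is broken
        return text
    repaired = text.rstrip()
    # a truncated document may end just after a value or a comma
    if repaired.endswith(","):
        repaired = repaired[:-1]
    repaired += "".join("]" if ch == "[" else "}" for ch in reversed(stack))
    json.loads(repaired)
    return repaired


def decode_sample_rate(code: int) -> float | None:
    """Decode the coded TD sample rate to Hz (None = channel disabled)."""
    try:
        return SAMPLE_RATE_CODES[int(code)]
    except (KeyError, TypeError) as exc:
        raise DecodeError(f"unknown sample-rate code {code!r}") from exc


def decode_contacts(spec: str) -> dict:
    """Decode a "+2-0"-style contact pair to anode/cathode labels."""
    try:
        plus = spec.index("+")
        minus = spec.index("-", plus + 1)
        anode = int(spec[plus + 1 : minus])
        cathode = int(spec[minus + 1 :])
    except (ValueError, IndexError) as exc:
        raise DecodeError(f"cannot decode contact spec {spec!r}") from exc
    return {"anode": anode, "cathode": cathode, "label": spec}


def decode_td_settings(records: list[dict]) -> list[dict]:
    """Decode raw DeviceSettings records into a human-readable timeline.

    One output record per settings change, carrying the start time and,
    per channel: fs in Hz, the numeric gain code (preserved for the
    RCS-unit conversion), filter corner frequencies and decoded contact
    labels.
    """
    timeline = []
    for rec in records:
        chans = {}
        for ch, raw in rec.get("TDSettings", {}).items():
            if "GainCode" not in raw:
                raise DecodeError(f"channel {ch}: missing gain code in settings")
            chans[ch] = {
                "fs": decode_sample_rate(raw["SampleRate"]),
                "gain_code": int(raw["GainCode"]),
                "hpf": float(raw.get("Hpf", float("nan"))),
                "lpf": float(raw.get("Lpf", float("nan"))),
                "contacts": decode_contacts(raw["Contacts"]) if "Contacts" in raw else None,
            }
        timeline.append({"time": float(rec["Time"]), "channels": chans})
    timeline.sort(key=lambda r: r["time"])
    return timeline


def extract_events(records: list[dict]) -> list[EventRecord]:
    """Chronological event records; unparseable entries logged and skipped."""
    events = []
    for rec in records:
        try:
            events.append(
                EventRecord(
                    time=float(rec["Time"]),
                    type=str(rec.get("EventType", "")),
                    payload=str(rec.get("Payload", "")),
                )
            )
        except (KeyError, TypeError, ValueError):
            logger.warning("skipping unparseable event record: %r", rec)
    events.sort(key=lambda e: e.time)
    return events


def _parse_packets(doc: dict, stream: str) -> list[Packet]:
    packets = []
    for raw in doc.get("Packets", []):
        if "SampleRateHz" in raw:
            fs = float(raw["SampleRateHz"])
        elif "SampleRate" in raw:
            fs = decode_sample_rate(raw["SampleRate"])
        else:
            fs = None
        packets.append(
            Packet(
                system_tick=int(raw["SystemTick"]),
                timestamp=int(raw["Timestamp"]),
                packet_gen_time=int(raw["PacketGenTime"]),
                packet_rx_unix_time=int(raw["PacketRxUnixTime"]),
                data_type_sequence=int(raw["DataTypeSequence"]),
                sample_rate=fs,
                samples={
                    k: np.asarray(v, dtype=float)
                    for k, v in raw["ChannelSamples"].items()
                },
            )
        )
    return packets


def _read_json_file(path: Path) -> tuple[dict | None, str, str]:
    """Read one dialect file; returns (document, status, note)."""
    if not path.exists():
        return None, "missing", "file absent"
    text = path.read_text()
    if not text.strip():
        return None, "empty", "file empty"
    try:
        return json.loads(text), "ok", ""
    except ValueError:
        pass
    try:
        repaired = repair_malformed_json(text)
    except (JSONRepairError, ValueError) as exc:
        return None, "failed", f"unrepairable: {exc}"
    return json.loads(repaired), "repaired", "closing brackets restored"


def load_session(folder: str | Path) -> SessionData:
    """Load a session folder into packets, settings, events and a report.

    Each of the 11 files is read independently; missing, empty or
    unrepairable files are logged in the load report and their stream
    skipped.  Raises :class:`EmptySessionError` only when *no* stream
    was usable, and ``FileNotFoundError`` when the folder is absent.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"session folder not found: {folder}")

    streams: dict[str, list[Packet]] = {}
    records: dict[str, list[dict]] = {}
    report_rows = []
    docs: dict[str, dict] = {}
    for fname in SESSION_FILES:
        stream = fname[: -len(".json")]
        doc, status, note = _read_json_file(folder / fname)
        n_items = 0
        if doc is not None:
            docs[stream] = doc
            try:
                if stream in PACKETIZED_STREAMS:
                    streams[stream] = _parse_packets(doc, stream)
                    n_items = len(streams[stream])
                else:
                    records[stream] = list(doc.get("Records", []))
                    n_items = len(records[stream])
            except (KeyError, ValueError, ConfigurationError, DecodeError) as exc:
                status, note = "failed", f"parse error: {exc}"
                streams.pop(stream, None)
                records.pop(stream, None)
        report_rows.append(
            {"file": fname, "status": status, "n_items": n_items, "note": note}
        )
        if status != "ok":
            logger.warning("%s: %s (%s)", fname, status, note)

    if not any(streams.values()) and not any(records.values()):
        raise EmptySessionError(f"no usable stream in {folder}")

    settings = SessionSettings()
    dsrecs = records.get("DeviceSettings", [])
    if dsrecs:
        settings.td_settings = decode_td_settings(dsrecs)
        first = dsrecs[0]
        fc = first.get("FFTConfig")
        td_fs = None
        for rec in settings.td_settings:
            for ch in rec["channels"].values():
                if ch["fs"]:
                    td_fs = ch["fs"]
                    break
        if fc and td_fs:
            settings.fft_config = FFTConfig(
                fft_size=int(fc["Size"]),
                interval=float(fc["IntervalMs"]) / 1000.0,
                window_load=int(fc["WindowLoad"]),
                fs=float(td_fs),
            )
        settings.power_bands = [
            PowerBand(b["Lo"], b["Hi"], gain=b.get("GainG", 2.0), channel=b.get("Channel", 0))
            for b in first.get("PowerBands", [])
        ]
        settings.adaptive_config = dict(first.get("Adaptive", {}))
        settings.metadata = dict(first.get("Metadata", {}))
    stim = records.get("StimLog", [])
    if stim:
        settings.stim_settings = (
            pd.DataFrame(stim).rename(columns={"Time": "time"}).sort_values("time")
        ).reset_index(drop=True)

    events = extract_events(records.get("EventLog", []))
    report = pd.DataFrame(report_rows)
    return SessionData(
        streams=streams,
        records=records,
        settings=settings,
        events=events,
        load_report=report,
    )
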