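"""End-to-end session processing: load -> reconstruct -> harmonize."""

from __future__ import annotations

from pathlib import Path

from .harmonize import ProcessedSession
from .ingestion import load_session
from .timealign import ClockConstants, reconstruct_stream

__all__ = ["process_session"]

_STREAM_ATTRS = (
    ("RawDataTD", "td"),
    ("RawDataAccel", "accel"),
    ("RawDataPower", "power"),
)


def process_session(
    folder: str | Path,
    method: str = "default",
    constants: ClockConstants = ClockConstants(),
) -> ProcessedSession:
    """Load a session folder and reconstruct every packetized stream.

    ``method`` selects the short-gap handling of the time reconstruction
    ("default" anchors every chunk on its Adjusted PacketGenTime; "gap"
    bridges short gaps with the tick counter — advanced use, only when
    the tick clock is known accurate).
    """
    data = load_session(folder)
    session = ProcessedSession(
        settings=data.settings, events=data.events, load_report=data.load_report
    )
    for stream, attr in _STREAM_ATTRS:
        packets = data.streams.get(stream)
        if packets:
            setattr(session, attr, reconstruct_stream(packets, constants, method=method))
    session.fft_records = data.records.get("RawDataFFT", [])
    session.adaptive_records = data.records.get("AdaptiveLog", [])
    return session
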