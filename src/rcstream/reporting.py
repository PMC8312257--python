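"""Session-level analysis and visualization.

Gap reporting, gap-aware spectral analysis, event reporting,
multi-session concatenation and static multi-panel stream plots.  The
organising principle: missing telemetry is explicit, so every analysis
must either respect gaps (no spectral window may span one) or report
them.  Gaps are defined at each stream's native rate — on the combined
grid a 64 Hz accelerometer has structural NaNs between its samples that
are not missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    SessionOverlapError,
)
from .harmonize import ProcessedSession, create_combined_table
from .timealign import DerivedTimeSeries

__all__ = [
    "gap_report",
    "gap_aware_psd",
    "combine_sessions",
    "CombinedSessions",
    "plot_streams",
    "event_report",
]


def _stream_gaps(series: DerivedTimeSeries) -> list[tuple[float, float]]:
    """(gap_start_ms, duration_s) pairs from native-grid index jumps."""
    k = series.grid_index
    if k.size < 2:
        return []
    step = series.step_ms
    jumps = np.flatnonzero(np.diff(k) > 1)
    out = []
    for j in jumps:
        n_missing = int(k[j + 1] - k[j] - 1)
        start = series.t_ref + (k[j] + 1) * step
        out.append((start, n_missing * step / 1000.0))
    return out


def gap_report(session: ProcessedSession) -> pd.DataFrame:
    """Per-stream table of gaps: start time, duration, probable cause.

    A gap is a maximal run of missing samples at the stream's native
    rate.  Cause attribution is heuristic: a gap overlapping a rejected
    packet's PacketGenTime is "rejected", a gap of 6 s or more is
    "stream_stop", anything else is "dropped" (lost in transmission).
    """
    rows = []
    for name, series in session.streams().items():
        rej_times = []
        if len(series.rejection_log) and "packet_gen_time" in series.rejection_log:
            rej_times = [
                float(t)
                for t in series.rejection_log["packet_gen_time"]
                if np.isfinite(t) and t > 0
            ]
        for start, dur in _stream_gaps(series):
            if dur >= 6.0:
                cause = "stream_stop"
            elif any(start <= t <= start + dur * 1000.0 for t in rej_times):
                cause = "rejected"
            else:
                cause = "dropped"
            rows.append(
                {"stream": name, "gap_start": start, "duration_s": dur, "cause": cause}
            )
    df = pd.DataFrame(rows, columns=["stream", "gap_start", "duration_s", "cause"])
    return df.sort_values(["stream", "gap_start"]).reset_index(drop=True)


def _welch_window_count(n: int, nperseg: int, noverlap: int) -> int:
    if n < nperseg:
        return 0
    return 1 + (n - nperseg) // (nperseg - noverlap)


def gap_aware_psd(
    data,
    channel: str,
    window_s: float = 1.0,
    overlap_frac: float = 0.5,
    fs: float | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Welch PSD that never lets an analysis window span a gap.

    ``data`` is a combined table (DataFrame with DerivedTime) or a
    :class:`DerivedTimeSeries`.  The channel is split at gaps into
    continuous segments; segments shorter than the window are discarded;
    Welch periodograms from all windows of all segments are averaged
    with window-count weights.  On gap-free data this equals a plain
    Welch estimate with the same parameters.

    Returns ``(freqs, psd, n_windows_used)``.
    """
    if isinstance(data, pd.DataFrame):
        if channel not in data.columns:
            raise ConfigurationError(f"channel {channel!r} not in table")
        x = data[channel].to_numpy(dtype=float)
        t = data["DerivedTime"].to_numpy(dtype=float)
        if fs is None:
            fs = 1000.0 / float(np.median(np.diff(t)))
        valid = np.isfinite(x)
        segments = []
        if valid.any():
            padded = np.concatenate(([False], valid, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            segments = [x[a:b] for a, b in zip(edges[::2], edges[1::2])]
    elif isinstance(data, DerivedTimeSeries):
        if channel not in data.samples:
            raise ConfigurationError(f"channel {channel!r} not in stream")
        fs = data.fs
        x = data.samples[channel]
        k = data.grid_index
        bounds = np.flatnonzero(np.diff(k) > 1) + 1
        segments = np.split(x, bounds)
    else:
        raise ConfigurationError("data must be a combined table or a DerivedTimeSeries")

    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap_frac * nperseg))
    if noverlap >= nperseg:
        raise ConfigurationError("overlap_frac must leave a positive hop")

    acc = None
    freqs = None
    total_windows = 0
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        if seg.size < nperseg:
            continue
        nw = _welch_window_count(seg.size, nperseg, noverlap)
        f, p = sps.welch(seg, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
        freqs = f
        acc = p * nw if acc is None else acc + p * nw
        total_windows += nw
    if acc is None:
        raise InsufficientDataError(
            f"no continuous segment of at least {window_s} s in channel {channel!r}"
        )
    return freqs, acc / total_windows, total_windows


@dataclass
class CombinedSessions:
    """Several sessions concatenated on unix time.

    Sessions are kept per-segment: a shared grid exists only within a
    segment of constant time-domain rate; rate changes across sessions
    are flagged in ``fs_changes``.
    """

    sessions: list[ProcessedSession]
    fs_changes: list[int] = field(default_factory=list)  # indices where TD fs changes

    def to_table(self, include=("td", "accel", "power", "adaptive")) -> pd.DataFrame:
        parts = [create_combined_table(s, include=include) for s in self.sessions]
        out = pd.concat(parts, ignore_index=True)
        return out

    @property
    def events(self):
        return [e for s in self.sessions for e in s.events]


def combine_sessions(sessions: list[ProcessedSession]) -> CombinedSessions:
    """Concatenate sessions chronologically into one structure.

    Sessions are sorted by start time; overlapping spans are an error
    (one device cannot record two sessions at once); the span between
    sessions appears downstream as a long gap.  Settings/events are kept
    per session and merge chronologically in reports.
    """
    if not sessions:
        raise ConfigurationError("no sessions to combine")
    ordered = sorted(sessions, key=lambda s: s.time_span_ms()[0])
    for a, b in zip(ordered, ordered[1:]):
        if a.time_span_ms()[1] >= b.time_span_ms()[0]:
            raise SessionOverlapError(
                f"sessions overlap in time: {a.time_span_ms()} vs {b.time_span_ms()}"
            )
    fs_changes = []
    for i in range(1, len(ordered)):
        fa = ordered[i - 1].td.fs if ordered[i - 1].td is not None else None
        fb = ordered[i].td.fs if ordered[i].td is not None else None
        if fa != fb:
            fs_changes.append(i)
    return CombinedSessions(sessions=ordered, fs_changes=fs_changes)


def event_report(session: ProcessedSession) -> pd.DataFrame:
    """Chronological event table with unix and local time columns."""
    offset_min = session.settings.metadata.get("UtcOffsetMinutes", 0)
    try:
        span = session.time_span_ms()
    except ConfigurationError:
        span = None
    rows = []
    for e in sorted(session.events, key=lambda e: e.time):
        local = pd.to_datetime(e.time, unit="ms", utc=True) + pd.Timedelta(minutes=offset_min)
        rows.append(
            {
                "time_unix_ms": e.time,
                "local_time": local.tz_localize(None),
                "type": e.type,
                "payload": e.payload,
                "outside_data_span": (
                    bool(span and not (span[0] <= e.time <= span[1]))
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["time_unix_ms", "local_time", "type", "payload", "outside_data_span"],
    )


def _td_title(session: ProcessedSession, key: str) -> str:
    try:
        rec = session.settings.td_settings[0]["channels"]
        ch = key  # native keys are "0".."3"
        s = rec[ch]
        contacts = s["contacts"]["label"] if s.get("contacts") else "?"
        return f"TD ch{int(ch) + 1} {contacts} | fs {s['fs']:g} Hz | HPF {s['hpf']:g} Hz LPF {s['lpf']:g} Hz"
    except (KeyError, IndexError, TypeError):
        return f"TD ch{key}"


def plot_streams(
    session: ProcessedSession,
    panels: tuple[str, ...] = ("td", "accel", "power", "stim", "adaptive"),
    out: str | None = None,
    show_events: bool = True,
):
    """Static multi-panel figure of the requested streams.

    One panel per stream on a shared time axis; panel titles carry the
    decoded settings (sense contacts, filters, stim parameters); stim
    parameter changes are drawn as step lines; event markers overlay
    every panel.  Returns the matplotlib figure (also saved when ``out``
    is given).
    """
    available = {"td", "accel", "power", "stim", "adaptive"}
    unknown = set(panels) - available
    if unknown:
        raise ConfigurationError(f"unknown stream panel(s) {sorted(unknown)}")
    rows = []
    for p in panels:
        if p == "stim":
            if len(session.settings.stim_settings):
                rows.append(p)
        elif p == "adaptive":
            if session.adaptive_records:
                rows.append(p)
        elif getattr(session, p) is not None and len(getattr(session, p)):
            rows.append(p)
    if not rows:
        raise ConfigurationError("no requested stream has data")

    span = session.time_span_ms()
    fig, axes = plt.subplots(
        len(rows), 1, sharex=True, figsize=(10, 2.2 * len(rows)), squeeze=False
    )
    axes = axes[:, 0]
    for ax, name in zip(axes, rows):
        if name in ("td", "accel", "power"):
            series = getattr(session, name)
            t = (series.derived_time - span[0]) / 1000.0
            for key, vals in series.samples.items():
                ax.plot(t, vals, lw=0.6, label=key)
            if name == "td":
                ax.set_title(_td_title(session, next(iter(series.samples))), fontsize=9)
                ax.set_ylabel("mV")
            elif name == "accel":
                ax.set_title(f"Accelerometry | fs {series.fs:g} Hz", fontsize=9)
                ax.set_ylabel("g")
            else:
                bands = ", ".join(
                    f"{b.f_lo:g}-{b.f_hi:g} Hz" for b in session.settings.power_bands
                )
                ax.set_title(f"Band power ({bands}) | G sum", fontsize=9)
                ax.set_ylabel("RCS units")
            ax.legend(fontsize=7, loc="upper right")
        elif name == "stim":
            stim = session.settings.stim_settings
            t = (stim["time"].to_numpy(dtype=float) - span[0]) / 1000.0
            amp = stim["AmplitudeMa"].to_numpy(dtype=float)
            t_step = np.append(t, (span[1] - span[0]) / 1000.0)
            amp_step = np.append(amp, amp[-1])
            ax.step(t_step, amp_step, where="post")
            first = stim.iloc[0]
            ax.set_title(
                f"Stim {first.get('Contacts', '?')} | {first.get('RateHz', '?')} Hz, "
                f"{first.get('PulseWidthUs', '?')} us",
                fontsize=9,
            )
            ax.set_ylabel("mA")
        elif name == "adaptive":
            t = np.array([r["Time"] for r in session.adaptive_records], dtype=float)
            out_v = np.array([r["Output"] for r in session.adaptive_records], dtype=float)
            state = np.array([r["State"] for r in session.adaptive_records], dtype=float)
            ax.plot((t - span[0]) / 1000.0, out_v, lw=0.8, label="detector output")
            ax.plot((t - span[0]) / 1000.0, state * np.nanmax(out_v), lw=0.8,
                    drawstyle="steps-post", label="state")
            ax.set_title("Adaptive detector", fontsize=9)
            ax.legend(fontsize=7, loc="upper right")
        if show_events:
            for e in session.events:
                ax.axvline((e.time - span[0]) / 1000.0, color="k", ls=":", lw=0.6)
    axes[-1].set_xlabel("time since session start (s)")
    axes[-1].set_xlim(0, (span[1] - span[0]) / 1000.0)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=110)
    return fig
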