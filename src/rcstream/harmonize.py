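"""Harmonization of streams onto one time base, and the stream store.

After per-stream reconstruction each stream lives on its own 1/Fs grid.
Harmonization aligns everything to the time-domain grid (the highest
rate): the grid is extended in exact 1/Fs steps to cover the earliest
and latest sample of any stream, every sample of every other stream is
shifted to its nearest grid time, and the combined data table carries
one row per grid point with explicit NaN where a stream has no sample.

Because a dense combined table of a long, gappy session is mostly NaN,
the persisted form (the "store") instead keeps each stream compact —
only its actual samples with their times — as Parquet plus JSON
settings, and the combined table is rebuilt on load.

Grid arithmetic is done in integer microseconds internally (1e6/Fs is an
integer for every supported rate) so that nearest-point rounding and
tie-breaks are exact; times are exposed as unix-millisecond floats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, StoreError, StoreVersionError
from .ingestion import EventRecord, SessionSettings
from .power import FFTConfig, PowerBand
from .timealign import DerivedTimeSeries

__all__ = [
    "Grid",
    "ProcessedSession",
    "build_unified_grid",
    "align_stream_to_grid",
    "create_combined_table",
    "save_store",
    "load_store",
]

STORE_VERSION = "1"

#: Fixed, documented column order of the combined table.
_COLUMN_GROUPS = ("td", "accel", "power", "adaptive", "fft")


@dataclass(frozen=True)
class Grid:
    """A uniform time grid: ``time(k) = (t0_us + k * step_us) / 1000`` ms."""

    t0_us: int
    step_us: int
    n: int

    @property
    def times_ms(self) -> np.ndarray:
        return (self.t0_us + np.arange(self.n, dtype=np.int64) * self.step_us) / 1000.0

    @property
    def fs(self) -> float:
        return 1e6 / self.step_us

    def nearest_index(self, times_ms: np.ndarray) -> np.ndarray:
        """Nearest grid index per time; exact half-interval ties go earlier."""
        t_us = np.round(np.asarray(times_ms, dtype=float) * 1000.0).astype(np.int64)
        d = t_us - self.t0_us
        q, r = np.divmod(d, self.step_us)
        return (q + (2 * r > self.step_us)).astype(np.int64)


def build_unified_grid(
    td_series: DerivedTimeSeries | None, *other_series: DerivedTimeSeries
) -> Grid:
    """The common grid: the TD grid extended to span every stream.

    The time-domain stream owns the grid (it has the highest rate); grid
    points are prepended/appended in exact 1/Fs steps until the earliest
    and latest sample of any stream are covered.  Without a TD stream
    the highest-rate available stream takes over (with a warning from
    the caller's side).
    """
    candidates = [s for s in (td_series, *other_series) if s is not None and len(s)]
    if not candidates:
        raise ConfigurationError("no non-empty stream to build a grid from")
    if td_series is not None and len(td_series):
        owner = td_series
    else:
        owner = max(candidates, key=lambda s: s.fs)
    step_us = int(round(1e6 / owner.fs))
    t0_us = int(round(owner.derived_time[0] * 1000.0))
    last_us = int(round(owner.derived_time[-1] * 1000.0))

    t_min = min(float(s.derived_time[0]) for s in candidates)
    t_max = max(float(s.derived_time[-1]) for s in candidates)
    t_min_us = int(round(t_min * 1000.0))
    t_max_us = int(round(t_max * 1000.0))

    n_pre = max(0, -(-(t0_us - t_min_us) // step_us)) if t_min_us < t0_us else 0
    n_post = max(0, -(-(t_max_us - last_us) // step_us)) if t_max_us > last_us else 0
    n_owner = int(round((last_us - t0_us) / step_us)) + 1
    return Grid(t0_us=t0_us - n_pre * step_us, step_us=step_us, n=n_pre + n_owner + n_post)


def align_stream_to_grid(
    series: DerivedTimeSeries, grid: Grid, stream_name: str = "stream"
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Assign every sample to its nearest grid point.

    Returns the grid indices plus per-channel full-length columns (NaN
    where no sample landed).  Two samples claiming one grid point is an
    alignment error — impossible when the stream rate does not exceed
    the grid rate, and a sign of a broken reconstruction otherwise.
    """
    idx = grid.nearest_index(series.derived_time)
    if idx.size and (idx[0] < 0 or idx[-1] >= grid.n):
        raise AlignmentError(
            f"{stream_name}: samples fall outside the grid span"
        )
    if idx.size > 1:
        dup = np.flatnonzero(np.diff(idx) == 0)
        if dup.size:
            t_bad = series.derived_time[dup[0] + 1]
            raise AlignmentError(
                f"{stream_name}: two samples map to one grid point near t={t_bad:.3f} ms"
            )
    columns = {}
    for name, vals in series.samples.items():
        col = np.full(grid.n, np.nan)
        col[idx] = vals
        columns[name] = col
    return idx, columns


@dataclass
class ProcessedSession:
    """All reconstructed streams and decoded metadata of one session."""

    td: DerivedTimeSeries | None = None
    accel: DerivedTimeSeries | None = None
    power: DerivedTimeSeries | None = None
    fft_records: list[dict] = field(default_factory=list)
    adaptive_records: list[dict] = field(default_factory=list)
    settings: SessionSettings = field(default_factory=SessionSettings)
    events: list[EventRecord] = field(default_factory=list)
    load_report: pd.DataFrame = field(default_factory=pd.DataFrame)

    def streams(self) -> dict[str, DerivedTimeSeries]:
        out = {}
        for name in ("td", "accel", "power"):
            s = getattr(self, name)
            if s is not None and len(s):
                out[name] = s
        return out

    def time_span_ms(self) -> tuple[float, float]:
        spans = [
            (float(s.derived_time[0]), float(s.derived_time[-1]))
            for s in self.streams().values()
        ]
        if not spans:
            raise ConfigurationError("session has no reconstructed samples")
        return min(a for a, _ in spans), max(b for _, b in spans)


_STREAM_COLUMN_PREFIX = {"td": "TD_ch", "accel": "Accel_", "power": "Power_band"}


def _stream_columns(name: str, series: DerivedTimeSeries) -> dict[str, str]:
    """Map native channel keys to combined-table column names."""
    mapping = {}
    for key in series.samples:
        if name == "td":
            mapping[key] = f"TD_ch{int(key) + 1}"
        elif name == "accel":
            mapping[key] = f"Accel_{key}"
        elif name == "power":
            # native keys Band0.. -> Power_band1..
            num = int(key.replace("Band", "")) + 1 if key.startswith("Band") else key
            mapping[key] = f"Power_band{num}"
        else:
            mapping[key] = f"{name}_{key}"
    return mapping


def create_combined_table(
    session: ProcessedSession,
    include: tuple[str, ...] = ("td", "accel", "power", "adaptive"),
    local_time: bool = True,
    drop_all_nan: bool = True,
) -> pd.DataFrame:
    """Build the analysis-ready combined data table.

    One row per grid point of the unified grid; whenever a stream lacks
    a value for a grid time the entry is NaN.  Columns entirely NaN are
    dropped.  ``include`` selects streams from
    {"td", "accel", "power", "adaptive", "fft"}.
    """
    known = set(_COLUMN_GROUPS)
    unknown = set(include) - known
    if unknown:
        raise ConfigurationError(f"unknown stream(s) {sorted(unknown)}; choose from {sorted(known)}")

    packet_streams = {n: s for n, s in session.streams().items() if n in include}
    grid = build_unified_grid(
        session.td if "td" in include else None,
        *[s for n, s in packet_streams.items() if n != "td"],
    )
    data: dict[str, np.ndarray] = {"DerivedTime": grid.times_ms}
    order: list[str] = ["DerivedTime"]

    if local_time:
        offset_min = session.settings.metadata.get("UtcOffsetMinutes", 0)
        lt = pd.to_datetime(data["DerivedTime"], unit="ms", utc=True) + pd.Timedelta(
            minutes=offset_min
        )
        data["localTime"] = lt.tz_localize(None)
        order.append("localTime")

    for name in ("td", "accel", "power"):
        if name not in packet_streams:
            continue
        series = packet_streams[name]
        _, cols = align_stream_to_grid(series, grid, stream_name=name)
        for key, colname in _stream_columns(name, series).items():
            data[colname] = cols[key]
            order.append(colname)

    if "adaptive" in include and session.adaptive_records:
        t = np.array([r["Time"] for r in session.adaptive_records], dtype=float)
        idx = grid.nearest_index(t)
        ok = (idx >= 0) & (idx < grid.n)
        for fld, colname in (
            ("State", "Adaptive_state"),
            ("Output", "Adaptive_output"),
            ("CurrentMa", "Adaptive_current"),
        ):
            col = np.full(grid.n, np.nan)
            col[idx[ok]] = [session.adaptive_records[i][fld] for i in np.flatnonzero(ok)]
            data[colname] = col
            order.append(colname)

    if "fft" in include and session.fft_records:
        t = np.array([r["Time"] for r in session.fft_records], dtype=float)
        idx = grid.nearest_index(t)
        ok = (idx >= 0) & (idx < grid.n)
        amps = np.array([r["Amplitude"] for r in session.fft_records], dtype=float)
        for b in range(amps.shape[1]):
            col = np.full(grid.n, np.nan)
            col[idx[ok]] = amps[ok, b]
            data[f"FFT_bin{b}"] = col
            order.append(f"FFT_bin{b}")

    table = pd.DataFrame(data, columns=order)
    if drop_all_nan:
        keep = [
            c
            for c in table.columns
            if c in ("DerivedTime", "localTime") or not table[c].isna().all()
        ]
        table = table[keep]
    return table


# ---------------------------------------------------------------------------
# persistence


def _series_to_frame(series: DerivedTimeSeries) -> pd.DataFrame:
    df = pd.DataFrame({"derived_time_us": np.round(series.derived_time * 1000).astype(np.int64)})
    df["grid_index"] = series.grid_index
    df["chunk"] = series.provenance
    for name, vals in series.samples.items():
        df[f"ch_{name}"] = vals
    return df


def _frame_to_series(df: pd.DataFrame, meta: dict) -> DerivedTimeSeries:
    samples = {
        c[len("ch_"):]: df[c].to_numpy() for c in df.columns if c.startswith("ch_")
    }
    return DerivedTimeSeries(
        derived_time=df["derived_time_us"].to_numpy() / 1000.0,
        samples=samples,
        fs=meta["fs"],
        t_ref=meta["t_ref"],
        grid_index=df["grid_index"].to_numpy(),
        provenance=df["chunk"].to_numpy(),
        rejection_log=pd.DataFrame(meta.get("rejection_log", [])),
        chunks=[],
        warnings=list(meta.get("warnings", [])),
    )


def save_store(folder: str | Path, session: ProcessedSession) -> Path:
    """Persist a processed session compactly (Parquet + JSON settings)."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    meta: dict = {"store_version": STORE_VERSION, "streams": {}}
    for name, series in session.streams().items():
        _series_to_frame(series).to_parquet(folder / f"{name}.parquet", index=False)
        meta["streams"][name] = {
            "fs": series.fs,
            "t_ref": series.t_ref,
            "warnings": series.warnings,
            "rejection_log": series.rejection_log.to_dict(orient="records"),
            "chunks": [
                {
                    "start": c.start,
                    "stop": c.stop,
                    "n_samples": c.n_samples,
                    "gap_class": c.gap_class,
                    "anchor_time": c.anchor_time,
                }
                for c in series.chunks
            ],
        }
    side = {
        "fft_records": session.fft_records,
        "adaptive_records": session.adaptive_records,
        "events": [
            {"time": e.time, "type": e.type, "payload": e.payload} for e in session.events
        ],
        "settings": {
            "td_settings": session.settings.td_settings,
            "stim_settings": session.settings.stim_settings.to_dict(orient="records"),
            "fft_config": (
                {
                    "fft_size": session.settings.fft_config.fft_size,
                    "interval": session.settings.fft_config.interval,
                    "window_load": session.settings.fft_config.window_load,
                    "fs": session.settings.fft_config.fs,
                }
                if session.settings.fft_config
                else None
            ),
            "power_bands": [
                {"f_lo": b.f_lo, "f_hi": b.f_hi, "gain": b.gain, "channel": b.channel}
                for b in session.settings.power_bands
            ],
            "adaptive_config": session.settings.adaptive_config,
            "metadata": session.settings.metadata,
        },
        "load_report": session.load_report.to_dict(orient="records"),
    }
    (folder / "meta.json").write_text(json.dumps(meta))
    (folder / "session.json").write_text(json.dumps(side))
    return folder


def load_store(folder: str | Path) -> ProcessedSession:
    """Load a persisted store; loud errors on version mismatch/corruption."""
    folder = Path(folder)
    meta_path = folder / "meta.json"
    if not meta_path.exists():
        raise StoreError(f"not a stream store (no meta.json): {folder}")
    try:
        meta = json.loads(meta_path.read_text())
        side = json.loads((folder / "session.json").read_text())
    except ValueError as exc:
        raise StoreError(f"corrupt store metadata in {folder}: {exc}") from exc
    version = meta.get("store_version")
    if version != STORE_VERSION:
        raise StoreVersionError(
            f"store version {version!r} incompatible with reader version {STORE_VERSION!r}"
        )
    session = ProcessedSession()
    for name, smeta in meta["streams"].items():
        try:
            df = pd.read_parquet(folder / f"{name}.parquet")
        except Exception as exc:  # pyarrow raises its own hierarchy
            raise StoreError(f"corrupt stream file {name}.parquet: {exc}") from exc
        series = _frame_to_series(df, smeta)
        from .timealign import Chunk

        series.chunks = [
            Chunk(
                start=c["start"],
                stop=c["stop"],
                fs=series.fs,
                n_samples=c["n_samples"],
                gap_class=c["gap_class"],
                anchor_time=c["anchor_time"],
            )
            for c in smeta.get("chunks", [])
        ]
        setattr(session, name, series)
    session.fft_records = side.get("fft_records", [])
    session.adaptive_records = side.get("adaptive_records", [])
    session.events = [
        EventRecord(time=e["time"], type=e["type"], payload=e["payload"])
        for e in side.get("events", [])
    ]
    s = side.get("settings", {})
    session.settings = SessionSettings(
        td_settings=s.get("td_settings", []),
        stim_settings=pd.DataFrame(s.get("stim_settings", [])),
        fft_config=FFTConfig(**s["fft_config"]) if s.get("fft_config") else None,
        power_bands=[PowerBand(**b) for b in s.get("power_bands", [])],
        adaptive_config=s.get("adaptive_config", {}),
        metadata=s.get("metadata", {}),
    )
    session.load_report = pd.DataFrame(side.get("load_report", []))
    return session
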