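"""Off-device replication of the RC+S on-board FFT band-power engine.

The implanted device computes band power on-board: the sensed signal (in
internal fixed-point "RCS units") is tapered by a Hann window of
``fft_size_actual`` points, transformed by a single-sided FFT of nominal
size 64/256/1024 (of which only 62/250/1000 points are real samples; the
rest is zero padding), and the squared single-sided amplitudes inside a
configured frequency band are summed and scaled by a gain factor ``G``
(default 2).  Replicating this arithmetic off-device lets users explore
band limits and FFT settings against recorded time-domain data without
re-collecting data on the implant.

The module exposes the individual arithmetic steps (unit conversion, hop
and overlap, window, bin selection, short-time FFT) plus
:func:`calculate_new_power`, which composes them gap-aware over a signal
with missing stretches, and the calibration/comparison helpers used to
match an off-device series against an on-device reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError

__all__ = [
    "AmplifierCalibration",
    "FFTConfig",
    "PowerBand",
    "BandPowerSeries",
    "mv_to_device_units",
    "compute_hop_and_overlap",
    "hann_window",
    "band_bin_indices",
    "short_time_fft_amplitude",
    "calculate_new_power",
    "calibrate_fft_gain",
    "compare_power_series",
]

#: Fixed-point constant the device uses to represent real numbers.
FPV_REAL_UNITS = 48_644.8683623726

#: Number of real (non-padded) samples per transform, keyed by nominal size.
FFT_SIZE_ACTUAL = {64: 62, 256: 250, 1024: 1000}

_VALID_WINDOW_LOADS = (25, 50, 100)


@dataclass(frozen=True)
class AmplifierCalibration:
    """Per-channel amplifier calibration for the mV -> RCS-unit transform.

    Parameters
    ----------
    gain_code : int
        The raw trimmer gain code from the device settings file
        (``config trimmer ch gain``).  The calibrated amplifier gain is
        ``250 * gain_code / 255``.
    fpv : float
        On-device fixed-point constant; do not change unless emulating a
        different firmware build.
    """

    gain_code: int = 250
    fpv: float = FPV_REAL_UNITS

    def __post_init__(self):
        if self.gain_code <= 0:
            raise CalibrationError(f"gain_code must be positive, got {self.gain_code}")


@dataclass(frozen=True)
class FFTConfig:
    """Parameters of the device FFT engine.

    Parameters
    ----------
    fft_size : {64, 256, 1024}
        Nominal transform length.  The device fills only
        ``fft_size_actual`` (62/250/1000) points with real samples and
        zero-pads the rest.
    interval : float
        Seconds between successive power updates (device convention is
        milliseconds; the CLI converts).
    window_load : {25, 50, 100}
        Hann taper depth in percent; 100 is the full Hann window.
    fs : float
        Time-domain sampling rate in Hz.
    """

    fft_size: int = 256
    interval: float = 0.1
    window_load: int = 100
    fs: float = 250.0

    def __post_init__(self):
        if self.fft_size not in FFT_SIZE_ACTUAL:
            raise ConfigurationError(
                f"fft_size must be one of {sorted(FFT_SIZE_ACTUAL)}, got {self.fft_size}"
            )
        if self.interval <= 0:
            raise ConfigurationError(f"interval must be positive, got {self.interval}")
        if self.window_load not in _VALID_WINDOW_LOADS:
            raise ConfigurationError(
                f"window_load must be one of {_VALID_WINDOW_LOADS}, got {self.window_load}"
            )
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")

    @property
    def fft_size_actual(self) -> int:
        return FFT_SIZE_ACTUAL[self.fft_size]

    @property
    def n_bins(self) -> int:
        """Number of single-sided bins (DC through Nyquist inclusive)."""
        return self.fft_size // 2 + 1

    @property
    def bin_centers(self) -> np.ndarray:
        """Center frequency of each single-sided bin, k * fs / fft_size."""
        return np.arange(self.n_bins) * self.fs / self.fft_size


@dataclass(frozen=True)
class PowerBand:
    """A frequency band whose bin powers the device sums.

    ``gain`` is the multiplicative factor G applied to the summed squared
    amplitudes; the device default is 2 but it may be calibrated per
    dataset (:func:`calibrate_fft_gain`).
    """

    f_lo: float
    f_hi: float
    gain: float = 2.0
    channel: int = 0

    def __post_init__(self):
        if not (0 <= self.f_lo < self.f_hi):
            raise ConfigurationError(
                f"band edges must satisfy 0 <= f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]"
            )

    @property
    def label(self) -> str:
        return f"{self.f_lo:g}-{self.f_hi:g}Hz"


@dataclass
class BandPowerSeries:
    """A band-power time series: one value per analysis window.

    ``time`` holds the unix-millisecond DerivedTime of each window's last
    sample (the device reports power at the window end); ``end_index``
    the corresponding sample index into the source signal.
    """

    time: np.ndarray
    power: np.ndarray
    end_index: np.ndarray
    band: PowerBand | None = None
    config: FFTConfig | None = None

    def __len__(self) -> int:
        return len(self.power)


def mv_to_device_units(signal_mv: np.ndarray, cal: AmplifierCalibration) -> np.ndarray:
    """Transform a millivolt signal to internal device (RCS) units.

    The offset voltage (mean over the full input, NaNs ignored) is removed,
    then the amplifier-calibration scaling is applied::

        rcs = (s - mean(s)) * (250 * gain_code / 255) * (fpv / 1000) / 1.2
    """
    s = np.asarray(signal_mv, dtype=float)
    if s.size == 0:
        raise CalibrationError("empty signal")
    mean = np.nanmean(s)
    gain = 250.0 * cal.gain_code / 255.0
    return (s - mean) * gain * (cal.fpv / 1000.0) / 1.2


def compute_hop_and_overlap(cfg: FFTConfig) -> tuple[int, float]:
    """Hop size in samples and fractional window overlap for a config.

    overlap = 1 - fs * interval / fft_size_actual.  A negative overlap
    means successive windows skip samples; it is permitted (the device
    supports sparse update intervals) and simply reported as negative.
    """
    overlap = 1.0 - (cfg.fs * cfg.interval) / cfg.fft_size_actual
    hop = int(round(cfg.fs * cfg.interval))
    if hop < 1:
        raise ConfigurationError(
            f"fft interval {cfg.interval}s is below one sample period at fs={cfg.fs}"
        )
    return hop, overlap


def hann_window(cfg: FFTConfig) -> np.ndarray:
    """The device Hann taper of length ``fft_size_actual``.

    At 100% load this is the standard Hann window
    w(n) = 0.5 (1 - cos(2 pi n / N)) for 0 <= n <= N with window length
    L = N + 1.  Reduced loads (25%, 50%) blend linearly toward a flat
    window: w_l = (1 - l) + l * w_100 with l the load fraction, which
    reproduces the shallower taper of the device's reduced settings and
    reduces to the closed form at 100%.
    """
    load = cfg.window_load
    if load not in _VALID_WINDOW_LOADS:
        raise ConfigurationError(f"window_load must be one of {_VALID_WINDOW_LOADS}")
    L = cfg.fft_size_actual
    n = np.arange(L)
    w100 = 0.5 * (1.0 - np.cos(2.0 * np.pi * n / (L - 1)))
    frac = load / 100.0
    return (1.0 - frac) + frac * w100


def band_bin_indices(band: PowerBand, cfg: FFTConfig) -> np.ndarray:
    """Indices of single-sided FFT bins whose centers lie inside the band.

    Bin k has center k * fs / fft_size for k = 0 .. fft_size/2; a bin is
    included iff f_lo <= center <= f_hi (inclusive at both edges).
    """
    if band.f_hi > cfg.fs / 2 + 1e-12:
        raise ConfigurationError(
            f"band upper edge {band.f_hi} Hz exceeds Nyquist {cfg.fs / 2} Hz"
        )
    centers = cfg.bin_centers
    idx = np.nonzero((centers >= band.f_lo) & (centers <= band.f_hi))[0]
    if idx.size == 0:
        below = centers[centers < band.f_lo]
        above = centers[centers > band.f_hi]
        lo = below[-1] if below.size else None
        hi = above[0] if above.size else None
        raise ConfigurationError(
            f"band [{band.f_lo}, {band.f_hi}] Hz contains no bin center; "
            f"nearest centers are {lo} and {hi} Hz"
        )
    return idx


def short_time_fft_amplitude(
    signal_rcs: np.ndarray, cfg: FFTConfig, times: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided short-time FFT amplitudes, device style.

    Windows of ``fft_size_actual`` consecutive samples advance by the hop
    implied by the FFT interval; each is Hann-tapered, zero-padded to
    ``fft_size`` and transformed.  Single-sided amplitudes are
    ``|X(k)| * 2 / fft_size`` for interior bins and ``|X(k)| / fft_size``
    at DC and Nyquist.  Each window is stamped at its *last* sample.

    Returns ``(window_end, amplitudes)`` where ``window_end`` holds the
    entry of ``times`` at each window's last sample (or the sample index
    itself when ``times`` is None) and ``amplitudes`` is windows x bins.
    """
    x = np.asarray(signal_rcs, dtype=float)
    hop, _ = compute_hop_and_overlap(cfg)
    L = cfg.fft_size_actual
    nbins = cfg.n_bins
    if x.size < L:
        return np.empty(0, dtype=float if times is not None else int), np.empty((0, nbins))
    n_windows = (x.size - L) // hop + 1
    w = hann_window(cfg)
    starts = np.arange(n_windows) * hop
    # gather windows as a strided matrix: n_windows x L
    frames = x[starts[:, None] + np.arange(L)[None, :]] * w[None, :]
    spec = np.fft.rfft(frames, n=cfg.fft_size, axis=1)
    amp = np.abs(spec) / cfg.fft_size
    amp[:, 1:-1] *= 2.0  # interior bins carry both halves of the spectrum
    end_idx = starts + L - 1
    window_end = end_idx if times is None else np.asarray(times)[end_idx]
    return window_end, amp


def _continuous_segments(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean mask."""
    if valid.size == 0:
        return []
    padded = np.concatenate(([False], valid, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def calculate_new_power(
    data,
    cfg: FFTConfig,
    band: PowerBand,
    cal: AmplifierCalibration,
    channel: str | int | None = None,
    times: np.ndarray | None = None,
    quantize: bool = False,
) -> BandPowerSeries:
    """Recompute a device-style band-power series from time-domain data.

    ``data`` is either a combined data table (DataFrame with a
    ``DerivedTime`` column and the requested channel column, NaN where
    samples are missing) or a plain millivolt vector with optional
    ``times``.  The signal is converted to RCS units (one mean over the
    full input), split at gaps into continuous segments so that no
    analysis window spans missing data, and each window contributes
    ``P = G * sum_k amp(k)^2`` over the band's bins.  ``quantize`` rounds
    each power value to the nearest integer, as the device streams
    integers.
    """
    if isinstance(data, pd.DataFrame):
        if channel is None:
            raise ConfigurationError("channel is required with a combined table")
        col = channel if isinstance(channel, str) else f"TD_ch{int(channel)}"
        if col not in data.columns:
            raise ConfigurationError(
                f"channel {col!r} not in table columns {list(data.columns)}"
            )
        signal_mv = data[col].to_numpy(dtype=float)
        times = data["DerivedTime"].to_numpy(dtype=float)
    else:
        signal_mv = np.asarray(data, dtype=float)
    if times is None:
        times = np.arange(signal_mv.size, dtype=float) * (1000.0 / cfg.fs)

    bins = band_bin_indices(band, cfg)
    rcs = mv_to_device_units(signal_mv, cal)
    valid = np.isfinite(rcs)

    out_t: list[np.ndarray] = []
    out_p: list[np.ndarray] = []
    out_i: list[np.ndarray] = []
    for start, stop in _continuous_segments(valid):
        seg = rcs[start:stop]
        end_rel, amp = short_time_fft_amplitude(seg, cfg)
        if len(end_rel) == 0:
            continue
        p = band.gain * np.sum(amp[:, bins] ** 2, axis=1)
        idx = start + np.asarray(end_rel, dtype=np.int64)
        out_i.append(idx)
        out_t.append(np.asarray(times)[idx])
        out_p.append(p)

    if out_p:
        power = np.concatenate(out_p)
        t = np.concatenate(out_t)
        idx = np.concatenate(out_i)
    else:
        power = np.empty(0)
        t = np.empty(0)
        idx = np.empty(0, dtype=np.int64)
    if quantize:
        power = np.rint(power)
    return BandPowerSeries(time=t, power=power, end_index=idx, band=band, config=cfg)


def calibrate_fft_gain(
    off_device: np.ndarray, on_device: np.ndarray, baseline_gain: float = 1.0
) -> float:
    """Least-squares estimate of the FFT gain factor G.

    ``off_device`` is the off-device series computed at ``baseline_gain``
    (pass the series computed with G = 1 for a direct estimate);
    ``on_device`` the device reference, matched sample-for-sample.  The
    estimate minimises sum (G x - y)^2, i.e. G = sum(xy) / sum(x^2),
    rescaled by the baseline.
    """
    x = np.asarray(off_device, dtype=float)
    y = np.asarray(on_device, dtype=float)
    if x.shape != y.shape:
        raise CalibrationError(
            f"series lengths differ: {x.shape} vs {y.shape} (align them first)"
        )
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 10:
        raise CalibrationError(
            f"need at least 10 matched samples to calibrate G, got {int(ok.sum())}"
        )
    x, y = x[ok], y[ok]
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise CalibrationError("off-device series is identically zero")
    return float(np.dot(x, y)) / sxx / baseline_gain


def compare_power_series(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """RMSE, normalized RMSE and percentage difference between two series.

    ``a`` is the on-device reference: nRMSE divides by its max-min range
    and the percentage difference is 100 * mean(|a - b|) / mean(a).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError(f"series lengths differ: {a.shape} vs {b.shape}")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ConfigurationError("need at least 2 aligned samples")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    rng = float(a.max() - a.min())
    mean_a = float(a.mean())
    if rng == 0.0 or mean_a == 0.0:
        raise ConfigurationError(
            "reference series has zero range or zero mean; nRMSE/pct undefined"
        )
    return {
        "rmse": rmse,
        "nrmse": rmse / rng,
        "pct_diff": 100.0 * float(np.mean(np.abs(a - b))) / mean_a,
    }
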