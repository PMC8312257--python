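# Methods

This note documents the models and procedures implemented in
`rcstream`, the choices made where the device documentation is silent,
and what the synthetic-session tests do and do not demonstrate.

## Clock model and time reconstruction

Each packet carries five timing/count variables (see README table).
Reconstruction treats them as follows.

**Order restoration.** Packets are processed in received (file) order;
local transport reordering is undone first by bubble-swapping adjacent
pairs whose sequence numbers are inverted in mod-256 order (difference
in 1..127). The half-modulus threshold distinguishes a swap from
counter rollover; confusing the two would require >127 consecutive
losses.

**Rejection rules**, applied in order, with the "previous packet" for
rules 3–4 being the previous *kept* packet (the reference after a
rejection is otherwise undefined):

1. `timestamp` more than 24 h from the stream's median timestamp;
2. negative `PacketGenTime`;
3. `PacketGenTime` moving backward by more than 500 ms;
4. elapsed `PacketGenTime` disagreeing with elapsed `timestamp` by
   more than 2 s.

**Chunking.** Adjacent packets belong to one chunk iff the sequence
counter advances by exactly 1 (mod 256), the sampling rate is
unchanged, the tick-counter elapsed time matches the sample-count
elapsed time `n/fs` within 10 ticks (1 ms — far below one sample
period at any supported rate, far above float error; the device states
no tolerance), and the timestamp elapsed matches within its 1 s
resolution. A sampling-rate change always starts a new chunk.

**Anchoring.** Within a chunk sampling is exactly regular (only whole
packets go missing). Each chunk is anchored at the *Adjusted
PacketGenTime* of its first packet: the mean (the arithmetic mean, kept
behind one function for easy replacement by a median) of the deviations
between each later packet's `PacketGenTime` and its sample-count
expectation is applied as a single correction. A single-packet chunk
anchors on its own `PacketGenTime`. Sample *m* of the chunk (1-indexed,
first packet holding c1 samples) falls at `anchor + (m - c1) * 1000/fs`
ms.

**Grid snapping.** Chunks after the first are shifted as a whole so
their first sample lands on the nearest point of the first chunk's
1/Fs grid (|shift| ≤ half a period; an exact half-interval tie rounds
toward the earlier point — deterministic and direction-stable). Grid
positions are carried as integer indices so spacing and uniqueness are
exact, not float-approximate. If the first packet of a recording is
rejected, the first kept packet defines the grid origin.

**Short-gap alternative.** Gaps are classified by timestamp: under 6 s
"short" (guaranteed within one tick-counter cycle), otherwise "long".
Optionally (`method="gap"`), short gaps are bridged by tick-counter
elapsed time `((tick_next - tick_prev) mod 2^16) * 1e-4 s` instead of
re-anchoring. Bridged chunks are deliberately *not* snapped back to the
grid: the bridge defines their time base, which is exactly why the tick
clock's rate error accumulates across a recording under this method —
the package reproduces that accumulation in its tests, and the default
method therefore remains PacketGenTime anchoring.

**Collisions.** With heavy jitter a chunk's snapped anchor can land at
or before the previous chunk's last sample. The chunk is pushed to the
next free grid slot and the event is recorded in the series' warnings;
dropping samples instead would violate sample conservation.

`PacketRxUnixTime` is parsed and carried but never used for timing.

## Harmonization

The time-domain stream owns the common grid (highest rate); it is
extended in exact 1/Fs steps to cover the earliest/latest sample of any
stream. Without a TD stream, the highest-rate available stream takes
over (with a warning). Other streams are assigned to their nearest grid
point (ties toward the earlier point, matching the snapping rule; the
tie rule is isolated in one function). Displacement is bounded by half
a TD period; two samples of one stream claiming one grid point is an
error, impossible while stream rates do not exceed the grid rate. Grid
arithmetic uses integer microseconds internally (1e6/Fs is integral for
every supported rate, 250/500/1000 Hz and 4–64 Hz accelerometry), so
rounding and tie-breaks are exact.

The combined table has one row per grid point, NaN for missing
entries, and drops columns that are entirely NaN. The persisted store
keeps each stream compact (only actual samples, Parquet) plus JSON
settings — the dense table of a long gappy session is mostly NaN — and
is versioned; version mismatch and corrupt files fail loudly.

## Device band-power replication

- mV → RCS units: one mean (over the full input, NaNs ignored) is
  subtracted — not per-window means — then scaling by
  `250*gain_code/255 * fpv/1000 / 1.2`, `fpv = 48,644.8683623726`.
- Hop and overlap: `hop = round(fs*interval)` samples,
  `overlap = 1 - fs*interval/fft_size_actual`; negative overlap
  (sparse updates) is permitted and flagged.
- Window: Hann of length `fft_size_actual` (L = N+1,
  `w(n) = 0.5(1 - cos(2πn/N))`). Reduced loads (25/50%) blend linearly
  toward flat, `w_l = (1-l) + l*w_100`: the device documents only the
  shapes, not the formula; the blend reproduces the reduced taper and
  equals the closed form at 100%. Device-exact fidelity of the reduced
  loads is unverified.
- Single-sided FFT scaling: windows take the most recent
  `fft_size_actual` samples, zero-pad to `fft_size`, and amplitudes are
  `|X(k)| * 2/fft_size` for interior bins, `|X(k)|/fft_size` at DC and
  Nyquist. The device's exact scaling constants are not public; the
  convention is fixed and shared between the stream-side emulator and
  the off-device path, so on/off-device comparisons are exact up to
  quantization by construction. Absolute device fidelity cannot be
  established from documentation alone.
- Band bins: bin k center is `k*fs/fft_size`; a bin is included iff
  `f_lo ≤ center ≤ f_hi`, inclusive at both edges (the most literal
  reading of "all bins within the band"; isolated in one function).
- Power: `G * Σ amp²` per window, stamped at the window's last sample;
  gaps split processing so no window spans missing data. `G` defaults
  to 2 and can be calibrated per dataset by least squares
  (`G = Σxy/Σx²` on a G=1 baseline).
- `interval` is seconds in the core API; the CLI takes milliseconds
  (device convention) and converts.

## The session simulator

The simulator is the package's oracle: it generates sessions in the
documented dialect (`dialect_schema.json`) with the true unix time of
every sample retained.

Defaults model a moderately troubled telemetry session: 250 Hz
two-channel LFP (pink noise + 10 Hz rhythm, tens of µV), 64 Hz
accelerometry (smoothed random walk plus broadband movement
transients), packets of 30–120 samples, 5% packet loss, 1% adjacent
reordering, 50 ms SD Gaussian `PacketGenTime` jitter (the error's true
distribution is undocumented; Gaussian is a stand-in, not a claim about
the device), and a 50 ppm tick-counter rate error — the order of
magnitude implied by seconds of tick/timestamp divergence over
multi-hour recordings. `PacketGenTime` is rounded to integer
milliseconds (API resolution). `PacketRxUnixTime` adds a 50 ms + Exp(20
ms) transmission delay. Timing metadata refers to each packet's last
sample; `systemTick = floor(elapsed * 1e4 * (1+drift)) mod 2^16`;
`timestamp = floor(unix seconds - 951,868,800)`. Signal content is
seeded separately (`signal_seed`) from transport impairments so two
simulated devices can record identical motion while suffering
independent packet loss.

The on-device power stream is produced by running the *same* band-power
arithmetic stream-side over the clean signal (integer quantization on
by default, opt-out to separate arithmetic agreement from rounding),
which makes the emulator/off-device comparison a true oracle: with no
packet loss the two series agree to float precision before quantization
and to ≤ 0.5 RCS units after.

What the simulator does *not* model: realistic neural dynamics, the
Bluetooth/UDP stack, sub-sample clock behaviour of the sampling ADC
(samples sit exactly on a unix-time lattice; only the tick counter
drifts), missing individual samples inside packets (the device loses
whole packets), battery/impedance telemetry, and the proprietary
on-device JSON schema (replaced by the documented dialect). Passing
tests therefore demonstrate the correctness of the reconstruction
logic under the stated clock model, not robustness to pathologies the
model excludes.

## Gap-aware analysis

A gap is defined at each stream's *native* rate (structural NaNs of a
slow stream on the TD grid are not gaps). Gap causes are attributed
heuristically: overlap with a rejected packet's `PacketGenTime` →
"rejected"; ≥ 6 s → "stream_stop"; otherwise "dropped". The gap-aware
PSD splits a channel at gaps, discards segments shorter than the
window, and averages Welch periodograms across segments weighted by
window count; on gap-free data it equals a plain Welch estimate with
identical parameters to float precision. Multi-session concatenation
keeps sessions sorted and non-overlapping; inter-session spans appear
as long gaps, and a time-domain rate change across sessions keeps
segments separate and flagged. Plots are static matplotlib panels on a
shared time axis with decoded settings in the titles; the interactive
linked-axis browsing of the original environment is out of scope.

## Problem sizes used in validation

The validation suite exercises: 5 minutes at 500 Hz for the on/off
power agreement (~2,981 windows); 20 minutes at 250 Hz with 5% loss
and 50 ms jitter for time-recovery statistics; two 30-minute devices
for the cross-device drift check; 90 s (>13 tick rollovers) for
rollover robustness. These sizes give stable statistics while keeping
the whole suite in the tens of seconds.

## Known limitations

- The 25/50% window-load shapes and the absolute FFT scaling are
  documented stand-ins (see above); on/off-device comparisons within
  this package are unaffected, absolute device fidelity is unverified.
- Gain, filter and contact codebooks are dialect-defined, not the
  proprietary ones; loaders isolate them so a real-schema adapter can
  replace them.
- The "percentage difference" metric is defined here as
  `100 * mean(|a-b|) / mean(a)` with the on-device series as
  reference; other definitions exist and the choice is isolated in
  `compare_power_series`.
- Mid-session time-domain rate changes are handled by forcing chunk
  boundaries and hosting the stream on the first chunk's grid; samples
  of a faster later segment are strictly ordered but cannot keep exact
  spacing on the host grid. Rate changes are far better handled as
  separate sessions.
- The embedded linear-discriminant detector is not emulated; the
  adaptive stream is ingested and displayed only.
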