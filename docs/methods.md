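# Methods

This note documents the models, conventions and numerical choices behind
`drivedaq`, and what the test suite does and does not establish.

## 1. The record format and its conventions

The on-disk session is a headerless concatenation of fixed 4096-byte
records (20 B metadata + 2048 B neural + 192 B aux + 1836 B zero
padding), written in 128-record blocks. Several low-level details are
conventions of this package, chosen once and fixed:

- **Record size and padding placement.** Padding is applied per sample,
  to 4096 bytes. This is the unique reading consistent with both the
  stream's 122.88 MB/s total rate at 30 kS/s (4096 = 122 880 000/30 000)
  and a padding share of 44.8 % (1836/4096). Per-block padding cannot
  produce both figures.
- **Endianness.** All integer fields are little-endian — a single
  constant, matching the commodity x86/ARM family that consumes these
  drives. The format has no mixed-endian fields.
- **Metadata packing.** `<QIII`: experiment id, module id, sample index,
  chip-live mask, no gaps (20 bytes exactly).
- **Signedness.** Channel words are raw unsigned ADC codes with mid-scale
  32768 ≡ 0 V. Conversion to microvolts lives only in the simulator and
  analysis helpers, never in the codec: the codec's contract is
  bit-exactness.
- **Chip-live bit order.** Bit *i* (LSB = chip 0) covers neural channels
  `32i..32i+31` and aux slots `3i..3i+2`. Channel ids are 0-based and
  chip-major; aux channels are globally numbered 1024–1119.
- **Partial blocks.** The hardware writes until the drive is full, so a
  file need not be a whole number of blocks. The reader accepts any
  multiple of 4096 bytes; a sub-record tail is reported (warning on read,
  `TRUNCATED_TAIL` in validation), never silently dropped.

### Overhead percentages: two denominators

The conventional figures "metadata = 0.9 %" and "padding = 44.8 %" are
both quoted against "the channel data rate", but they are reproducible
only with different denominators: 20/2240 (metadata over neural+aux
payload) and 1836/4096 (padding over the whole record). `budget`
implements exactly these two ratios and this note is the documentation of
the discrepancy.

### The 831-channel headroom

Each additional neural channel costs its own 2 bytes plus a proportional
share of aux (2 × 96/1024 B) and metadata (20/1024 B), i.e.
2.20703125 B, so ⌊1836/2.20703125⌋ = 831 channels fit in the padding.
Whole-chip accounting cannot reproduce this number (26 chips would need
1840 B > 1836 B); the continuous proportional reading is used.

### Units

Decimal throughout: MB = 10⁶ B, GB = 10⁹ B — the only convention under
which 4096 × 30 000 prints as 122.88 MB/s. Drive capacity in minutes is
reported as a ceiling ("up to N min"); raw seconds are also returned.
Capacity arithmetic takes arbitrary byte counts rather than hard-coding
any vendor's usable-capacity convention.

## 2. The synthetic session generator

`simulate.generate_session` emulates the acquisition front end, not the
brain. Its defaults are the recorded system's operating conditions:

| parameter | default | rationale |
|---|---|---|
| `sample_rate` | 30 000 /s | the module's acquisition rate |
| `noise_rms_uv` | 3.9 µV | the measured input-referred noise floor of the full system |
| `lsb_uv` | 0.195 µV/code | the digitization step of the amplifier-chip family used; the format itself does not fix a scale, so this is a package default |
| `pitch_um`, `n_columns` | 11.5 µm, 4 | the close-packed probe geometry |
| `spike_peak_uv` | 150 µV | a typical well-isolated extracellular unit on such probes (recordings there span ~±200 µV) |
| `spike_duration_ms` | 1.2 ms | extracellular spike width |
| `spatial_decay_um` | 25 µm | length constant giving a multi-site footprint of order ten sites, as seen on close-packed arrays |
| `n_units`, `firing_rate_hz` | 8 units, 5 Hz | a modest cortical population under light anesthesia |
| `gpio` | 2 kHz latch | GPIO state is recorded at 2 kHz among the aux channels |

Model components:

- **Noise** is white Gaussian in µV, added before quantization. The
  600–9700 Hz band is the *measurement* band: `analysis.bandpass` applies
  it when analyzing, generation does not shape the spectrum. Passing the
  RMS-recovery test therefore shows correct amplitude calibration, not a
  realistic noise spectrum (no 1/f, no line hum, no spatial correlation).
- **Spikes** are a homogeneous Poisson process per unit (`rng.poisson`
  count + sorted uniform times), rendered with a fixed biphasic template
  (fast negative lobe, slower positive lobe, negative peak normalized to
  −1) and per-site amplitude `peak · exp(−distance/decay)` from a unit
  position drawn uniformly over the array. Amplitudes below 0.25 µV
  (≈ 0.1 LSB) are truncated to zero for speed. No bursting, drift,
  refractoriness between units, or waveform variability is modeled —
  detection tests validate the data path, not a spike sorter.
- **GPIO**: the 16-bit word is sampled on the 2 kHz tick grid and held
  for 15 consecutive 30 kS/s samples in one designated aux slot
  (default: global aux 0); the mapping of a 2 kHz signal onto 30 kS/s aux
  slots is a package convention, configurable. Remaining aux slots of
  live chips carry a constant filler code (default 32768).
- **Dead chips** have their chip-live bit clear and carry zero filler:
  consumers must rely on the mask, never on content.
- **Determinism**: one `SeedSequence(seed)` is split into independent
  spike and noise streams; noise is drawn in fixed 128-sample blocks so
  the byte stream is invariant to how the iterator is consumed. Two runs
  with equal `(config, seed)` are byte-identical.
- **Ground truth**: `session_ground_truth(config)` re-derives the exact
  unit positions, per-site amplitudes and spike trains the generator
  embedded, so analyses can be scored against the generator's own events.

## 3. The integrity validator

A single streaming pass (one record in memory at a time) checks:
constant experiment/module identifiers, sample index advancing by exactly
1 mod 2³² (so a rollover is not a skip), all-zero padding, and — when an
expected byte count is given — agreement of ⌊bytes/4096⌋ with the record
count. Design choices:

- **Repeat vs skip** are distinct error kinds (`INDEX_REPEAT` for delta
  0, `INDEX_SKIP` for delta ≥ 2): they have different hardware causes.
- **Full census, not fail-fast**: validation continues after the first
  error, for forensic use. Identifier checks compare against the first
  record (not the previous one), so a single corrupted record yields a
  single error rather than a change-and-change-back pair.
- **Chip-live changes** mid-session are reported as `ID_CHANGE` by
  default; whether a chip may legitimately die mid-session is
  system-dependent, so `allow_chip_live_change=True` relaxes it.
- Exit codes at the CLI: 0 pass, 1 fail, 2 usage/I-O — an unreadable
  file is an I/O failure, not a failed report.

## 4. The datagram data plane

Snapshots (one full 1024-channel time point) and selected-channel
streams are fragmented into datagrams of at most 1472 bytes (Ethernet
MTU minus IP/UDP headers) with a 30-byte little-endian header — this
wire dialect is the package's own, documented in `netstream`. The
default fragmentation cap is 700 words/datagram, so a snapshot is 2
fragments (700 + 324). Loss is i.i.d. Bernoulli erasure (no reordering
or corruption model); reassembly is out-of-order and duplicate tolerant
and never blocks: missing fragments are enumerated per (sample,
fragment), and sample indices inside the observed contiguous range with
no surviving fragment are reported as wholly missing. Samples lost at
the very edges of the range are indistinguishable from a shorter
transmission — a limitation inherent to sequence-number gap detection.
The reliable TCP control plane is out of scope; its reliability contrast
with the data plane is captured by the loss tests, not by a protocol
implementation. Transport is in-memory (packet logs are length-prefixed
files); no sockets are bound.

`stream_bandwidth` counts payload plus this header at the chosen
fragmentation: a full 1024-channel, 30 kS/s mirror is 491.52 Mb/s of
payload (≈ 506 Mb/s with headers), comfortably within 1 Gb/s.

## 5. Clock synchronization and merging

`ModuleClock` models a crystal: nominal rate, fractional error in ppm
(|drift| < 1000), per-edge Gaussian jitter, fixed latch delay. Three
schemes:

- **FREE**: sample *k* at `k/(rate·(1+drift))` — drift accumulates;
  two modules differing by *d* ppm are `d·10⁻⁶·t` apart after elapsed
  time *t* (90 ms after 30 min at 50 ppm, thousands of sample periods).
- **PULSED**: a shared pulse at every 30 kHz tick; each sample fires at
  the pulse time plus latch delay and jitter, so skew is bounded
  uniformly in time — sub-microsecond for realistic jitter, well within
  the 33.3 µs sample period.
- **START_ONLY**: a single shared start edge then free running —
  numerically identical to FREE here since all schemes share t = 0; it
  exists so the two readings of "start pulse" can be compared.

Pulses are modeled as lossless. `simulate_timestamps` accepts a
decimated ordinal grid so half-hour recordings can be probed without
materializing 5.4 × 10⁷ ticks per module.

Merging aligns per-module sessions on (experiment id, unwrapped sample
index): rows cover the union of index ranges, columns are module-major
(all neural blocks, then all aux blocks), and a module missing an index
yields an explicit per-row presence flag with zero-filled words — never
a silent misalignment. No cross-correlation alignment is attempted, and
unwrapping assumes the sessions began within the same 2³² index epoch.

## 6. Problem sizes and numerical details

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each statistic is sharp: 10³ random samples for
codec round-trips, 10⁵ samples for noise RMS (±5 % band; standard error
of RMS at n = 10⁵ is ≈ 0.2 %), 10⁴ datagrams at 10 % loss (binomial 4σ
band), 256-record sessions for fault injection, and a 30-minute skew
simulation probed once per second. Quantization rounds half to even
(numpy `rint`) and saturates at 0/65535; spike detection uses negative
threshold crossings with a 1–1.5 ms refractory merge, which slightly
overcounts on long noisy traces (isolated noise excursions below −4·RMS)
and undercounts coincident spikes — both effects are within the Poisson
tolerance the recovery checks use.

## 7. Known limitations

- The simulator validates the *data path*, not biology: no drift,
  bursting, correlated noise, or electrode impedance effects; conclusions
  from passing tests transfer to real recordings only at the format and
  bookkeeping level.
- The wire dialect and the GPIO aux-slot mapping are package
  conventions; hardware implementations may differ while sharing the
  on-disk format.
- The validator assumes one session per source; concatenated sessions
  are reported as identifier changes by design.
- Merging requires whole sessions in memory (matrix construction); a
  streaming merge is future work.
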