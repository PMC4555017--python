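"""Synthetic acquisition sessions: spiking signals, noise, GPIO, rollover.

Emulates what the acquisition front end would digitize during an
extracellular recording on a close-packed silicon probe: a white Gaussian
noise floor (default 3.9 µV RMS input-referred), Poisson-firing units
whose ~1 ms biphasic spikes are picked up by several neighbouring sites of
an 11.5 µm-pitch, 4-column array with exponentially decaying amplitude,
16 GPIO lines latched at 2 kHz into a designated auxiliary channel, dead
amplifier chips, and the 32-bit sample-counter rollover.

Generation is a pure function of ``(config, seed)``: two runs with the
same configuration produce byte-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from .layout import DEFAULT_LAYOUT, INDEX_MODULUS, ModuleSample, RecordLayout, SampleMetadata

__all__ = [
    "SimConfig",
    "generate_spike_times",
    "biphasic_waveform",
    "site_positions",
    "render_unit",
    "quantize",
    "dequantize",
    "gpio_words",
    "generate_session",
    "session_ground_truth",
    "UnitGroundTruth",
    "named_gpio_pattern",
]

MID_CODE = 32768  # ADC code corresponding to 0 V


@dataclass
class SimConfig:
    """Generative model parameters for one synthetic session.

    Parameters
    ----------
    n_chips
        Amplifier chips present (1-32); chips beyond this count are marked
        absent in the chip-live mask.
    dead_chips
        Chips within range that are powered but inactive; their chip-live
        bit is clear and their channels carry zero filler.
    duration_samples
        Session length in 30 kS/s ticks.
    noise_rms_uv
        Input-referred noise floor, µV RMS (white Gaussian before
        quantization).
    lsb_uv
        Microvolts per ADC code; mid-scale code 32768 is 0 V.
    n_units, firing_rate_hz
        Count of simulated neurons and their per-unit homogeneous Poisson
        rate.
    spike_peak_uv, spike_duration_ms
        Negative-peak amplitude at the nearest site and total width of the
        biphasic spike template.
    pitch_um, n_columns
        Recording-site geometry: a close-packed grid, 4 columns at
        11.5 µm pitch by default.
    spatial_decay_um
        Length constant of the exponential amplitude falloff across sites.
    gpio_pattern
        Callable ``t_seconds -> 16-bit word`` giving the GPIO state; it is
        sampled on the 2 kHz tick grid and held for 15 acquisition samples.
    gpio_aux_slot
        Global auxiliary slot (0-95) that carries the GPIO word.
    aux_fill
        Constant code filling the remaining auxiliary slots of live chips.
    start_index
        Initial 32-bit sample index; the counter wraps modulo 2**32.
    """

    n_chips: int = 32
    dead_chips: frozenset[int] = field(default_factory=frozenset)
    sample_rate: int = 30_000
    duration_samples: int = 30_000
    noise_rms_uv: float = 3.9
    lsb_uv: float = 0.195
    n_units: int = 8
    firing_rate_hz: float = 5.0
    spike_peak_uv: float = 150.0
    spike_duration_ms: float = 1.2
    pitch_um: float = 11.5
    n_columns: int = 4
    spatial_decay_um: float = 25.0
    gpio_pattern: Callable[[float], int] | None = None
    gpio_aux_slot: int = 0
    aux_fill: int = MID_CODE
    start_index: int = 0
    experiment_id: int = 1_441_065_600  # session tag: a UNIX UTC timestamp
    module_id: int = 0xDAC0FFEE
    seed: int = 0

    def __post_init__(self):
        self.dead_chips = frozenset(self.dead_chips)
        if not 1 <= self.n_chips <= 32:
            raise ValueError(f"n_chips must be in 1..32, got {self.n_chips}")
        if any(not 0 <= c < self.n_chips for c in self.dead_chips):
            raise ValueError("dead_chips outside configured chip range")
        if self.duration_samples < 1:
            raise ValueError("duration_samples must be >= 1")
        if self.noise_rms_uv < 0 or self.firing_rate_hz < 0:
            raise ValueError("noise_rms_uv and firing_rate_hz must be >= 0")

    @property
    def chip_live(self) -> int:
        mask = (1 << self.n_chips) - 1
        for c in self.dead_chips:
            mask &= ~(1 << c)
        return mask

    @property
    def duration_s(self) -> float:
        return self.duration_samples / self.sample_rate

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        pat = d.get("gpio_pattern")
        if isinstance(pat, str):
            d["gpio_pattern"] = named_gpio_pattern(pat)
        if "dead_chips" in d and d["dead_chips"] is not None:
            d["dead_chips"] = frozenset(d["dead_chips"])
        return cls(**d)


def named_gpio_pattern(name: str) -> Callable[[float], int] | None:
    """Resolve a config-file GPIO pattern spec into a callable.

    Supported: ``zero``, ``constant:<word>``, ``counter`` (2 kHz tick count
    truncated to 16 bits), ``square:<pin>:<freq_hz>``.
    """
    if name in ("zero", "none", ""):
        return None
    if name.startswith("constant:"):
        word = int(name.split(":", 1)[1], 0) & 0xFFFF

        return lambda t: word
    if name == "counter":
        return lambda t: int(round(t * 2000)) & 0xFFFF
    if name.startswith("square:"):
        _, pin, freq = name.split(":")
        pin, freq = int(pin), float(freq)
        return lambda t: (int(t * 2 * freq) & 1) << pin
    raise ValueError(f"unknown GPIO pattern spec: {name!r}")


def generate_spike_times(
    rate_hz: float, duration_s: float, seed
) -> np.ndarray:
    """Sorted event times (s) of a homogeneous Poisson process.

    ``seed`` may be an int, SeedSequence, or Generator; identical seeds
    give identical trains.
    """
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def biphasic_waveform(
    sample_rate: int = 30_000, duration_ms: float = 1.2
) -> np.ndarray:
    """Unit-amplitude extracellular spike template.

    A fast negative (depolarization) lobe followed by a slower positive
    repolarization lobe, normalized so the negative peak is exactly -1.
    """
    n = max(3, int(round(duration_ms * 1e-3 * sample_rate)))
    t = np.arange(n) / sample_rate * 1e3  # ms
    t_neg = 0.3 * duration_ms
    t_pos = 0.55 * duration_ms
    w = -np.exp(-0.5 * ((t - t_neg) / (0.08 * duration_ms)) ** 2)
    w += 0.35 * np.exp(-0.5 * ((t - t_pos) / (0.18 * duration_ms)) ** 2)
    return w / np.abs(w.min())


def site_positions(
    n_sites: int, pitch_um: float = 11.5, n_columns: int = 4
) -> np.ndarray:
    """(n_sites, 2) x/y positions in µm of a close-packed column grid."""
    idx = np.arange(n_sites)
    return np.column_stack([(idx % n_columns), (idx // n_columns)]) * pitch_um


def render_unit(
    sites: np.ndarray,
    unit_position: np.ndarray,
    peak_uv: float,
    spatial_decay_um: float,
) -> np.ndarray:
    """Per-site spike amplitude map: peak * exp(-distance / decay).

    Amplitude decreases strictly with distance; with a decay constant at
    or above the inter-site pitch, several neighbouring sites see more
    than half the peak, reproducing the multi-site footprint of
    close-packed arrays.
    """
    dist = np.linalg.norm(np.asarray(sites, float) - np.asarray(unit_position, float), axis=1)
    return peak_uv * np.exp(-dist / spatial_decay_um)


def quantize(uv, lsb_uv: float = 0.195) -> np.ndarray:
    """Microvolts -> 16-bit ADC code: round, offset to mid-scale, saturate."""
    code = np.rint(np.asarray(uv, dtype=np.float64) / lsb_uv) + MID_CODE
    return np.clip(code, 0, 65535).astype(np.uint16)


def dequantize(code, lsb_uv: float = 0.195) -> np.ndarray:
    """16-bit ADC code -> microvolts (inverse of :func:`quantize` up to rounding)."""
    return (np.asarray(code, dtype=np.float64) - MID_CODE) * lsb_uv


def gpio_words(
    duration_samples: int,
    gpio_pattern: Callable[[float], int] | None,
    sample_rate: int = 30_000,
    gpio_rate: int = 2_000,
    start_sample: int = 0,
) -> np.ndarray:
    """Per-acquisition-sample 16-bit GPIO words.

    GPIO state is latched on the 2 kHz tick grid and each latched word is
    held for ``sample_rate // gpio_rate`` (= 15) consecutive acquisition
    samples.
    """
    if gpio_pattern is None:
        return np.zeros(duration_samples, dtype=np.uint16)
    hold = sample_rate // gpio_rate
    samples = np.arange(start_sample, start_sample + duration_samples)
    ticks = samples // hold
    uniq = np.unique(ticks)
    lut = {int(k): int(gpio_pattern(k / gpio_rate)) & 0xFFFF for k in uniq}
    return np.array([lut[int(k)] for k in ticks], dtype=np.uint16)


@dataclass
class UnitGroundTruth:
    """What the generator actually drew for one simulated neuron."""

    position: np.ndarray  # (2,) µm
    amplitudes: np.ndarray  # per live channel, µV at the negative peak
    spike_times: np.ndarray  # seconds
    spike_samples: np.ndarray  # acquisition-sample ordinals within the session


def _unit_ground_truth(config: SimConfig, sites: np.ndarray, seed_seq) -> list[UnitGroundTruth]:
    ss_pos, ss_trains = seed_seq.spawn(2)
    rng_pos = np.random.default_rng(ss_pos)
    lo, hi = sites.min(axis=0), sites.max(axis=0)
    units = []
    for ss in ss_trains.spawn(config.n_units):
        pos = rng_pos.uniform(lo, hi)
        amp = render_unit(sites, pos, config.spike_peak_uv, config.spatial_decay_um)
        amp[amp < 0.25] = 0.0  # negligible far-field, below 0.1 LSB
        times = generate_spike_times(config.firing_rate_hz, config.duration_s, ss)
        starts = np.rint(times * config.sample_rate).astype(np.int64)
        keep = starts < config.duration_samples
        units.append(UnitGroundTruth(pos, amp, times[keep], starts[keep]))
    return units


def session_ground_truth(
    config: SimConfig, layout: RecordLayout = DEFAULT_LAYOUT
) -> list[UnitGroundTruth]:
    """Unit positions, per-site amplitudes and spike trains of a session.

    Reproduces exactly what :func:`generate_session` embeds for the same
    config, so detection analyses can be scored against the generator's
    own events.  Amplitudes are indexed over live channels in chip-major
    order.
    """
    live_chips = [c for c in range(config.n_chips) if c not in config.dead_chips]
    live_cols = np.concatenate(
        [np.arange(c * layout.channels_per_chip, (c + 1) * layout.channels_per_chip) for c in live_chips]
    ) if live_chips else np.empty(0, dtype=int)
    sites = site_positions(
        config.n_chips * layout.channels_per_chip, config.pitch_um, config.n_columns
    )[live_cols]
    ss_spikes, _ = np.random.SeedSequence(config.seed).spawn(2)
    return _unit_ground_truth(config, sites, ss_spikes)


class _SpikePainter:
    """Adds rendered spikes into per-block signal matrices."""

    def __init__(self, config: SimConfig, sites: np.ndarray, seed_seq):
        self.template = biphasic_waveform(config.sample_rate, config.spike_duration_ms)
        self.length = self.template.size
        units = _unit_ground_truth(config, sites, seed_seq)
        self.amps = [u.amplitudes for u in units]
        events = [(int(s), u) for u, unit in enumerate(units) for s in unit.spike_samples]
        self.events = sorted(events)
        self.starts = np.array([e[0] for e in self.events], dtype=np.int64)

    def paint(self, signal_uv: np.ndarray, b0: int) -> None:
        """Add every spike overlapping block rows [b0, b0 + len(signal))."""
        b1 = b0 + signal_uv.shape[0]
        i = np.searchsorted(self.starts, b0 - self.length + 1)
        j = np.searchsorted(self.starts, b1)
        for s, u in self.events[i:j]:
            t0, t1 = max(s, b0), min(s + self.length, b1)
            seg = self.template[t0 - s : t1 - s]
            signal_uv[t0 - b0 : t1 - b0, :] += seg[:, None] * self.amps[u][None, :]


def generate_session(
    config: SimConfig, layout: RecordLayout = DEFAULT_LAYOUT
) -> Iterator[ModuleSample]:
    """Stream a synthetic session as an ordered source of samples.

    Live chips carry quantized noise + rendered spikes; dead or absent
    chips carry zero filler with their chip-live bit clear (readers must
    consult the mask, not the content).  Auxiliary slots hold the constant
    filler code except the designated GPIO slot.  Memory use is constant:
    the session is produced one 128-sample write block at a time, and the
    random draws are block-structured so output bytes do not depend on how
    the iterator is consumed.
    """
    if config.n_chips > layout.n_chips:
        raise ValueError(
            f"n_chips={config.n_chips} exceeds layout capacity {layout.n_chips}"
        )
    live_chips = [c for c in range(config.n_chips) if c not in config.dead_chips]
    live_cols = np.concatenate(
        [np.arange(c * layout.channels_per_chip, (c + 1) * layout.channels_per_chip) for c in live_chips]
    ) if live_chips else np.empty(0, dtype=int)
    sites_all = site_positions(
        config.n_chips * layout.channels_per_chip, config.pitch_um, config.n_columns
    )
    ss = np.random.SeedSequence(config.seed)
    ss_spikes, ss_noise = ss.spawn(2)
    rng_noise = np.random.default_rng(ss_noise)
    painter = (
        _SpikePainter(config, sites_all[live_cols], ss_spikes)
        if config.n_units > 0 and live_cols.size
        else None
    )
    meta_proto = SampleMetadata(
        experiment_id=config.experiment_id,
        module_id=config.module_id,
        sample_index=0,
        chip_live=config.chip_live,
    )
    gpio_chip = config.gpio_aux_slot // layout.aux_per_chip
    aux_base = np.zeros(layout.n_aux, dtype=np.uint16)
    for c in live_chips:
        aux_base[c * layout.aux_per_chip : (c + 1) * layout.aux_per_chip] = config.aux_fill
    block = layout.block_samples
    for b0 in range(0, config.duration_samples, block):
        n = min(block, config.duration_samples - b0)
        if live_cols.size:
            signal = rng_noise.normal(0.0, config.noise_rms_uv, size=(n, live_cols.size))
            if painter is not None:
                painter.paint(signal, b0)
            codes = quantize(signal, config.lsb_uv)
        gpio = gpio_words(
            n, config.gpio_pattern, config.sample_rate, layout.gpio_rate, start_sample=b0
        )
        for r in range(n):
            neural = np.zeros(layout.n_neural, dtype=np.uint16)
            if live_cols.size:
                neural[live_cols] = codes[r]
            aux = aux_base.copy()
            aux[config.gpio_aux_slot] = gpio[r]
            idx = (config.start_index + b0 + r) % INDEX_MODULUS
            meta = SampleMetadata(
                meta_proto.experiment_id, meta_proto.module_id, idx, meta_proto.chip_live
            )
            yield ModuleSample(meta, neural, aux)
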