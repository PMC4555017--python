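"""Rate, overhead, capacity and headroom arithmetic for the record format.

All figures derive from a :class:`~drivedaq.layout.RecordLayout` in closed
form.  Units are decimal throughout: 1 MB = 10**6 bytes, 1 GB = 10**9
bytes — the convention under which a 4096-byte record at 30 kS/s is
exactly 122.88 MB/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .layout import DEFAULT_LAYOUT, INDEX_MODULUS, RecordLayout

__all__ = [
    "SATA1_BYTES_PER_S",
    "BudgetSpec",
    "data_rate",
    "channel_data_rate",
    "metadata_overhead_pct",
    "padding_pct",
    "recording_capacity",
    "rollover_hours",
    "per_chip_rate_mbit",
    "total_channel_count",
    "extra_channel_capacity",
    "sata_headroom",
    "budget_table",
]

#: SATA 1 payload rate: 1.5 Gb/s line rate with 8b/10b coding = 187.5 MB/s.
SATA1_BYTES_PER_S = 187_500_000


@dataclass(frozen=True)
class BudgetSpec:
    """A layout paired with a storage target and interface limit."""

    layout: RecordLayout = DEFAULT_LAYOUT
    drive_bytes: int = 512 * 10**9
    sata_limit: int = SATA1_BYTES_PER_S

    def __post_init__(self):
        if self.drive_bytes <= 0:
            raise ValueError("drive_bytes must be positive")


def data_rate(layout: RecordLayout = DEFAULT_LAYOUT) -> int:
    """Total bytes/s to disk: record size times sample rate.

    Default layout: 4096 x 30000 = 122,880,000 B/s (122.88 MB/s).
    """
    return layout.record_bytes * layout.sample_rate


def channel_data_rate(layout: RecordLayout = DEFAULT_LAYOUT) -> int:
    """Bytes/s of neural + auxiliary payload only (no metadata, no padding)."""
    return (layout.neural_bytes + layout.aux_bytes) * layout.sample_rate


def metadata_overhead_pct(layout: RecordLayout = DEFAULT_LAYOUT) -> float:
    """Metadata bytes as a percentage of the channel payload, 1 decimal.

    20 / 2240 for the default layout -> 0.9.
    """
    payload = layout.neural_bytes + layout.aux_bytes
    if payload == 0:
        return 0.0
    return round(100.0 * layout.meta_bytes / payload, 1)


def padding_pct(layout: RecordLayout = DEFAULT_LAYOUT) -> float:
    """Zero padding as a percentage of the whole record, 1 decimal.

    1836 / 4096 for the default layout -> 44.8.  Note the denominator
    differs from :func:`metadata_overhead_pct`: these are the two readings
    under which the conventional printed figures are reproduced.
    """
    if layout.record_bytes == 0:
        return 0.0
    return round(100.0 * layout.pad_bytes / layout.record_bytes, 1)


def recording_capacity(spec: BudgetSpec) -> dict:
    """How much a drive holds: whole samples, seconds, and ceiled minutes.

    A 512 GB (decimal) drive at the default layout stores 125,000,000
    samples = 69.44 min, reported as "up to 70 min".
    """
    samples = spec.drive_bytes // spec.layout.record_bytes
    seconds = samples / spec.layout.sample_rate
    return {
        "samples": samples,
        "seconds": seconds,
        "minutes_ceil": math.ceil(seconds / 60.0),
    }


def rollover_hours(layout: RecordLayout = DEFAULT_LAYOUT) -> int:
    """Whole hours until the 32-bit sample counter wraps (floor).

    floor(2**32 / 30000 / 3600) = 39 h at the default rate.
    """
    return int(INDEX_MODULUS // layout.sample_rate // 3600)


def per_chip_rate_mbit(layout: RecordLayout = DEFAULT_LAYOUT) -> float:
    """Mbit/s produced by one amplifier chip (32 neural + 3 aux words).

    35 words x 16 bit x 30000 /s = 16.8 Mbit/s.
    """
    words = layout.channels_per_chip + layout.aux_per_chip
    return words * layout.sample_rate * 16 / 1e6


def total_channel_count(layout: RecordLayout = DEFAULT_LAYOUT) -> int:
    """All channels sampled at the full rate: 32 x (32 + 3) = 1120."""
    return layout.n_chips * (layout.channels_per_chip + layout.aux_per_chip)


def extra_channel_capacity(layout: RecordLayout = DEFAULT_LAYOUT) -> int:
    """Additional neural channels the padding region could carry.

    Each added neural channel costs its own 2 bytes plus a proportional
    share of auxiliary data (96 aux words per 1024 neural) and metadata
    (20 B per 1024 neural):

        cost = 2 + 2 * (n_aux / n_neural) + meta_bytes / n_neural

    = 2.20703125 B for the default layout, so floor(1836 / cost) = 831
    channels fit in the padding.  Whole-chip accounting cannot reach this
    figure (26 chips would need 1840 B > 1836 B); the proportional reading
    is the one consistent with the format's stated headroom.
    """
    if layout.n_neural == 0:
        return 0
    cost = 2.0 + 2.0 * layout.n_aux / layout.n_neural + layout.meta_bytes / layout.n_neural
    return int(layout.pad_bytes / cost)


def sata_headroom(spec: BudgetSpec) -> dict:
    """Whether the stream fits the storage interface, and by how much."""
    rate = data_rate(spec.layout)
    return {"fits": rate <= spec.sata_limit, "margin": spec.sata_limit - rate}


def budget_table(spec: BudgetSpec) -> dict:
    """Every derived figure for one spec, as a flat JSON-friendly dict."""
    layout = spec.layout
    cap = recording_capacity(spec)
    head = sata_headroom(spec)
    return {
        "record_bytes": layout.record_bytes,
        "block_bytes": layout.block_bytes,
        "neural_bytes": layout.neural_bytes,
        "aux_bytes": layout.aux_bytes,
        "meta_bytes": layout.meta_bytes,
        "pad_bytes": layout.pad_bytes,
        "total_channels": total_channel_count(layout),
        "data_rate_bytes_s": data_rate(layout),
        "data_rate_mb_s": data_rate(layout) / 1e6,
        "channel_data_rate_bytes_s": channel_data_rate(layout),
        "metadata_overhead_pct": metadata_overhead_pct(layout),
        "padding_pct": padding_pct(layout),
        "per_chip_rate_mbit_s": per_chip_rate_mbit(layout),
        "rollover_hours": rollover_hours(layout),
        "extra_neural_channels": extra_channel_capacity(layout),
        "drive_bytes": spec.drive_bytes,
        "capacity_samples": cap["samples"],
        "capacity_seconds": cap["seconds"],
        "capacity_minutes_ceil": cap["minutes_ceil"],
        "sata_limit_bytes_s": spec.sata_limit,
        "sata_fits": head["fits"],
        "sata_margin_bytes_s": head["margin"],
    }
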