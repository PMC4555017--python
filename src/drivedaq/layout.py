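"""On-disk record layout and in-memory sample containers.

A direct-to-drive acquisition module emits one fixed-size binary record per
sample tick.  Each record is the concatenation of

* 20 bytes of metadata (experiment id, module id, sample index, chip-live
  mask),
* 1024 neural channel words (32 amplifier chips x 32 channels, 16-bit),
* 96 auxiliary words (3 per chip, carrying GPIO state and amplifier
  housekeeping), and
* zero padding bringing the record to exactly 4096 bytes.

Records are written to the drive sequentially, with no file system, headers
or separators, in blocks of 128 records (512 KiB).  All integers are
little-endian; neural and auxiliary samples are raw unsigned 16-bit ADC
codes (mid-scale 32768 corresponds to 0 V at the input).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RecordLayout",
    "SampleMetadata",
    "ModuleSample",
    "DEFAULT_LAYOUT",
    "METADATA_STRUCT",
]

#: Metadata packing: experiment id (u64), module id (u32), sample index
#: (u32), chip-live mask (u32) -- little-endian, no gaps.
METADATA_STRUCT = struct.Struct("<QIII")

INDEX_MODULUS = 2**32


@dataclass(frozen=True)
class RecordLayout:
    """Byte-level constants of the record format.

    The defaults describe the 1024-channel module: every derived figure
    (data rate, padding fraction, capacity) is computed from these fields,
    never hard-coded downstream.
    """

    meta_bytes: int = 20
    neural_bytes: int = 2048
    aux_bytes: int = 192
    pad_bytes: int = 1836
    block_samples: int = 128
    sample_rate: int = 30_000
    n_chips: int = 32
    channels_per_chip: int = 32
    aux_per_chip: int = 3
    n_gpio: int = 16
    gpio_rate: int = 2_000

    @property
    def record_bytes(self) -> int:
        """Total on-disk size of one sample record, padding included."""
        return self.meta_bytes + self.neural_bytes + self.aux_bytes + self.pad_bytes

    @property
    def block_bytes(self) -> int:
        """Size of one write block (``block_samples`` whole records)."""
        return self.block_samples * self.record_bytes

    @property
    def n_neural(self) -> int:
        return self.n_chips * self.channels_per_chip

    @property
    def n_aux(self) -> int:
        return self.n_chips * self.aux_per_chip

    @property
    def n_channels(self) -> int:
        """Total channel count: neural plus auxiliary."""
        return self.n_neural + self.n_aux

    def validate(self) -> None:
        if self.neural_bytes != 2 * self.n_neural:
            raise ValueError(
                f"neural_bytes={self.neural_bytes} inconsistent with "
                f"{self.n_neural} 16-bit channels"
            )
        if self.aux_bytes != 2 * self.n_aux:
            raise ValueError(
                f"aux_bytes={self.aux_bytes} inconsistent with "
                f"{self.n_aux} 16-bit aux channels"
            )
        if self.pad_bytes < 0:
            raise ValueError("pad_bytes must be non-negative")

    def replace(self, **kwargs) -> "RecordLayout":
        return replace(self, **kwargs)


DEFAULT_LAYOUT = RecordLayout()


@dataclass(frozen=True)
class SampleMetadata:
    """The 20-byte per-sample header.

    Parameters
    ----------
    experiment_id
        Unsigned 64-bit session tag shared by every record of an
        acquisition session; by convention the UNIX UTC time of session
        start.
    module_id
        Unsigned 32-bit module identity (bottom 32 bits of a MAC address).
    sample_index
        Unsigned 32-bit sequential counter; wraps modulo 2**32 (about 39 h
        at 30 kS/s).
    chip_live
        32-bit mask; bit ``i`` set means amplifier chip ``i`` is active and
        its channels carry meaningful data.
    """

    experiment_id: int = 0
    module_id: int = 0
    sample_index: int = 0
    chip_live: int = 0xFFFFFFFF

    def __post_init__(self):
        if not 0 <= self.experiment_id < 2**64:
            raise ValueError("experiment_id out of unsigned 64-bit range")
        for name in ("module_id", "sample_index", "chip_live"):
            v = getattr(self, name)
            if not 0 <= v < 2**32:
                raise ValueError(f"{name} out of unsigned 32-bit range")

    def pack(self) -> bytes:
        return METADATA_STRUCT.pack(
            self.experiment_id, self.module_id, self.sample_index, self.chip_live
        )

    @classmethod
    def unpack(cls, buf: bytes) -> "SampleMetadata":
        eid, mid, idx, live = METADATA_STRUCT.unpack(buf[: METADATA_STRUCT.size])
        return cls(eid, mid, idx, live)

    def chip_is_live(self, chip: int) -> bool:
        return bool((self.chip_live >> chip) & 1)


@dataclass
class ModuleSample:
    """One complete module sample: metadata plus all channel words.

    ``neural`` holds 1024 unsigned 16-bit codes in chip-major order
    (chip 0 channels 0-31, then chip 1, ...); ``aux`` holds 96 codes,
    3 per chip in the same chip order.
    """

    metadata: SampleMetadata = field(default_factory=SampleMetadata)
    neural: np.ndarray = field(
        default_factory=lambda: np.zeros(1024, dtype=np.uint16)
    )
    aux: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.uint16))

    def __post_init__(self):
        self.neural = np.ascontiguousarray(self.neural)
        self.aux = np.ascontiguousarray(self.aux)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModuleSample):
            return NotImplemented
        return (
            self.metadata == other.metadata
            and np.array_equal(self.neural, other.neural)
            and np.array_equal(self.aux, other.aux)
        )
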