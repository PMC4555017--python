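"""Datagram model of the module's Ethernet data plane.

The acquisition module mirrors neural data onto a 1 Gb/s network as UDP
datagrams, either as full-array snapshots (one complete 1024-channel time
point, fragmented across datagrams) or as a continuous stream of selected
channels.  UDP gives no delivery guarantee, so the receiver must tolerate
loss, reordering and duplication; this module models that data plane in
memory: packetization, a Bernoulli loss channel, and gap-reporting
reassembly that never blocks on a missing datagram.

Wire dialect
------------
The on-the-wire payload layout is this package's own versioned convention
(the hardware's UDP payload format is not part of the record format).
All fields little-endian:

====== ====== =====================================
offset size   field
====== ====== =====================================
0      4      magic ``b"NDQ1"`` (version 1)
4      1      mode (0 = SNAPSHOT, 1 = STREAM)
5      1      reserved (0)
6      2      channel_start (u16)
8      2      channel_count (u16)
10     2      fragment_ordinal (u16)
12     2      fragment_total (u16)
14     8      experiment_id (u64)
22     4      module_id (u32)
26     4      sample_index (u32)
30     --     payload: channel_count u16 words
====== ====== =====================================

A serialized packet must fit one standard Ethernet frame after UDP/IP
headers: at most 1472 bytes.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from enum import IntEnum
from typing import BinaryIO, Iterable, Sequence

import numpy as np

from .layout import DEFAULT_LAYOUT, ModuleSample, RecordLayout

__all__ = [
    "PacketMode",
    "DataPacket",
    "GapReport",
    "MAGIC",
    "HEADER_BYTES",
    "MAX_DATAGRAM_BYTES",
    "DEFAULT_WORDS_PER_PACKET",
    "packetize_snapshot",
    "packetize_stream",
    "lossy_channel",
    "reassemble",
    "stream_bandwidth",
    "write_packet_log",
    "read_packet_log",
]

MAGIC = b"NDQ1"
_HEADER = struct.Struct("<4sBBHHHHQII")
HEADER_BYTES = _HEADER.size  # 30
MAX_DATAGRAM_BYTES = 1472  # Ethernet MTU 1500 minus IP (20) and UDP (8) headers
#: Default fragmentation cap, in 16-bit words per datagram.
DEFAULT_WORDS_PER_PACKET = 700


class PacketMode(IntEnum):
    SNAPSHOT = 0
    STREAM = 1


@dataclass(frozen=True, eq=False)
class DataPacket:
    """One datagram of neural data with its reassembly header."""

    mode: PacketMode
    experiment_id: int
    module_id: int
    sample_index: int
    channel_start: int
    fragment_ordinal: int
    fragment_total: int
    payload: np.ndarray  # uint16 words

    def __post_init__(self):
        object.__setattr__(
            self, "payload", np.ascontiguousarray(self.payload, dtype=np.uint16)
        )
        if not self.fragment_ordinal < self.fragment_total:
            raise ValueError("fragment_ordinal must be < fragment_total")
        if HEADER_BYTES + 2 * self.payload.size > MAX_DATAGRAM_BYTES:
            raise ValueError(
                f"packet of {HEADER_BYTES + 2 * self.payload.size} bytes exceeds "
                f"the {MAX_DATAGRAM_BYTES}-byte datagram limit"
            )

    @property
    def channel_count(self) -> int:
        return int(self.payload.size)

    def pack(self) -> bytes:
        header = _HEADER.pack(
            MAGIC,
            int(self.mode),
            0,
            self.channel_start,
            self.channel_count,
            self.fragment_ordinal,
            self.fragment_total,
            self.experiment_id,
            self.module_id,
            self.sample_index,
        )
        return header + self.payload.astype("<u2").tobytes()

    @classmethod
    def unpack(cls, buf: bytes) -> "DataPacket":
        magic, mode, _res, ch_start, ch_count, frag, total, eid, mid, idx = _HEADER.unpack(
            buf[:HEADER_BYTES]
        )
        if magic != MAGIC:
            raise ValueError(f"bad packet magic {magic!r}")
        payload = np.frombuffer(buf, dtype="<u2", count=ch_count, offset=HEADER_BYTES)
        return cls(PacketMode(mode), eid, mid, idx, ch_start, frag, total, payload.copy())

    def key(self) -> tuple:
        return (self.sample_index, self.fragment_ordinal)


def _fragment_bounds(n_words: int, words_per_packet: int) -> list[tuple[int, int]]:
    if words_per_packet < 1:
        raise ValueError("words_per_packet must be >= 1")
    if HEADER_BYTES + 2 * words_per_packet > MAX_DATAGRAM_BYTES:
        raise ValueError(
            f"words_per_packet={words_per_packet} would exceed the datagram limit"
        )
    return [(s, min(s + words_per_packet, n_words)) for s in range(0, n_words, words_per_packet)]


def packetize_snapshot(
    sample: ModuleSample,
    words_per_packet: int = DEFAULT_WORDS_PER_PACKET,
    layout: RecordLayout = DEFAULT_LAYOUT,
) -> list[DataPacket]:
    """Fragment one full-array snapshot into the minimum number of datagrams.

    All fragments carry the same sample index; ``channel_start`` locates
    each fragment within the 1024-channel neural vector.
    """
    bounds = _fragment_bounds(layout.n_neural, words_per_packet)
    total = len(bounds)
    meta = sample.metadata
    return [
        DataPacket(
            PacketMode.SNAPSHOT,
            meta.experiment_id,
            meta.module_id,
            meta.sample_index,
            lo,
            i,
            total,
            sample.neural[lo:hi],
        )
        for i, (lo, hi) in enumerate(bounds)
    ]


def packetize_stream(
    samples: Iterable[ModuleSample],
    channel_ids: Sequence[int],
    words_per_packet: int = DEFAULT_WORDS_PER_PACKET,
    layout: RecordLayout = DEFAULT_LAYOUT,
) -> list[DataPacket]:
    """Packetize selected channels of an ordered sample stream.

    One datagram per sample per fragment of the selection; ``channel_start``
    indexes into the selection list, so the receiver needs the selection to
    map words back to channel ids.
    """
    ids = list(channel_ids)
    if not ids:
        raise ValueError("channel selection must not be empty")
    for cid in ids:
        if not 0 <= cid < layout.n_channels:
            raise ValueError(f"channel id {cid} out of range [0, {layout.n_channels})")
    neural_ids = [c for c in ids if c < layout.n_neural]
    aux_ids = [c - layout.n_neural for c in ids if c >= layout.n_neural]
    order = np.argsort(
        [i for i, c in enumerate(ids) if c < layout.n_neural]
        + [i for i, c in enumerate(ids) if c >= layout.n_neural]
    )
    bounds = _fragment_bounds(len(ids), words_per_packet)
    total = len(bounds)
    packets = []
    for sample in samples:
        values = np.concatenate(
            [sample.neural[neural_ids], sample.aux[aux_ids]]
        )[order]
        meta = sample.metadata
        for i, (lo, hi) in enumerate(bounds):
            packets.append(
                DataPacket(
                    PacketMode.STREAM,
                    meta.experiment_id,
                    meta.module_id,
                    meta.sample_index,
                    lo,
                    i,
                    total,
                    values[lo:hi],
                )
            )
    return packets


def lossy_channel(
    packets: Iterable[DataPacket], loss_prob: float, seed
) -> list[DataPacket]:
    """Drop each datagram independently with probability ``loss_prob``.

    Models best-effort delivery: no retransmission, no ordering guarantee
    is added or removed here, just Bernoulli erasure, deterministic per
    seed.
    """
    if not 0.0 <= loss_prob <= 1.0:
        raise ValueError("loss_prob must be in [0, 1]")
    packets = list(packets)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(packets)) >= loss_prob
    return [p for p, k in zip(packets, keep) if k]


@dataclass
class GapReport:
    """What the receiver knows it did not get."""

    missing_fragments: list[tuple[int, int]] = field(default_factory=list)  # (sample_index, fragment)
    missing_samples: list[int] = field(default_factory=list)  # sample_index entirely absent
    duplicates: int = 0

    def total_missing(self, fragments_per_sample: int = 1) -> int:
        """Datagram count lost, counting wholly missing samples at the given fragmentation."""
        return len(self.missing_fragments) + len(self.missing_samples) * fragments_per_sample


def reassemble(packets: Iterable[DataPacket]) -> tuple[dict[int, np.ndarray], GapReport]:
    """Rebuild per-sample channel vectors from surviving datagrams.

    Out-of-order and duplicate tolerant; never blocks on loss.  Returns a
    mapping from sample index to the reassembled word vector (missing
    words left as zeros) and a :class:`GapReport` enumerating missing
    fragments and, for sample indices inside the observed contiguous
    range with no surviving fragment at all, missing samples.
    """
    by_sample: dict[int, dict[int, DataPacket]] = {}
    report = GapReport()
    for p in packets:
        frags = by_sample.setdefault(p.sample_index, {})
        if p.fragment_ordinal in frags:
            report.duplicates += 1
            continue
        frags[p.fragment_ordinal] = p
    data: dict[int, np.ndarray] = {}
    for idx in sorted(by_sample):
        frags = by_sample[idx]
        total = max(p.fragment_total for p in frags.values())
        last = max(frags.values(), key=lambda p: p.fragment_ordinal)
        if last.fragment_ordinal == total - 1:
            full = last.channel_start + last.channel_count
        else:
            # final fragment lost: assume the uniform fragment stride
            stride = next(iter(frags.values())).channel_count
            full = max(
                stride * total,
                max(p.channel_start + p.channel_count for p in frags.values()),
            )
        vec = np.zeros(full, dtype=np.uint16)
        for i in range(total):
            if i in frags:
                p = frags[i]
                vec[p.channel_start : p.channel_start + p.channel_count] = p.payload
            else:
                report.missing_fragments.append((idx, i))
        data[idx] = vec
    if by_sample:
        seen = sorted(by_sample)
        expect = set(range(seen[0], seen[-1] + 1))
        report.missing_samples = sorted(expect - set(seen))
    return data, report


def stream_bandwidth(
    channel_count: int,
    sample_rate: int = 30_000,
    words_per_packet: int = DEFAULT_WORDS_PER_PACKET,
) -> float:
    """Bits/s on the wire for a channel selection, header overhead included.

    Used to check that a selection fits a 1 Gb/s link: payload bits plus
    per-datagram header bits at the chosen fragmentation.
    """
    if channel_count == 0:
        return 0.0
    n_packets = -(-channel_count // words_per_packet)  # ceil
    bytes_per_sample = 2 * channel_count + HEADER_BYTES * n_packets
    return bytes_per_sample * 8 * sample_rate


def write_packet_log(packets: Iterable[DataPacket], sink: BinaryIO) -> int:
    """Length-prefixed packet capture: u32 length then packet bytes, repeated."""
    n = 0
    for p in packets:
        raw = p.pack()
        sink.write(struct.pack("<I", len(raw)))
        sink.write(raw)
        n += 1
    return n


def read_packet_log(source: BinaryIO) -> list[DataPacket]:
    packets = []
    while True:
        head = source.read(4)
        if not head:
            return packets
        (length,) = struct.unpack("<I", head)
        packets.append(DataPacket.unpack(source.read(length)))
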