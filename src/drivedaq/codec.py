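"""Exact byte-level codec and random access for raw session streams.

The session file is nothing but back-to-back 4096-byte records; fixed-size
records make O(1) random access trivial (``seek_sample``) and let the
reader stream with constant memory (``read_session``).
"""

from __future__ import annotations

import io
import json
import os
import warnings
from dataclasses import dataclass
from typing import BinaryIO, Iterable, Iterator, Sequence

import numpy as np

from .layout import (
    DEFAULT_LAYOUT,
    INDEX_MODULUS,
    METADATA_STRUCT,
    ModuleSample,
    RecordLayout,
    SampleMetadata,
)

__all__ = [
    "CodecError",
    "SizeError",
    "RangeError",
    "CorruptionError",
    "ConsistencyError",
    "TruncatedSessionWarning",
    "encode_sample",
    "decode_sample",
    "SessionWriter",
    "write_session",
    "read_session",
    "count_records",
    "seek_sample",
    "unwrap_indices",
    "ChannelMatrix",
    "extract_channels",
    "export_channels_csv",
    "export_channels_binary",
]


class CodecError(Exception):
    """Base class for codec failures."""


class SizeError(CodecError):
    """A buffer or section has the wrong length."""


class RangeError(CodecError, ValueError):
    """A value does not fit its field."""


class CorruptionError(CodecError):
    """Record content violates the format (e.g. nonzero padding)."""


class ConsistencyError(CodecError):
    """Session-level contract violated (e.g. identifier change mid-stream)."""


class TruncatedSessionWarning(UserWarning):
    """A session source ended with a partial (<4096 B) record."""


def encode_sample(
    sample: ModuleSample, layout: RecordLayout = DEFAULT_LAYOUT
) -> bytes:
    """Encode one sample to its fixed-size on-disk record.

    Layout: metadata (20 B) || neural (2048 B) || aux (192 B) || zero
    padding (1836 B), all little-endian.  Deterministic; inverse of
    :func:`decode_sample`.
    """
    neural = np.asarray(sample.neural)
    aux = np.asarray(sample.aux)
    if neural.shape != (layout.n_neural,):
        raise SizeError(
            f"neural section has {neural.size} entries, expected {layout.n_neural}"
        )
    if aux.shape != (layout.n_aux,):
        raise SizeError(
            f"aux section has {aux.size} entries, expected {layout.n_aux}"
        )
    for name, arr in (("neural", neural), ("aux", aux)):
        if arr.dtype != np.uint16:
            if np.any((arr < 0) | (arr > 0xFFFF)):
                raise RangeError(f"{name} values out of 16-bit range")
            arr = arr.astype(np.uint16)
        if name == "neural":
            neural = arr
        else:
            aux = arr
    record = bytearray(layout.record_bytes)
    record[: layout.meta_bytes] = sample.metadata.pack()
    off = layout.meta_bytes
    record[off : off + layout.neural_bytes] = neural.astype("<u2").tobytes()
    off += layout.neural_bytes
    record[off : off + layout.aux_bytes] = aux.astype("<u2").tobytes()
    return bytes(record)


def decode_sample(
    record: bytes,
    layout: RecordLayout = DEFAULT_LAYOUT,
    strict_padding: bool = False,
) -> ModuleSample:
    """Decode one fixed-size record back into a :class:`ModuleSample`.

    With ``strict_padding`` any nonzero byte in the padding region raises
    :class:`CorruptionError`; otherwise padding content is ignored.
    """
    if len(record) != layout.record_bytes:
        raise SizeError(
            f"record is {len(record)} bytes, expected {layout.record_bytes}"
        )
    meta = SampleMetadata.unpack(record)
    off = layout.meta_bytes
    neural = np.frombuffer(
        record, dtype="<u2", count=layout.n_neural, offset=off
    ).astype(np.uint16)
    off += layout.neural_bytes
    aux = np.frombuffer(
        record, dtype="<u2", count=layout.n_aux, offset=off
    ).astype(np.uint16)
    off += layout.aux_bytes
    if strict_padding and any(record[off:]):
        bad = next(i for i, b in enumerate(record[off:]) if b)
        raise CorruptionError(f"nonzero padding byte at record offset {off + bad}")
    return ModuleSample(meta, neural, aux)


class SessionWriter:
    """Block-buffered writer for a raw session stream.

    Records are emitted to the sink only in whole write blocks
    (``block_samples`` records, 512 KiB by default), mirroring the
    hardware's block-granular drive writes.  Trailing records that do not
    fill a block are buffered and flushed as a final short block on
    :meth:`close`.
    """

    def __init__(self, sink: BinaryIO, layout: RecordLayout = DEFAULT_LAYOUT):
        self._sink = sink
        self._layout = layout
        self._buffer: list[bytes] = []
        self._ids: tuple[int, int] | None = None
        self.samples_written = 0  # durable (flushed) samples
        self._closed = False

    def write(self, sample: ModuleSample) -> None:
        if self._closed:
            raise ValueError("writer is closed")
        ids = (sample.metadata.experiment_id, sample.metadata.module_id)
        if self._ids is None:
            self._ids = ids
        elif ids != self._ids:
            raise ConsistencyError(
                f"experiment/module identifiers changed mid-session: "
                f"{self._ids} -> {ids}"
            )
        self._buffer.append(encode_sample(sample, self._layout))
        if len(self._buffer) == self._layout.block_samples:
            self._flush_block()

    def _flush_block(self) -> None:
        block = b"".join(self._buffer)
        n = len(self._buffer)
        self._buffer.clear()
        try:
            self._sink.write(block)
        except OSError as exc:
            raise IOError(
                f"sink failure after {self.samples_written} durable samples"
            ) from exc
        self.samples_written += n

    def close(self) -> int:
        """Flush any buffered partial block; return total samples written."""
        if not self._closed:
            if self._buffer:
                self._flush_block()
            self._closed = True
        return self.samples_written

    def __enter__(self) -> "SessionWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_session(
    samples: Iterable[ModuleSample],
    sink: BinaryIO,
    layout: RecordLayout = DEFAULT_LAYOUT,
) -> int:
    """Write an ordered sample source to ``sink``; return the count written.

    All samples must share experiment and module identifiers
    (:class:`ConsistencyError` otherwise).  The byte stream contains no
    headers or separators -- it is the format.
    """
    with SessionWriter(sink, layout) as w:
        for s in samples:
            w.write(s)
        return w.close()


def _open_source(source) -> tuple[BinaryIO, bool]:
    if isinstance(source, (str, os.PathLike)):
        return open(source, "rb"), True
    if isinstance(source, (bytes, bytearray, memoryview)):
        return io.BytesIO(source), True
    return source, False


def read_session(
    source,
    layout: RecordLayout = DEFAULT_LAYOUT,
    strict_padding: bool = False,
) -> Iterator[ModuleSample]:
    """Lazily yield samples from a path, bytes, or binary file object.

    Memory use is constant in session length.  A trailing remainder
    shorter than one record is reported via
    :class:`TruncatedSessionWarning` and skipped.
    """
    fh, should_close = _open_source(source)
    try:
        while True:
            record = fh.read(layout.record_bytes)
            if not record:
                return
            if len(record) < layout.record_bytes:
                warnings.warn(
                    f"session ends with a {len(record)}-byte partial record; "
                    "skipped",
                    TruncatedSessionWarning,
                    stacklevel=2,
                )
                return
            yield decode_sample(record, layout, strict_padding=strict_padding)
    finally:
        if should_close:
            fh.close()


def count_records(source, layout: RecordLayout = DEFAULT_LAYOUT) -> int:
    """Number of whole records in a session source (floor(bytes/4096))."""
    if isinstance(source, (str, os.PathLike)):
        n_bytes = os.path.getsize(source)
    elif isinstance(source, (bytes, bytearray, memoryview)):
        n_bytes = len(source)
    else:
        pos = source.tell()
        source.seek(0, os.SEEK_END)
        n_bytes = source.tell()
        source.seek(pos)
    return n_bytes // layout.record_bytes


def seek_sample(
    source, k: int, layout: RecordLayout = DEFAULT_LAYOUT
) -> ModuleSample:
    """Random-access the k-th sample of a session in O(1).

    Equivalent to the k-th element of :func:`read_session`.
    """
    n = count_records(source, layout)
    if not 0 <= k < n:
        raise IndexError(f"sample ordinal {k} out of range [0, {n})")
    fh, should_close = _open_source(source)
    try:
        fh.seek(k * layout.record_bytes)
        return decode_sample(fh.read(layout.record_bytes), layout)
    finally:
        if should_close:
            fh.close()


def unwrap_indices(indices: Sequence[int] | np.ndarray) -> np.ndarray:
    """Unwrap 32-bit sample counters into a monotone 64-bit sequence.

    The raw counter wraps to zero modulo 2**32 (about every 39 h at
    30 kS/s); a wrap is detected whenever a raw index is smaller than its
    predecessor and 2**32 is added cumulatively.

    Examples
    --------
    >>> unwrap_indices([4294967294, 4294967295, 0, 1]).tolist()
    [4294967294, 4294967295, 4294967296, 4294967297]
    """
    raw = np.asarray(indices, dtype=np.uint64)
    if raw.size == 0:
        return raw.astype(np.uint64)
    wraps = np.zeros(raw.size, dtype=np.uint64)
    wraps[1:] = np.cumsum(raw[1:] < raw[:-1]).astype(np.uint64)
    return raw + wraps * np.uint64(INDEX_MODULUS)


@dataclass
class ChannelMatrix:
    """Channel extraction result.

    ``data[i, j]`` is the raw 16-bit code of ``channel_ids[j]`` at the
    sample with unwrapped index ``index[i]``.  ``analyzable[j]`` is False
    when the channel belongs to a chip whose chip-live bit was clear in any
    sample -- such channels should be ignored, not interpreted.
    """

    index: np.ndarray  # (n_samples,) uint64, unwrapped
    channel_ids: list[int]
    data: np.ndarray  # (n_samples, n_channels) uint16
    analyzable: np.ndarray  # (n_channels,) bool
    experiment_id: int = 0
    module_id: int = 0


def channel_chip(channel_id: int, layout: RecordLayout = DEFAULT_LAYOUT) -> int:
    """Owning amplifier chip of a global channel id (neural or aux)."""
    if channel_id < layout.n_neural:
        return channel_id // layout.channels_per_chip
    return (channel_id - layout.n_neural) // layout.aux_per_chip


def extract_channels(
    source,
    channel_ids: Sequence[int],
    layout: RecordLayout = DEFAULT_LAYOUT,
) -> ChannelMatrix:
    """Extract selected channels across an entire session.

    Channel ids are 0-based and chip-major: 0..1023 are neural, 1024..1119
    auxiliary.  Rows are ordered by unwrapped sample index.
    """
    ids = list(channel_ids)
    for cid in ids:
        if not 0 <= cid < layout.n_channels:
            raise RangeError(
                f"channel id {cid} out of range [0, {layout.n_channels})"
            )
    raw_idx: list[int] = []
    rows: list[np.ndarray] = []
    live_mask = np.uint32(0xFFFFFFFF)
    eid = mid = 0
    neural_ids = [c for c in ids if c < layout.n_neural]
    aux_ids = [c - layout.n_neural for c in ids if c >= layout.n_neural]
    order = [i for i, c in enumerate(ids) if c < layout.n_neural] + [
        i for i, c in enumerate(ids) if c >= layout.n_neural
    ]
    for sample in read_session(source, layout):
        raw_idx.append(sample.metadata.sample_index)
        row = np.empty(len(ids), dtype=np.uint16)
        vals = np.concatenate(
            [sample.neural[neural_ids], sample.aux[aux_ids]]
        ) if ids else np.empty(0, dtype=np.uint16)
        row[order] = vals
        rows.append(row)
        live_mask &= np.uint32(sample.metadata.chip_live)
        eid, mid = sample.metadata.experiment_id, sample.metadata.module_id
    analyzable = np.array(
        [bool((int(live_mask) >> channel_chip(c, layout)) & 1) for c in ids],
        dtype=bool,
    )
    data = (
        np.vstack(rows) if rows else np.empty((0, len(ids)), dtype=np.uint16)
    )
    return ChannelMatrix(
        index=unwrap_indices(raw_idx),
        channel_ids=ids,
        data=data,
        analyzable=analyzable,
        experiment_id=eid,
        module_id=mid,
    )


def export_channels_csv(matrix: ChannelMatrix, path) -> None:
    """Write a ChannelMatrix as delimited text with an index column."""
    header = "index," + ",".join(f"ch{c}" for c in matrix.channel_ids)
    table = np.column_stack(
        [matrix.index.astype(np.uint64), matrix.data.astype(np.uint64)]
    )
    np.savetxt(path, table, fmt="%d", delimiter=",", header=header, comments="")


def export_channels_binary(matrix: ChannelMatrix, directory) -> None:
    """Write one flat little-endian 16-bit file per channel plus a JSON sidecar."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    for j, cid in enumerate(matrix.channel_ids):
        matrix.data[:, j].astype("<u2").tofile(
            os.path.join(directory, f"channel_{cid:04d}.i16")
        )
    sidecar = {
        "experiment_id": matrix.experiment_id,
        "module_id": matrix.module_id,
        "n_samples": int(matrix.index.size),
        "first_index": int(matrix.index[0]) if matrix.index.size else None,
        "channels": [
            {"id": int(c), "analyzable": bool(a)}
            for c, a in zip(matrix.channel_ids, matrix.analyzable)
        ],
        "dtype": "uint16-le",
    }
    with open(os.path.join(directory, "session.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
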