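"""Post-acquisition integrity checks for stored session streams.

Re-implements the offline validation procedure run after an experiment:
confirm the hardware and experiment identifiers never change, the sample
index increments by exactly one (modulo 2**32, so a counter rollover is
not a skip), the padding region is all zeros, and the amount of data on
disk matches the expected storage size.  Validation is a single streaming
pass with constant memory, and it continues past the first error so a
damaged session yields a full error census rather than one failure.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .codec import _open_source
from .layout import DEFAULT_LAYOUT, INDEX_MODULUS, RecordLayout, SampleMetadata

__all__ = ["FaultKind", "ValidationError", "ValidationReport", "validate_session", "summarize", "diff_sessions"]


class FaultKind(str, Enum):
    ID_CHANGE = "ID_CHANGE"
    INDEX_SKIP = "INDEX_SKIP"
    INDEX_REPEAT = "INDEX_REPEAT"
    NONZERO_PADDING = "NONZERO_PADDING"
    TRUNCATED_TAIL = "TRUNCATED_TAIL"
    SIZE_MISMATCH = "SIZE_MISMATCH"


@dataclass
class ValidationError:
    kind: FaultKind
    record_ordinal: int
    detail: str

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "record_ordinal": self.record_ordinal,
            "detail": self.detail,
        }


@dataclass
class ValidationReport:
    """Structured outcome of a session integrity check."""

    n_records: int = 0
    first_index_raw: Optional[int] = None
    last_index_raw: Optional[int] = None
    first_index_unwrapped: Optional[int] = None
    last_index_unwrapped: Optional[int] = None
    experiment_id: Optional[int] = None
    module_id: Optional[int] = None
    errors: list[ValidationError] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "n_records": self.n_records,
            "first_index_raw": self.first_index_raw,
            "last_index_raw": self.last_index_raw,
            "first_index_unwrapped": self.first_index_unwrapped,
            "last_index_unwrapped": self.last_index_unwrapped,
            "experiment_id": self.experiment_id,
            "module_id": self.module_id,
            "n_errors": len(self.errors),
            "errors": [e.to_dict() for e in self.errors],
        }


def validate_session(
    source,
    expected_bytes: Optional[int] = None,
    layout: RecordLayout = DEFAULT_LAYOUT,
    allow_chip_live_change: bool = False,
) -> ValidationReport:
    """Single-pass integrity check of a raw session stream.

    Checks, per record: constant experiment/module identifiers (and, by
    default, constant chip-live mask), sample index incrementing by
    exactly 1 modulo 2**32 (a repeat and a skip are distinct error
    kinds), and all-zero padding.  A trailing remainder shorter than one
    record is a TRUNCATED_TAIL error; if ``expected_bytes`` is given, a
    whole-record count disagreeing with it is a SIZE_MISMATCH.

    An unreadable source raises ``OSError`` -- that is an I/O failure,
    not a failed report.
    """
    report = ValidationReport()
    fh, should_close = _open_source(source)
    rec = layout.record_bytes
    pad_off = layout.meta_bytes + layout.neural_bytes + layout.aux_bytes
    prev_idx = None
    chip_live_ref = None
    unwrapped = None
    try:
        ordinal = 0
        while True:
            record = fh.read(rec)
            if not record:
                break
            if len(record) < rec:
                report.errors.append(
                    ValidationError(
                        FaultKind.TRUNCATED_TAIL,
                        ordinal,
                        f"trailing remainder of {len(record)} bytes (< {rec})",
                    )
                )
                break
            meta = SampleMetadata.unpack(record)
            if ordinal == 0:
                report.experiment_id = meta.experiment_id
                report.module_id = meta.module_id
                report.first_index_raw = meta.sample_index
                chip_live_ref = meta.chip_live
                unwrapped = meta.sample_index
            else:
                if meta.experiment_id != report.experiment_id:
                    report.errors.append(
                        ValidationError(
                            FaultKind.ID_CHANGE,
                            ordinal,
                            f"experiment_id {report.experiment_id} -> {meta.experiment_id}",
                        )
                    )
                if meta.module_id != report.module_id:
                    report.errors.append(
                        ValidationError(
                            FaultKind.ID_CHANGE,
                            ordinal,
                            f"module_id {report.module_id} -> {meta.module_id}",
                        )
                    )
                if not allow_chip_live_change and meta.chip_live != chip_live_ref:
                    report.errors.append(
                        ValidationError(
                            FaultKind.ID_CHANGE,
                            ordinal,
                            f"chip_live {chip_live_ref:#010x} -> {meta.chip_live:#010x}",
                        )
                    )
                delta = (meta.sample_index - prev_idx) % INDEX_MODULUS
                if delta == 0:
                    report.errors.append(
                        ValidationError(
                            FaultKind.INDEX_REPEAT,
                            ordinal,
                            f"index {meta.sample_index} repeated",
                        )
                    )
                elif delta != 1:
                    expected = (prev_idx + 1) % INDEX_MODULUS
                    report.errors.append(
                        ValidationError(
                            FaultKind.INDEX_SKIP,
                            ordinal,
                            f"expected {expected}, found {meta.sample_index} "
                            f"(skipped {delta - 1})",
                        )
                    )
                unwrapped += delta
            if any(record[pad_off:]):
                report.errors.append(
                    ValidationError(
                        FaultKind.NONZERO_PADDING,
                        ordinal,
                        "nonzero byte in padding region",
                    )
                )
            prev_idx = meta.sample_index
            report.last_index_raw = meta.sample_index
            ordinal += 1
        report.n_records = ordinal
        if report.first_index_raw is not None:
            report.first_index_unwrapped = report.first_index_raw
            report.last_index_unwrapped = int(unwrapped)
        if expected_bytes is not None and expected_bytes // rec != report.n_records:
            report.errors.append(
                ValidationError(
                    FaultKind.SIZE_MISMATCH,
                    report.n_records,
                    f"{report.n_records} records found, expected "
                    f"{expected_bytes // rec} from {expected_bytes} bytes",
                )
            )
    finally:
        if should_close:
            fh.close()
    return report


def summarize(report: ValidationReport, as_json: bool = False) -> str:
    """Human-readable or JSON rendering of a report.

    Exit-code convention for callers: 0 pass, 1 fail, 2 I/O error.
    """
    if as_json:
        return json.dumps(report.to_dict(), indent=2)
    lines = [
        f"records:        {report.n_records}",
        f"experiment_id:  {report.experiment_id}",
        f"module_id:      {report.module_id}",
        f"index range:    {report.first_index_raw} .. {report.last_index_raw} (raw)",
        f"                {report.first_index_unwrapped} .. {report.last_index_unwrapped} (unwrapped)",
        f"result:         {'PASS' if report.passed else f'FAIL ({len(report.errors)} errors)'}",
    ]
    for e in report.errors[:50]:
        lines.append(f"  [{e.kind.value}] record {e.record_ordinal}: {e.detail}")
    if len(report.errors) > 50:
        lines.append(f"  ... and {len(report.errors) - 50} more")
    return "\n".join(lines)


def diff_sessions(a, b, layout: RecordLayout = DEFAULT_LAYOUT):
    """Byte-exact comparison of two sessions at record granularity.

    Returns ``None`` when the sessions are identical, else the ordinal of
    the first divergent record; length differences report the shorter
    session's record count.
    """
    fa, close_a = _open_source(a)
    fb, close_b = _open_source(b)
    rec = layout.record_bytes
    try:
        k = 0
        while True:
            ra = fa.read(rec)
            rb = fb.read(rec)
            if not ra and not rb:
                return None
            if len(ra) != len(rb) or not ra or not rb:
                return k
            if ra != rb:
                return k
            k += 1
    finally:
        if close_a:
            fa.close()
        if close_b:
            fb.close()
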