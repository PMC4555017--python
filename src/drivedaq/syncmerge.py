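"""Multi-module timing simulation and combined-session reconstruction.

Scaling beyond 1024 channels means running several acquisition modules in
parallel and recombining their sessions offline.  Two timing questions
follow:

* **Clock skew.**  Each module has its own crystal with a frequency error
  of tens of ppm.  Free-running modules drift apart linearly (50 ppm over
  30 min is 90 ms — thousands of sample periods), while distributing a
  shared sample-start pulse to every module at each 30 kHz tick bounds the
  skew by latch delay differences plus jitter, well within one 33.3 µs
  sample period.  :func:`simulate_timestamps` models three schemes:
  per-sample pulses (PULSED), a single shared start edge (START_ONLY), and
  fully free-running clocks (FREE).

* **Alignment.**  Offline, per-module sessions are merged on the key
  (experiment id, unwrapped sample index); a sample missing from one
  module produces an explicit gap marker, never a silent misalignment.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .codec import read_session, unwrap_indices
from .layout import DEFAULT_LAYOUT, RecordLayout

__all__ = [
    "ModuleClock",
    "SyncMode",
    "simulate_timestamps",
    "max_skew",
    "MergedSession",
    "merge_sessions",
    "write_merged",
]


@dataclass(frozen=True)
class ModuleClock:
    """One module's sampling clock model.

    drift_ppm is the fractional frequency error in parts per million
    (|drift| < 1000 keeps the model in the crystal-oscillator regime);
    jitter_s is the per-edge timing noise standard deviation; latch_delay_s
    a fixed pulse-to-sample latency.
    """

    nominal_rate: float = 30_000.0
    drift_ppm: float = 0.0
    jitter_s: float = 0.0
    latch_delay_s: float = 0.0

    def __post_init__(self):
        if abs(self.drift_ppm) >= 1000:
            raise ValueError("drift_ppm out of crystal-oscillator range (|d| < 1000)")
        if self.jitter_s < 0:
            raise ValueError("jitter_s must be >= 0")


class SyncMode(str, Enum):
    PULSED = "PULSED"  # shared pulse at every sample tick: drift cannot accumulate
    START_ONLY = "START_ONLY"  # shared start edge, then free-running
    FREE = "FREE"  # independent clocks: drift accumulates linearly


def simulate_timestamps(
    clocks: Sequence[ModuleClock],
    n_samples: int,
    mode: SyncMode | str = SyncMode.PULSED,
    seed=0,
    ordinals: np.ndarray | None = None,
) -> np.ndarray:
    """Per-module sample acquisition times, shape (n_modules, n_ordinals).

    PULSED: sample k of every module fires at the shared pulse time
    ``k / nominal_rate`` plus that module's latch delay and jitter; the
    module's own frequency error never accumulates.  FREE and START_ONLY:
    sample k fires at ``k / (rate * (1 + drift))`` plus delay and jitter,
    so a drift difference ``d`` between two modules opens a skew of
    ``d * elapsed_time`` (90 ms after 30 min at 50 ppm).

    ``ordinals`` selects which sample ordinals to evaluate (default: all of
    ``0..n_samples-1``); long recordings can be probed on a decimated grid
    without materializing every tick.
    """
    if not clocks:
        raise ValueError("at least one module clock is required")
    mode = SyncMode(mode)
    rng = np.random.default_rng(seed)
    if ordinals is None:
        k = np.arange(n_samples, dtype=np.float64)
    else:
        k = np.asarray(ordinals, dtype=np.float64)
        if k.size and (k.min() < 0 or k.max() >= n_samples):
            raise ValueError("ordinals outside [0, n_samples)")
    out = np.empty((len(clocks), k.size), dtype=np.float64)
    for m, clk in enumerate(clocks):
        if mode is SyncMode.PULSED:
            base = k / clk.nominal_rate
        else:
            base = k / (clk.nominal_rate * (1.0 + clk.drift_ppm * 1e-6))
        t = base + clk.latch_delay_s
        if clk.jitter_s > 0:
            t = t + rng.normal(0.0, clk.jitter_s, size=k.size)
        out[m] = t
    return out


def max_skew(timestamps: np.ndarray) -> np.ndarray:
    """Max pairwise timing difference per sample ordinal (max minus min)."""
    ts = np.asarray(timestamps, dtype=np.float64)
    if ts.ndim != 2:
        raise ValueError("expected a (n_modules, n_samples) matrix")
    return ts.max(axis=0) - ts.min(axis=0)


@dataclass
class MergedSession:
    """A combined multi-module dataset aligned on unwrapped sample index.

    ``data[i]`` concatenates, module-major, all neural channels then all
    auxiliary channels for the sample with unwrapped index ``index[i]``:
    columns ``[0, 1024*n)`` are neural (module 0 first), columns
    ``[1024*n, 1120*n)`` auxiliary.  ``present[i, m]`` is False where
    module ``m`` had no record at that index; the corresponding words are
    zero-filled and must not be interpreted.
    """

    experiment_id: int
    module_ids: list[int]
    index: np.ndarray  # (n_rows,) uint64
    data: np.ndarray  # (n_rows, n_modules * 1120) uint16
    present: np.ndarray  # (n_rows, n_modules) bool

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)

    @property
    def complete(self) -> bool:
        return bool(self.present.all())


def merge_sessions(
    sessions: Sequence, layout: RecordLayout = DEFAULT_LAYOUT
) -> MergedSession:
    """Reconstruct a combined dataset from per-module session sources.

    All sessions must share an experiment id (a mix of sessions is
    refused) and carry pairwise distinct module ids.  Rows cover the union
    of the modules' unwrapped index ranges; a module missing a given index
    contributes a gap marker.
    """
    if not sessions:
        raise ValueError("at least one session is required")
    per_module = []
    for src in sessions:
        raw_idx, neural_rows, aux_rows = [], [], []
        eid = mid = None
        for s in read_session(src, layout):
            if eid is None:
                eid, mid = s.metadata.experiment_id, s.metadata.module_id
            raw_idx.append(s.metadata.sample_index)
            neural_rows.append(s.neural)
            aux_rows.append(s.aux)
        if eid is None:
            raise ValueError("empty session source")
        per_module.append(
            (
                eid,
                mid,
                unwrap_indices(raw_idx),
                np.vstack(neural_rows),
                np.vstack(aux_rows),
            )
        )
    eids = {m[0] for m in per_module}
    if len(eids) != 1:
        raise ValueError(f"sessions mix experiment ids: {sorted(eids)}")
    mids = [m[1] for m in per_module]
    if len(set(mids)) != len(mids):
        raise ValueError(f"duplicate module ids: {mids}")
    all_idx = np.unique(np.concatenate([m[2] for m in per_module]))
    n_rows, n_mod = all_idx.size, len(per_module)
    data = np.zeros((n_rows, n_mod * layout.n_channels), dtype=np.uint16)
    present = np.zeros((n_rows, n_mod), dtype=bool)
    neural_width = n_mod * layout.n_neural
    for m, (_eid, _mid, idx, neural, aux) in enumerate(per_module):
        rows = np.searchsorted(all_idx, idx)
        present[rows, m] = True
        n0 = m * layout.n_neural
        a0 = neural_width + m * layout.n_aux
        data[rows, n0 : n0 + layout.n_neural] = neural
        data[rows, a0 : a0 + layout.n_aux] = aux
    return MergedSession(
        experiment_id=per_module[0][0],
        module_ids=mids,
        index=all_idx,
        data=data,
        present=present,
    )


def write_merged(merged: MergedSession, out_prefix) -> None:
    """Persist a merged dataset: flat 16-bit matrix + JSON metadata sidecar.

    ``<prefix>.u16`` holds the row-major (sample x channel) little-endian
    matrix; ``<prefix>.json`` describes shape, module order, index range
    and per-row presence.
    """
    prefix = os.fspath(out_prefix)
    merged.data.astype("<u2").tofile(prefix + ".u16")
    sidecar = {
        "experiment_id": merged.experiment_id,
        "module_ids": merged.module_ids,
        "n_rows": int(merged.index.size),
        "n_columns": int(merged.data.shape[1]),
        "column_order": "module-major: all neural blocks, then all aux blocks",
        "first_index": int(merged.index[0]),
        "last_index": int(merged.index[-1]),
        "complete": merged.complete,
        "gaps": [
            {"index": int(merged.index[i]), "missing_modules": [
                merged.module_ids[m] for m in np.flatnonzero(~merged.present[i])
            ]}
            for i in np.flatnonzero(~merged.present.all(axis=1))
        ],
        "dtype": "uint16-le",
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
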