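"""Small signal-analysis helpers used to check simulated sessions.

These mirror the offline checks an experimenter would run on downloaded
data: measure the noise floor in the spike band and count threshold
crossings.  The 600-9700 Hz band-pass is a measurement filter applied
here in analysis only, never during generation.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal

__all__ = ["bandpass", "rms", "detect_spikes"]


def bandpass(
    x: np.ndarray,
    sample_rate: int = 30_000,
    low_hz: float = 600.0,
    high_hz: float = 9_700.0,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass over the spike band."""
    sos = _signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=sample_rate, output="sos"
    )
    return _signal.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=0)


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude."""
    x = np.asarray(x, dtype=np.float64)
    return float(np.sqrt(np.mean(x * x)))


def detect_spikes(
    x_uv: np.ndarray,
    threshold_uv: float,
    sample_rate: int = 30_000,
    refractory_ms: float = 1.0,
) -> np.ndarray:
    """Sample indices of negative threshold crossings.

    A crossing is the first sample where the trace drops below
    ``-threshold_uv``; further crossings within the refractory window are
    merged into the same event (extracellular spikes are negative-going at
    the nearest site).
    """
    x = np.asarray(x_uv, dtype=np.float64)
    below = x < -abs(threshold_uv)
    onsets = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below.size and below[0]:
        onsets = np.concatenate([[0], onsets])
    if onsets.size == 0:
        return onsets
    refractory = max(1, int(round(refractory_ms * 1e-3 * sample_rate)))
    keep = [int(onsets[0])]
    for s in onsets[1:]:
        if s - keep[-1] >= refractory:
            keep.append(int(s))
    return np.array(keep, dtype=np.int64)
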