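"""Zero-phase filtering and sensor-specific cleaning.

All filters are fourth-order bidirectional (zero-phase) Butterworth filters
unless configured otherwise.  Edge transients are bounded by odd signal
extension at both ends (the scipy ``filtfilt`` convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._errors import ParameterError


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter: ``kind`` lowpass or bandpass, cutoffs in Hz."""

    kind: str = "lowpass"
    cutoffs: tuple = (6.0,)
    order: int = 4
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        cut = tuple(float(c) for c in self.cutoffs)
        if self.kind == "lowpass" and len(cut) != 1:
            raise ParameterError("lowpass takes exactly one cutoff")
        if self.kind == "bandpass" and len(cut) != 2:
            raise ParameterError("bandpass takes exactly two cutoffs")
        if any(c <= 0 for c in cut):
            raise ParameterError("cutoffs must be positive")
        object.__setattr__(self, "cutoffs", cut)


def butter_filter(x: np.ndarray, rate_hz: float, spec: FilterSpec) -> np.ndarray:
    """Apply ``spec`` to a uniformly sampled signal; same length out, zero phase."""
    x = np.asarray(x, dtype=float)
    nyq = rate_hz / 2.0
    if max(spec.cutoffs) >= nyq:
        raise ParameterError(
            f"cutoff {max(spec.cutoffs)} Hz >= Nyquist {nyq} Hz at rate {rate_hz} Hz"
        )
    btype = "low" if spec.kind == "lowpass" else "bandpass"
    wn = spec.cutoffs[0] / nyq if spec.kind == "lowpass" else [c / nyq for c in spec.cutoffs]
    sos = sps.butter(spec.order, wn, btype=btype, output="sos")
    if spec.bidirectional:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def emg_envelope(x: np.ndarray, rate_hz: float, reference_max: float,
                 band=(30.0, 500.0), envelope_cutoff: float = 6.0,
                 order: int = 4) -> np.ndarray:
    """Linear envelope of a raw EMG signal.

    Pipeline, in this exact order: band-pass (default 30–500 Hz) → full-wave
    rectification → low-pass (default 6 Hz) → division by ``reference_max``
    (the envelope maximum from a designated reference condition).
    """
    if reference_max <= 0:
        raise ParameterError("reference_max must be positive")
    banded = butter_filter(x, rate_hz, FilterSpec("bandpass", band, order))
    rectified = np.abs(banded)
    enveloped = butter_filter(rectified, rate_hz, FilterSpec("lowpass", (envelope_cutoff,), order))
    return enveloped / reference_max


def insole_clean(force: np.ndarray, rate_hz: float, window_s: float = 10.0) -> np.ndarray:
    """Correct pressure-insole force for negative readings and slow drift.

    Step 1 replaces each negative sample with the nearest preceding non-negative
    sample (leading negatives become 0).  Step 2 removes drift by shifting the
    minimum of each consecutive non-overlapping ``window_s`` window to 0 — the
    flight phase of each stride should carry no vertical ground reaction force.
    The trailing partial window is treated the same way.
    """
    force = np.asarray(force, dtype=float).copy()
    # step 1: forward-fill from the last non-negative value
    neg = force < 0
    if neg.any():
        idx = np.arange(force.size)
        last_ok = np.where(neg, -1, idx)
        np.maximum.accumulate(last_ok, out=last_ok)
        force = np.where(last_ok >= 0, force[np.maximum(last_ok, 0)], 0.0)
    # step 2: per-window minimum shift
    win = max(1, int(round(window_s * rate_hz)))
    out = force.copy()
    for start in range(0, force.size, win):
        block = out[start:start + win]
        block -= block.min()
    return out
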