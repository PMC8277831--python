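"""Gait-cycle detection and quiet-standing identification.

The primary segmentation signal is the sagittal-plane (mediolateral-axis)
angular velocity of the shank: one prominent peak per gait cycle, present in
any cyclic lower-limb activity including biking.  An insole-force threshold
crossing detector is provided as the laboratory alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from ._errors import ParameterError
from .preprocess import FilterSpec, butter_filter

DEFAULT_PROMINENCE = 0.3  # rad/s; rejects jitter peaks
DEFAULT_DURATION_BOUNDS = (0.4, 2.5)  # s; plausibility guard on stride length


@dataclass(frozen=True)
class StrideSegment:
    """One gait cycle as a half-open sample interval [start, end) on a recording."""

    start_index: int
    end_index: int
    start_time: float
    end_time: float

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ParameterError("stride end must be after start")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


@dataclass(frozen=True)
class StandingInterval:
    """A span with no detected strides, labeled quiet standing."""

    start_time: float
    end_time: float

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def _strides_from_boundaries(boundaries: np.ndarray, times: np.ndarray,
                             duration_bounds) -> list[StrideSegment]:
    lo, hi = duration_bounds
    out = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        seg = StrideSegment(int(a), int(b), float(times[a]), float(times[b]))
        if lo <= seg.duration <= hi:
            out.append(seg)
    return out


def segment_by_gyro(sagittal_gyro: np.ndarray, rate_hz: float,
                    min_separation_s: float = 0.5, lowpass_hz: float = 6.0,
                    prominence: float = DEFAULT_PROMINENCE,
                    duration_bounds=DEFAULT_DURATION_BOUNDS,
                    invert: bool = False,
                    t0: float = 0.0) -> list[StrideSegment]:
    """Segment strides at the largest relative peaks of the shank sagittal gyro.

    The signal is low-pass filtered (4th-order bidirectional Butterworth,
    default 6 Hz) and local maxima above a prominence floor are kept greedily
    in descending height subject to a pairwise spacing of at least
    ``min_separation_s``.  Consecutive kept peaks bound one stride.  Peaks are
    relative, so the output is invariant to a constant signal offset.

    ``invert`` flips the sign for mirrored sensor mounting.  Series too short
    to filter return no strides.
    """
    x = np.asarray(sagittal_gyro, dtype=float)
    if invert:
        x = -x
    order = 4
    if x.size <= 3 * (order + 1) * 2:  # too short for stable zero-phase filtering
        return []
    if lowpass_hz is not None:
        x = butter_filter(x, rate_hz, FilterSpec("lowpass", (lowpass_hz,), order))
    distance = max(1, int(round(min_separation_s * rate_hz)))
    # find_peaks' `distance` keeps peaks greedily by descending height,
    # removing any smaller peak closer than `distance` to a kept one —
    # exactly the spacing rule we need.
    peaks, _ = find_peaks(x, prominence=prominence, distance=distance)
    if peaks.size < 2:
        return []
    times = t0 + np.arange(x.size) / rate_hz
    return _strides_from_boundaries(peaks, times, duration_bounds)


def segment_by_force(force: np.ndarray, rate_hz: float,
                     threshold_n: float = 150.0,
                     duration_bounds=DEFAULT_DURATION_BOUNDS,
                     t0: float = 0.0) -> list[StrideSegment]:
    """Segment strides at rising crossings of an insole-force threshold.

    A boundary is any sample where force rises from below ``threshold_n`` to at
    or above it (default 150 N); consecutive crossings bound one stride.
    Expects a cleaned force series (see :func:`gaitmet.preprocess.insole_clean`).
    """
    f = np.asarray(force, dtype=float)
    if f.size < 2:
        return []
    rising = np.nonzero((f[:-1] < threshold_n) & (f[1:] >= threshold_n))[0] + 1
    if rising.size < 2:
        return []
    times = t0 + np.arange(f.size) / rate_hz
    return _strides_from_boundaries(rising, times, duration_bounds)


def detect_quiet_standing(stride_times, session_span, timeout_s: float = 8.0,
                          leading_from_start: bool = True) -> list[StandingInterval]:
    """Label quiet standing wherever no stride occurs for ``timeout_s`` seconds.

    For every gap between consecutive stride events (or between a session edge
    and the nearest stride) longer than ``timeout_s``, an interval is emitted
    starting ``timeout_s`` after the gap's left edge and ending at its right
    edge — mirroring a device that waits out the timeout before switching to
    the standing heuristic.  With ``leading_from_start`` (the offline,
    retrospective labeling) a gap at the very start of the session, where no
    stride precedes, is standing from the session start instead.
    """
    t0, t1 = float(session_span[0]), float(session_span[1])
    if t1 < t0:
        raise ParameterError("session span end before start")
    stride_times = sorted(float(t) for t in stride_times)
    if not stride_times and leading_from_start:
        return [StandingInterval(t0, t1)] if t1 > t0 else []
    events = [t0] + stride_times + [t1]
    out = []
    for i, (left, right) in enumerate(zip(events[:-1], events[1:])):
        if right - left <= timeout_s:
            continue
        # a leading gap has no preceding stride: retrospective labeling marks
        # it standing from the session start rather than after the timeout
        start = t0 if (i == 0 and leading_from_start) else left + timeout_s
        if right > start:
            out.append(StandingInterval(start, right))
    return out


def write_intervals(path: str | Path, strides: list[StrideSegment],
                    standing: list[StandingInterval]) -> None:
    """Dump strides and standing spans as a BED-like TSV for inspection."""
    rows = [(s.start_time, s.end_time, "stride") for s in strides]
    rows += [(s.start_time, s.end_time, "standing") for s in standing]
    rows.sort()
    with open(path, "w") as fh:
        for a, b, label in rows:
            fh.write(f"{a:.3f}\t{b:.3f}\t{label}\n")
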