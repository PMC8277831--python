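"""Error metrics for time-varying energy-expenditure estimates.

Three metrics, all comparing an estimate series to a ground-truth series after
both are linearly interpolated onto a common 1-second grid:

* absolute percent error — mean of |est − truth| / truth over the window;
* relative percent error — the same after removing each subject's mean
  est − truth offset pooled across all their conditions;
* cumulative error — percent error of total energy over the condition plus
  any above-standing expenditure during a fixed recovery window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import DataError, ParameterError
from .series import EESeries

GRID_STEP_S = 1.0


@dataclass
class ConditionEvaluation:
    """Everything the three error metrics need for one condition."""

    condition_id: str
    estimate: EESeries
    truth: EESeries
    standing_level: float  # Watts
    condition_window: tuple  # (t_start, t_end)
    recovery_window: tuple | None = None  # defaults to 180 s after the condition

    def __post_init__(self) -> None:
        if self.recovery_window is None:
            t_end = self.condition_window[1]
            self.recovery_window = (t_end, t_end + 180.0)


def _grid(window, step=GRID_STEP_S) -> np.ndarray:
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ParameterError("window end must be after start")
    n = int(np.floor((t1 - t0) / step + 1e-9)) + 1
    return t0 + np.arange(n) * step


def absolute_percent_error(est: EESeries, truth: EESeries, window) -> float:
    """Mean |est − truth| / truth × 100 on the 1-s grid over ``window``."""
    grid = _grid(window)
    e = est.at(grid)
    t = truth.at(grid)
    if np.any(t <= 0):
        raise DataError("ground truth must be positive on the comparison grid")
    return float(np.mean(np.abs(e - t) / t) * 100.0)


def relative_percent_error(per_subject_conditions) -> float:
    """Offset-free error: precision in tracking *changes* in EE.

    ``per_subject_conditions`` is a list (one entry per subject) of lists of
    ``(est, truth, window)`` tuples.  Per subject, the mean est − truth
    difference pooled across all their condition grids is removed from the
    estimates before the absolute percent error is computed; errors are then
    averaged over all conditions and subjects.
    """
    all_errors = []
    for conditions in per_subject_conditions:
        if not conditions:
            raise ParameterError("each subject needs at least one condition")
        diffs = []
        grids = []
        for est, truth, window in conditions:
            grid = _grid(window)
            e, t = est.at(grid), truth.at(grid)
            if np.any(t <= 0):
                raise DataError("ground truth must be positive on the comparison grid")
            diffs.append(e - t)
            grids.append((e, t))
        offset = float(np.mean(np.concatenate(diffs)))
        for e, t in grids:
            all_errors.append(float(np.mean(np.abs(e - offset - t) / t) * 100.0))
    return float(np.mean(all_errors))


def cumulative_energy(series: EESeries, condition_window, recovery_window,
                      standing_level: float) -> float:
    """Total energy in Joules: the condition integral plus the above-standing
    excess during recovery.

    Trapezoidal integration on the 1-s grid; the recovery term is
    ``∫ max(0, EE − standing_level)`` so a subject back at standing contributes
    nothing.  Additive over a partition of the condition window.
    """
    if standing_level is None or standing_level <= 0:
        raise ParameterError("standing_level must be a positive Watts value")
    grid_c = _grid(condition_window)
    joules = float(np.trapezoid(series.at(grid_c), grid_c))
    grid_r = _grid(recovery_window)
    excess = np.maximum(series.at(grid_r) - standing_level, 0.0)
    joules += float(np.trapezoid(excess, grid_r))
    return joules


def cumulative_average_power(series: EESeries, condition_window, recovery_window,
                             standing_level: float,
                             average_window_s: float = 180.0) -> float:
    """Alternative cumulative reading: mean power over the last
    ``average_window_s`` of the condition, plus the recovery excess energy
    spread over that window (W)."""
    t0, t1 = condition_window
    grid_c = _grid((max(t0, t1 - average_window_s), t1))
    mean_power = float(np.mean(series.at(grid_c)))
    grid_r = _grid(recovery_window)
    excess = np.maximum(series.at(grid_r) - standing_level, 0.0)
    return mean_power + float(np.trapezoid(excess, grid_r)) / average_window_s


def cumulative_error(evaluation: ConditionEvaluation,
                     definition: str = "total") -> float:
    """Percent error between cumulative estimate and cumulative truth.

    ``definition`` selects the cumulative quantity: ``"total"`` energy in
    Joules (default) or ``"average"`` power over the last 3 min — two readings
    of the same protocol; the ratio-style error makes them numerically close.
    """
    if definition == "total":
        fn = cumulative_energy
        args = ()
    elif definition == "average":
        fn = cumulative_average_power
        args = ()
    else:
        raise ParameterError(f"unknown cumulative definition {definition!r}")
    cum_est = fn(evaluation.estimate, evaluation.condition_window,
                 evaluation.recovery_window, evaluation.standing_level, *args)
    cum_truth = fn(evaluation.truth, evaluation.condition_window,
                   evaluation.recovery_window, evaluation.standing_level, *args)
    if cum_truth <= 0:
        raise DataError("cumulative truth must be positive")
    return float(abs(cum_est - cum_truth) / cum_truth * 100.0)


def acceleration_cost_bound(measured_increase_pct=(4.0, 8.0),
                            measured_accel: float = 0.15,
                            target_accel: float = 0.07) -> tuple:
    """Bound the energy cost of speed fluctuations that speed interpolation
    misses.

    Varying walking speed is known to cost extra energy roughly in proportion
    to the average acceleration: a measured ``measured_increase_pct`` range at
    ``measured_accel`` m/s² rescales linearly to the protocol's
    ``target_accel``.  Returns the (low, high) percent range; rounding the high
    end gives the headline upper bound on how much interpolated ground truth
    underestimates true cumulative expenditure.
    """
    if measured_accel <= 0 or target_accel < 0:
        raise ParameterError("accelerations must be positive")
    scale = target_accel / measured_accel
    lo, hi = measured_increase_pct
    return (lo * scale, hi * scale)
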