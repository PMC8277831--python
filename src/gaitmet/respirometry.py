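"""Indirect-calorimetry ground truth: Brockway conversion, steady-state
averaging, fast exponential estimation, and speed-interpolated truth for
time-varying conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._errors import ParameterError
from .io import BreathRecords
from .series import EESeries

#: Brockway-type linear conversion, J per mL of V̇O2 and V̇CO2
BROCKWAY_COEFFS = (16.58, 4.51)


def brockway_power(vo2, vco2, coeffs=BROCKWAY_COEFFS):
    """Metabolic power (W) from gas-exchange rates (mL/s): c1·V̇O2 + c2·V̇CO2.

    Homogeneous of degree 1: doubling both flows doubles power.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ParameterError("gas flows must be non-negative")
    return coeffs[0] * vo2 + coeffs[1] * vco2


def breath_series(breaths: BreathRecords, coeffs=BROCKWAY_COEFFS) -> EESeries:
    """Per-breath EE series from gas-exchange records."""
    return EESeries(breaths.times, brockway_power(breaths.vo2, breaths.vco2, coeffs),
                    "breath")


def default_window(condition_duration_s: float) -> float:
    """Averaging window convention: 6-min conditions average the last 3 min,
    5-min conditions the last 2 min; otherwise the last half."""
    if abs(condition_duration_s - 360.0) < 1e-6:
        return 180.0
    if abs(condition_duration_s - 300.0) < 1e-6:
        return 120.0
    return condition_duration_s / 2.0


def steady_state_average(ee: EESeries, condition_duration_s: float,
                         window_s: float | None = None) -> float:
    """Time-weighted mean EE over the last ``window_s`` of a condition."""
    if window_s is None:
        window_s = default_window(condition_duration_s)
    if window_s > condition_duration_s:
        raise ParameterError("averaging window longer than the condition")
    t_start = condition_duration_s - window_s
    # integrate on a dense grid including the exact window edges
    grid = np.union1d(ee.times[(ee.times > t_start) & (ee.times < condition_duration_s)],
                      [t_start, condition_duration_s])
    vals = ee.at(grid)
    return float(np.trapezoid(vals, grid) / (condition_duration_s - t_start))


@dataclass
class ExponentialFit:
    """First-order on-kinetics fit ``y(t) = y_ss + (y0 − y_ss)·exp(−t/τ)``.

    ``y_ss`` (the asymptote) is the fast steady-state estimate.  ``success``
    is False when the optimizer failed; ``message`` carries diagnostics.
    """

    y0: float
    y_ss: float
    tau: float
    residual_norm: float
    success: bool = True
    message: str = ""


def _exp_model(t, y_ss, y0, tau):
    return y_ss + (y0 - y_ss) * np.exp(-t / tau)


def fast_estimate(breath_ee: EESeries, tau_bounds=(1.0, 300.0)) -> ExponentialFit:
    """Estimate steady state quickly from early breaths.

    Nonlinear least squares of a first-order exponential to the per-breath EE
    series (time measured from the first breath); the asymptote is the
    estimate.  Initialization: y0 from the first breath, y_ss from the mean of
    the last quartile, τ = 30 s, with τ bounded to ``tau_bounds``.
    """
    if len(breath_ee) < 5:
        raise ParameterError("need at least 5 breaths for an exponential fit")
    t = breath_ee.times - breath_ee.times[0]
    y = breath_ee.values
    if np.ptp(y) < 1e-12:  # degenerate: a constant series is its own asymptote
        return ExponentialFit(float(y[0]), float(y[0]), tau_bounds[0], 0.0,
                              True, "constant series")
    y0_init = float(y[0])
    yss_init = float(y[-max(1, y.size // 4):].mean())
    p0 = [yss_init, y0_init, 30.0]
    lo = [0.0, 0.0, tau_bounds[0]]
    hi = [np.inf, np.inf, tau_bounds[1]]
    try:
        popt, _ = curve_fit(_exp_model, t, y, p0=p0, bounds=(lo, hi), maxfev=10000)
    except RuntimeError as exc:  # non-convergence
        return ExponentialFit(y0_init, yss_init, 30.0, float("nan"), False, str(exc))
    resid = float(np.linalg.norm(y - _exp_model(t, *popt)))
    return ExponentialFit(float(popt[1]), float(popt[0]), float(popt[2]), resid)


@dataclass
class SpeedEEMap:
    """Per-subject (steady speed, steady EE) pairs, standing included at 0 m/s."""

    speeds: np.ndarray
    ee: np.ndarray

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        self.ee = np.asarray(self.ee, dtype=float)
        if self.speeds.size != self.ee.size or self.speeds.size == 0:
            raise ParameterError("map needs paired, non-empty speed/EE values")
        if np.unique(self.speeds).size != self.speeds.size:
            raise ParameterError("map speeds must be distinct")
        if np.any(self.ee <= 0):
            raise ParameterError("map EE values must be positive")
        order = np.argsort(self.speeds)
        self.speeds = self.speeds[order]
        self.ee = self.ee[order]


def interpolated_ground_truth(times, speeds, speed_ee_map: SpeedEEMap) -> EESeries:
    """Approximate time-varying ground truth from steady-state measurements.

    EE is piecewise-linearly interpolated against treadmill speed along the
    profile, assuming instantaneous metabolic power tracks instantaneous work
    rate (valid below the aerobic threshold).  Speeds outside the mapped range
    clamp to the nearest endpoint (standing at 0 m/s anchors the low end).
    """
    if speed_ee_map.speeds.size < 2:
        raise ParameterError("map needs at least 2 points to interpolate")
    values = np.interp(np.asarray(speeds, dtype=float),
                       speed_ee_map.speeds, speed_ee_map.ee)
    return EESeries(np.asarray(times, dtype=float), values, "interpolated")
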