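"""Comparator estimators: the one-parameter heart-rate regression and the
acceleration-count activity monitor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import FitError, ParameterError
from .io import ImuRecording
from .preprocess import FilterSpec, butter_filter

#: 1 MET = 1 kcal·kg⁻¹·h⁻¹ = 4184/3600 W/kg
MET_TO_W_PER_KG = 4184.0 / 3600.0


@dataclass
class HeartRateModel:
    """EE = weight·bpm + bias — one weight, one bias, nothing else."""

    weight: float  # W per bpm
    bias: float  # W


def fit_hr_model(hr_means, ee_truth) -> HeartRateModel:
    """OLS line from steady-state condition-mean heart rates to measured EE.

    One point per condition per subject.  All-identical heart rates make the
    design degenerate and raise :class:`FitError`.
    """
    hr = np.asarray(hr_means, dtype=float)
    ee = np.asarray(ee_truth, dtype=float)
    if hr.size < 2 or hr.shape != ee.shape:
        raise ParameterError("need >= 2 paired (hr, ee) points")
    if np.ptp(hr) == 0:
        raise FitError("all heart-rate values identical: slope is unidentifiable")
    slope, bias = np.polyfit(hr, ee, 1)
    return HeartRateModel(float(slope), float(bias))


def predict_hr(model: HeartRateModel, bpm) -> np.ndarray:
    """Affine prediction in beats per minute."""
    return model.weight * np.asarray(bpm, dtype=float) + model.bias


@dataclass
class CountsModel:
    """Activity-monitor configuration.

    Acceleration is band-passed, its magnitude thresholded, and supra-threshold
    samples counted per epoch; a linear MET regression converts counts/min to
    energy.  The MET coefficients are deliberately config-required — the
    vendor regression is proprietary — and are typically calibrated on
    training data.
    """

    met_intercept: float  # METs at zero counts
    met_slope: float  # METs per (count/min)
    count_threshold: float = 0.5  # m/s² on the band-passed magnitude
    epoch_s: float = 60.0
    band: tuple = (0.25, 2.5)  # Hz
    met_to_watts: float = MET_TO_W_PER_KG  # W per (MET·kg)

    def __post_init__(self) -> None:
        if self.count_threshold <= 0:
            raise ParameterError("count threshold must be positive")
        if self.epoch_s <= 0:
            raise ParameterError("epoch must be positive")


def activity_counts(accel: ImuRecording, model: CountsModel,
                    rate_hz: float | None = None) -> np.ndarray:
    """Counts per epoch from a uniform triaxial accelerometer stream.

    Each axis is band-passed (default 0.25–2.5 Hz, 4th-order bidirectional
    Butterworth), the per-sample vector magnitude taken, and samples at or
    above the threshold counted in consecutive ``epoch_s`` windows anchored at
    the first timestamp.
    """
    if rate_hz is None:
        dt = np.diff(accel.timestamps)
        rate_hz = 1.0 / float(np.median(dt))
    spec = FilterSpec("bandpass", model.band, 4)
    banded = np.column_stack([butter_filter(accel.accel[:, j], rate_hz, spec)
                              for j in range(3)])
    magnitude = np.linalg.norm(banded, axis=1)
    hits = magnitude >= model.count_threshold
    per_epoch = max(1, int(round(model.epoch_s * rate_hz)))
    n_epochs = int(np.ceil(hits.size / per_epoch))
    return np.array([int(hits[k * per_epoch:(k + 1) * per_epoch].sum())
                     for k in range(n_epochs)])


def counts_to_watts(counts_per_min, mass_kg: float, model: CountsModel) -> np.ndarray:
    """Convert counts/min to Watts via the MET regression.

    METs = intercept + slope·counts, floored at 0 (a negative regression output
    is unphysical); Watts = METs × mass × 4184/3600.
    """
    if mass_kg <= 0:
        raise ParameterError("mass must be positive")
    counts = np.asarray(counts_per_min, dtype=float)
    if np.any(counts < 0):
        raise ParameterError("counts must be non-negative")
    mets = np.maximum(model.met_intercept + model.met_slope * counts, 0.0)
    return mets * mass_kg * model.met_to_watts


def fit_met_regression(counts_per_min, ee_watts, mass_kg) -> tuple[float, float]:
    """Calibrate (intercept, slope) of the MET regression by OLS.

    Counts/min from training conditions against measured EE expressed in METs
    (EE / mass / 1.162 W·kg⁻¹).  Stands in for the unpublished vendor equation.
    """
    counts = np.asarray(counts_per_min, dtype=float)
    mets = np.asarray(ee_watts, dtype=float) / np.asarray(mass_kg, dtype=float) / MET_TO_W_PER_KG
    if counts.size < 2 or np.ptp(counts) == 0:
        raise FitError("MET regression needs >= 2 distinct count values")
    slope, intercept = np.polyfit(counts, mets, 1)
    return float(intercept), float(slope)
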