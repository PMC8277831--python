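"""The wearable estimator: ridge regression on stride features, rotation
augmentation for mounting robustness, and the quiet-standing basal heuristic.

The deployable model is a single linear map on standardized features fit with
ridge regularization (λ = 1 by default, bias unpenalized).  When no stride is
detected for 8 s the estimator switches to a scaled basal rate computed from
the subject's anthropometrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.linear_model import Ridge

from ._errors import FitError, ParameterError
from .features import (FeatureScaler, assemble_features, feature_names,
                       fit_scaler)
from .io import ImuRecording, SubjectInfo
from .segmentation import detect_quiet_standing, segment_by_gyro
from .series import EESeries, concat_series

KCAL_PER_DAY_TO_W = 4184.0 / 86400.0
DEFAULT_STANDING_SCALE = 1.3

#: Mifflin–St Jeor resting-rate coefficients, kcal/day:
#: 10·mass[kg] + 6.25·height[cm] − 5·age[y] + (+5 male / −161 female)
MIFFLIN_ST_JEOR = {"mass": 10.0, "height_cm": 6.25, "age": -5.0,
                   "male": 5.0, "female": -161.0}


def basal_power(subject: SubjectInfo, equation: dict | None = None) -> float:
    """Basal energy expenditure in Watts from anthropometrics.

    Uses the configured empirical equation (default Mifflin–St Jeor, in
    kcal/day) and converts with 1 kcal/day = 4184/86400 W.
    """
    eq = equation or MIFFLIN_ST_JEOR
    kcal_day = (eq["mass"] * subject.mass + eq["height_cm"] * subject.height * 100.0
                + eq["age"] * subject.age + eq[subject.sex])
    if kcal_day <= 0:
        raise ParameterError("basal equation produced a nonpositive rate")
    return kcal_day * KCAL_PER_DAY_TO_W


def basal_standing_estimate(subject: SubjectInfo,
                            standing_scale: float = DEFAULT_STANDING_SCALE,
                            equation: dict | None = None) -> float:
    """Quiet-standing EE heuristic: ``standing_scale × basal(subject)`` Watts."""
    if standing_scale <= 0:
        raise ParameterError("standing_scale must be positive")
    return standing_scale * basal_power(subject, equation)


def fit_standing_scale(training_standing_ee, basal_estimates) -> float:
    """Calibrate the standing factor on training subjects.

    The factor is the mean over subjects of (measured standing EE / basal
    estimate); a new subject's standing EE is their basal estimate times this
    factor.  Scale-invariant: rescaling both inputs leaves it unchanged.
    """
    ee = np.asarray(training_standing_ee, dtype=float)
    basal = np.asarray(basal_estimates, dtype=float)
    if ee.shape != basal.shape or ee.size == 0:
        raise ParameterError("need paired, non-empty standing/basal values")
    if np.any(basal <= 0) or np.any(ee <= 0):
        raise ParameterError("standing and basal estimates must be positive")
    return float(np.mean(ee / basal))


@dataclass
class RidgeEEModel:
    """Trained per-stride energy-expenditure estimator.

    ``weights`` act on standardized features (see :class:`FeatureScaler`);
    ``bias`` is in Watts and was not penalized during fitting.
    """

    weights: np.ndarray
    bias: float
    lam: float
    scaler: FeatureScaler
    standing_scale: float = DEFAULT_STANDING_SCALE
    basal_equation: dict = field(default_factory=lambda: dict(MIFFLIN_ST_JEOR))
    feature_order: list = field(default_factory=feature_names)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.lam <= 0:
            raise ParameterError("lambda must be positive")
        if self.standing_scale <= 0:
            raise ParameterError("standing_scale must be positive")
        if self.scaler is not None and self.weights.size != self.scaler.mean.size:
            raise ParameterError("weight length does not match scaler dimensions")

    def predict(self, rows: np.ndarray, standardized: bool = False) -> np.ndarray:
        """Predict Watts for feature rows (raw by default; scaler applied here)."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if not standardized:
            rows = self.scaler.transform(rows)
        return rows @ self.weights + self.bias

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "bias": float(self.bias),
            "lambda": float(self.lam),
            "scaler": {
                "mean": self.scaler.mean.tolist(),
                "std": self.scaler.std.tolist(),
                "degenerate": self.scaler.degenerate.astype(int).tolist(),
            },
            "standing_scale": float(self.standing_scale),
            "basal_equation": dict(self.basal_equation),
            "feature_order": list(self.feature_order),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RidgeEEModel":
        scaler = FeatureScaler(
            np.asarray(d["scaler"]["mean"], dtype=float),
            np.asarray(d["scaler"]["std"], dtype=float),
            np.asarray(d["scaler"]["degenerate"], dtype=bool),
        )
        return cls(np.asarray(d["weights"], dtype=float), d["bias"], d["lambda"],
                   scaler, d["standing_scale"], dict(d["basal_equation"]),
                   list(d["feature_order"]))


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float = 1.0,
              scaler: FeatureScaler | None = None,
              standing_scale: float = DEFAULT_STANDING_SCALE) -> RidgeEEModel:
    """Closed-form ridge fit on standardized rows.

    Minimizes ``‖y − Xw − b‖² + λ‖w‖²`` with the bias unpenalized.  ``X`` must
    already be standardized; pass the scaler so the model can standardize raw
    rows at prediction time.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError("need at least 2 rows")
    if y.shape != (X.shape[0],):
        raise ParameterError(f"y shape {y.shape} does not match X rows {X.shape[0]}")
    if lam <= 0:
        raise ParameterError("lambda must be positive")
    ridge = Ridge(alpha=lam, fit_intercept=True, solver="cholesky")
    ridge.fit(X, y)
    if scaler is None:
        scaler = FeatureScaler(np.zeros(X.shape[1]), np.ones(X.shape[1]),
                               np.zeros(X.shape[1], dtype=bool))
    return RidgeEEModel(ridge.coef_, float(ridge.intercept_), lam, scaler,
                        standing_scale)


def train_on_features(X_raw: np.ndarray, y: np.ndarray, lam: float = 1.0,
                      standing_scale: float = DEFAULT_STANDING_SCALE) -> RidgeEEModel:
    """Convenience: fit scaler on raw rows, standardize, then ridge-fit."""
    scaler = fit_scaler(X_raw)
    return fit_ridge(scaler.transform(X_raw), y, lam, scaler, standing_scale)


# ---------------------------------------------------------------------------
# Rotation augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationConfig:
    """Synthetic mounting-misalignment copies added to the training data."""

    copies_per_recording: int = 5
    max_angle: float = 15.0 * math.pi / 180.0  # rad
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies_per_recording < 0:
            raise ParameterError("copies_per_recording must be >= 0")
        if not (0.0 <= self.max_angle <= math.pi):
            raise ParameterError("max_angle must lie in [0, pi]")


def random_rotation(rng: np.random.Generator, max_angle: float) -> Rotation:
    """Uniform random axis on the sphere, angle uniform on [0, max_angle]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle)
    return Rotation.from_rotvec(angle * axis)


def rotate_recording(recording: ImuRecording, rotation: Rotation) -> ImuRecording:
    """Apply one rigid rotation to both sensor triads at every sample."""
    return ImuRecording(recording.sensor_location, recording.timestamps.copy(),
                        rotation.apply(recording.accel), rotation.apply(recording.gyro))


def augment_rotations(recordings: list[ImuRecording],
                      config: AugmentationConfig) -> list[list[ImuRecording]]:
    """Emit the originals plus rotated copies, one independent rotation per
    sensor per copy.

    Returns ``[originals, copy_1, copy_2, ...]`` where each element is a list
    parallel to ``recordings``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    out = [list(recordings)]
    for _ in range(config.copies_per_recording):
        copy = [rotate_recording(rec, random_rotation(rng, config.max_angle))
                for rec in recordings]
        out.append(copy)
    return out


# ---------------------------------------------------------------------------
# Session-level estimation
# ---------------------------------------------------------------------------

def estimate_session(model: RidgeEEModel, shank: ImuRecording, thigh: ImuRecording,
                     subject: SubjectInfo, rate_hz: float = 100.0,
                     feature_lowpass_hz: float = 6.0,
                     standing_timeout_s: float = 8.0,
                     standing_rate_hz: float = 1.0,
                     min_watts: float = 1.0) -> EESeries:
    """Run the full wearable pipeline on one preprocessed session.

    Strides are segmented from the shank sagittal (mediolateral-axis) gyro,
    converted to feature rows on low-pass-filtered channels, and predicted one
    Watts value per stride stamped at stride end.  Gaps of ``standing_timeout_s``
    with no stride emit the standing heuristic at ``standing_rate_hz``.
    Predictions are floored at ``min_watts`` so the series stays physical.
    """
    from .preprocess import FilterSpec, butter_filter

    strides = segment_by_gyro(shank.gyro[:, 1], rate_hz,
                              t0=float(shank.timestamps[0]))
    parts = []
    if strides:
        def _filtered(rec: ImuRecording) -> ImuRecording:
            if feature_lowpass_hz is None:
                return rec
            spec = FilterSpec("lowpass", (feature_lowpass_hz,), 4)
            ch = rec.channels()
            filt = np.column_stack([butter_filter(ch[:, j], rate_hz, spec)
                                    for j in range(6)])
            return ImuRecording(rec.sensor_location, rec.timestamps,
                                filt[:, :3], filt[:, 3:])

        X, accepted, _ = assemble_features(strides, _filtered(shank),
                                           _filtered(thigh), subject)
        if len(accepted):
            pred = np.maximum(model.predict(X), min_watts)
            times = np.array([s.end_time for s in accepted])
            parts.append(EESeries(times, pred, "stride_model"))
    span = (float(shank.timestamps[0]), float(shank.timestamps[-1]))
    standing = detect_quiet_standing([s.end_time for s in strides], span,
                                     timeout_s=standing_timeout_s)
    level = basal_standing_estimate(subject, model.standing_scale,
                                    model.basal_equation)
    for interval in standing:
        t = np.arange(interval.start_time, interval.end_time, 1.0 / standing_rate_hz)
        if t.size:
            parts.append(EESeries(t, np.full(t.size, level), "standing_heuristic"))
    return concat_series(parts)


# ---------------------------------------------------------------------------
# Interpretation
# ---------------------------------------------------------------------------

def weight_saliency(model: RidgeEEModel, training_rows: np.ndarray,
                    n_channels: int = 12, n_bins: int = 30) -> dict:
    """Which inputs the linear model relies on.

    A larger weight magnitude marks a more informative input.  Returns the
    per-channel and per-bin shares of total kinematic ``|weight|`` (each
    summing to 1) and the cosine similarity between the kinematic ``|weight|``
    vector and the per-feature standard deviation of the raw training inputs
    across all conditions.  A zero weight vector leaves the similarity
    undefined (``None``).
    """
    n_kin = n_channels * n_bins
    w = np.abs(model.weights[:n_kin]).reshape(n_channels, n_bins)
    total = w.sum()
    report = {
        "channel_share": (w.sum(axis=1) / total if total > 0
                          else np.full(n_channels, np.nan)),
        "bin_share": (w.sum(axis=0) / total if total > 0
                      else np.full(n_bins, np.nan)),
    }
    std = np.asarray(training_rows, dtype=float)[:, :n_kin].std(axis=0)
    wflat = w.ravel()
    if np.linalg.norm(wflat) == 0 or np.linalg.norm(std) == 0:
        report["cosine_similarity"] = None
    else:
        report["cosine_similarity"] = float(
            wflat @ std / (np.linalg.norm(wflat) * np.linalg.norm(std)))
    return report


# ---------------------------------------------------------------------------
# Activity-specific variant
# ---------------------------------------------------------------------------

@dataclass
class ActivitySpecificModel:
    """One ridge model per labeled activity on height, mass and stride duration.

    The comparator that assumes ideal activity classification: inputs are just
    the three scalars, so it captures cadence–intensity trends within an
    activity but no waveform shape.
    """

    models: dict

    @classmethod
    def fit(cls, scalar_rows: np.ndarray, y: np.ndarray, activities,
            lam: float = 1.0) -> "ActivitySpecificModel":
        scalar_rows = np.asarray(scalar_rows, dtype=float)
        activities = np.asarray(activities)
        models = {}
        for act in np.unique(activities):
            m = activities == act
            if m.sum() < 2:
                raise FitError(f"activity {act!r} has fewer than 2 training rows")
            models[str(act)] = train_on_features(scalar_rows[m], y[m], lam)
        return cls(models)

    def predict(self, scalar_rows: np.ndarray, activities) -> np.ndarray:
        scalar_rows = np.atleast_2d(np.asarray(scalar_rows, dtype=float))
        activities = np.asarray(activities)
        out = np.empty(scalar_rows.shape[0])
        for act in np.unique(activities):
            m = activities == act
            if str(act) not in self.models:
                raise ParameterError(f"no model for activity {act!r}")
            out[m] = self.models[str(act)].predict(scalar_rows[m])
        return out
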