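"""From segmented 12-channel strides to the fixed-size standardized rows the
ridge model consumes.

Each stride yields 360 kinematic features — 12 channels (shank accel XYZ,
shank gyro XYZ, thigh accel XYZ, thigh gyro XYZ) × 30 percent-stride bins,
channel-major — followed by three scalars: subject height (m), mass (kg) and
stride duration (s).  363 features in total, in a fixed, documented order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._errors import ParameterError, StrideRejected
from .io import ImuRecording, SubjectInfo
from .segmentation import StrideSegment

N_BINS = 30
N_CHANNELS = 12
N_KINEMATIC = N_BINS * N_CHANNELS  # 360
N_FEATURES = N_KINEMATIC + 3  # + height, mass, stride duration

_CHANNEL_NAMES = [
    f"{loc}_{kind}_{axis}"
    for loc in ("shank", "thigh")
    for kind in ("accel", "gyro")
    for axis in ("X", "Y", "Z")
]


def feature_names() -> list[str]:
    """The canonical ordering of all 363 features."""
    names = [f"{ch}_bin{b:02d}" for ch in _CHANNEL_NAMES for b in range(N_BINS)]
    return names + ["height_m", "mass_kg", "stride_duration_s"]


def bin_stride(channel_samples: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Average a stride's samples into ``n_bins`` contiguous blocks.

    Samples are partitioned into contiguous index blocks whose sizes differ by
    at most one (longer blocks first when the count does not divide evenly);
    output ``k`` is the mean of block ``k``.  A stride with fewer samples than
    bins cannot be binned and raises :class:`StrideRejected`.
    """
    x = np.asarray(channel_samples, dtype=float)
    if x.size < n_bins:
        raise StrideRejected(f"stride has {x.size} samples, fewer than {n_bins} bins")
    return np.array([block.mean() for block in np.array_split(x, n_bins)])


def assemble_features(strides: list[StrideSegment],
                      shank: ImuRecording, thigh: ImuRecording,
                      subject: SubjectInfo,
                      n_bins: int = N_BINS) -> tuple[np.ndarray, list[StrideSegment], list[str]]:
    """Build one feature row per accepted stride.

    Returns ``(X, accepted, rejections)`` where ``X`` has shape
    ``(n_accepted, 363)``.  Strides extending past either recording, or too
    short to bin, are rejected with a reason rather than silently dropped.
    Rows are independent: permuting stride order permutes rows identically.
    """
    chans = np.hstack([shank.channels(), thigh.channels()])  # (n, 12)
    n = chans.shape[0]
    rows, accepted, rejections = [], [], []
    for k, s in enumerate(strides):
        if s.start_index < 0 or s.end_index > n:
            rejections.append(f"stride {k}: extends past recording [{s.start_index}, {s.end_index})")
            continue
        try:
            kin = np.concatenate([
                bin_stride(chans[s.start_index:s.end_index, c], n_bins)
                for c in range(N_CHANNELS)
            ])
        except StrideRejected as exc:
            rejections.append(f"stride {k}: {exc}")
            continue
        rows.append(np.concatenate([kin, [subject.height, subject.mass, s.duration]]))
        accepted.append(s)
    X = np.array(rows) if rows else np.empty((0, n_bins * N_CHANNELS + 3))
    return X, accepted, rejections


@dataclass
class FeatureScaler:
    """Per-feature standardization statistics learned on training rows.

    Degenerate (zero-variance) features are guarded: their std is replaced by 1
    and the feature is masked, so any value maps to 0 under :meth:`transform`.
    """

    mean: np.ndarray
    std: np.ndarray
    degenerate: np.ndarray  # boolean mask of zero-variance training features

    def transform(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        out = (rows - self.mean) / self.std
        out[:, self.degenerate] = 0.0
        return out

    def inverse_transform(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return rows * self.std + self.mean


def fit_scaler(train_rows: np.ndarray) -> FeatureScaler:
    """Learn per-feature mean/std from training rows (test rows reuse them)."""
    X = np.asarray(train_rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ParameterError("need at least 2 training rows to fit a scaler")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    degenerate = std <= 0
    std = np.where(degenerate, 1.0, std)
    return FeatureScaler(mean, std, degenerate)


def apply_scaler(scaler: FeatureScaler, rows: np.ndarray) -> np.ndarray:
    return scaler.transform(rows)


def select_training_strides(condition_strides: list, k: int = 50) -> list:
    """Keep the last ``k`` (most recent) strides of a time-ordered condition.

    Warming up at the start of a condition makes early strides unrepresentative
    of steady state, so training uses a suffix.  Fewer than ``k`` available
    triggers a warning and returns them all.
    """
    if len(condition_strides) < k:
        warnings.warn(
            f"only {len(condition_strides)} strides available, fewer than the "
            f"requested {k}", stacklevel=2)
        return list(condition_strides)
    return list(condition_strides[-k:])
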