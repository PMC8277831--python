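"""On-disk formats and the time-series containers they load into.

All streams are plain delimited text (CSV, one header row, times in seconds as
floats).  Units are converted at this boundary only; everything downstream works
in SI: m/s² for acceleration, rad/s for angular velocity, Watts for power.

Axis convention for IMU channels: X fore-aft, Y mediolateral, Z vertical, all
assigned at the quiet-standing calibration pose.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DataError, FormatError, ParameterError

IMU_COLUMNS = ["time", "ax", "ay", "az", "gx", "gy", "gz"]
BREATH_COLUMNS = ["time", "vo2", "vco2"]
HR_COLUMNS = ["time", "bpm"]

SENSOR_LOCATIONS = ("shank", "thigh", "pelvis", "foot", "wrist", "trunk")

#: degrees → radians, standard gravity for unit conversion at the I/O boundary
DEG_TO_RAD = math.pi / 180.0
G_TO_MS2 = 9.80665

MODEL_SCHEMA_VERSION = 1


def _check_monotone(times: np.ndarray, what: str) -> None:
    if times.size >= 2:
        bad = np.nonzero(np.diff(times) <= 0)[0]
        if bad.size:
            raise DataError(
                f"{what}: time not strictly increasing at row {int(bad[0]) + 1} "
                f"(t={times[bad[0] + 1]!r})"
            )


@dataclass
class ImuRecording:
    """Timestamped 6-channel stream from one body-segment IMU.

    Parameters
    ----------
    sensor_location : str
        One of ``shank, thigh, pelvis, foot, wrist, trunk``.
    timestamps : ndarray, shape (n,)
        Seconds, strictly increasing.
    accel : ndarray, shape (n, 3)
        Acceleration in m/s², axes X (fore-aft), Y (mediolateral), Z (vertical).
    gyro : ndarray, shape (n, 3)
        Angular velocity in rad/s about the same axes.
    """

    sensor_location: str
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        if self.sensor_location not in SENSOR_LOCATIONS:
            raise ParameterError(f"unknown sensor location {self.sensor_location!r}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(-1, 3)
        n = self.timestamps.size
        if self.accel.shape[0] != n or self.gyro.shape[0] != n:
            raise DataError("accel/gyro sample count does not match timestamps")
        _check_monotone(self.timestamps, f"{self.sensor_location} IMU")
        for name, arr in (("timestamps", self.timestamps), ("accel", self.accel),
                          ("gyro", self.gyro)):
            if not np.all(np.isfinite(arr)):
                row = int(np.argwhere(~np.isfinite(arr))[0][0])
                raise DataError(f"non-finite value in {name} at row {row}")

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if self.n_samples else 0.0

    def channels(self) -> np.ndarray:
        """All six channels as an (n, 6) array, accel XYZ then gyro XYZ."""
        return np.hstack([self.accel, self.gyro])


@dataclass
class BreathRecords:
    """Per-breath gas exchange: time of breath end (s), V̇O2 and V̇CO2 in mL/s."""

    times: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        if not (self.times.size == self.vo2.size == self.vco2.size):
            raise DataError("breath columns have unequal lengths")
        _check_monotone(self.times, "breaths")
        if np.any(self.vo2 < 0) or np.any(self.vco2 < 0):
            raise DataError("negative gas flow in breath records")


@dataclass(frozen=True)
class SubjectInfo:
    """Anthropometrics used by the basal-rate equation and as model features."""

    height: float  # m
    mass: float  # kg
    age: float  # years
    sex: str  # "male" | "female"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ParameterError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (1.0 <= self.height <= 2.3):
            raise ParameterError(f"height {self.height} m outside [1.0, 2.3]")
        if not (30.0 <= self.mass <= 200.0):
            raise ParameterError(f"mass {self.mass} kg outside [30, 200]")
        if self.age <= 0:
            raise ParameterError("age must be positive")


@dataclass
class ConditionMetadata:
    """What a recording session contains: activity, intensity profile, subject."""

    activity: str  # standing | walk | run | stair | bike | other
    duration: float  # s
    subject: SubjectInfo
    speed_profile: object | None = None  # callable time -> m/s (or W / steps/min)
    label: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError("duration must be positive")


def read_imu_csv(path: str | Path, units_config: dict | None = None,
                 sensor_location: str = "shank") -> ImuRecording:
    """Read a 7-column IMU CSV (``time,ax,ay,az,gx,gy,gz``).

    ``units_config`` may declare ``{"gyro": "deg_s" | "rad_s", "accel": "g" | "m_s2"}``;
    declared non-internal units are converted on load.
    """
    units_config = units_config or {}
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in IMU_COLUMNS:
        nan_rows = df.index[df[col].isna()]
        if len(nan_rows):
            raise DataError(f"{path}: NaN in required column {col!r} at row {nan_rows[0]}")
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    if units_config.get("gyro", "rad_s") == "deg_s":
        gyro = gyro * DEG_TO_RAD
    if units_config.get("accel", "m_s2") == "g":
        accel = accel * G_TO_MS2
    return ImuRecording(sensor_location, df["time"].to_numpy(dtype=float), accel, gyro)


def write_imu_csv(path: str | Path, recording: ImuRecording) -> None:
    df = pd.DataFrame(
        np.column_stack([recording.timestamps, recording.accel, recording.gyro]),
        columns=IMU_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_breath_csv(path: str | Path) -> BreathRecords:
    """Read per-breath respirometry (``time,vo2,vco2``; flows in mL/s)."""
    df = pd.read_csv(path)
    missing = [c for c in BREATH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in BREATH_COLUMNS:
        nan_rows = df.index[df[col].isna()]
        if len(nan_rows):
            raise DataError(f"{path}: NaN in required column {col!r} at row {nan_rows[0]}")
    return BreathRecords(df["time"].to_numpy(float), df["vo2"].to_numpy(float),
                         df["vco2"].to_numpy(float))


def write_breath_csv(path: str | Path, breaths: BreathRecords) -> None:
    pd.DataFrame({"time": breaths.times, "vo2": breaths.vo2,
                  "vco2": breaths.vco2}).to_csv(path, index=False)


def read_hr_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a heart-rate stream (``time,bpm``); returns (times, bpm)."""
    df = pd.read_csv(path)
    missing = [c for c in HR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df.isna().any().any():
        raise DataError(f"{path}: NaN in heart-rate stream")
    times = df["time"].to_numpy(float)
    _check_monotone(times, "heart rate")
    return times, df["bpm"].to_numpy(float)


def resample_uniform(recording: ImuRecording, rate_hz: float = 100.0) -> ImuRecording:
    """Resample onto a uniform clock ``t0 + k/rate`` by linear interpolation.

    Output covers ``k = 0 .. floor((t_end - t0) * rate)``; no extrapolation
    beyond the recorded span.  Idempotent on input already uniform at ``rate``.
    """
    if recording.n_samples < 2:
        raise DataError("resampling needs at least 2 samples")
    t = recording.timestamps
    span = t[-1] - t[0]
    # small epsilon so a span that is an exact multiple of 1/rate keeps its endpoint
    n_out = int(math.floor(span * rate_hz + 1e-9)) + 1
    new_t = t[0] + np.arange(n_out) / rate_hz
    chans = recording.channels()
    out = np.empty((n_out, 6))
    for j in range(6):
        out[:, j] = np.interp(new_t, t, chans[:, j])
    return ImuRecording(recording.sensor_location, new_t, out[:, :3], out[:, 3:])


# ---------------------------------------------------------------------------
# Model artifact (JSON, schema-versioned)
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> dict:
    """Serialize a trained :class:`~gaitmet.model.RidgeEEModel` to JSON.

    The artifact stores weights, bias, scaler statistics, feature ordering and
    a schema version; :func:`load_model` reproduces predictions bit-for-bit.
    """
    payload = {"schema_version": MODEL_SCHEMA_VERSION, "model": model.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=1))
    return payload


def load_model(path: str | Path):
    from .model import RidgeEEModel  # local import: io must not depend on model at import time

    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"model artifact schema version {version!r} is incompatible with "
            f"this package (expected {MODEL_SCHEMA_VERSION})"
        )
    return RidgeEEModel.from_dict(payload["model"])
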