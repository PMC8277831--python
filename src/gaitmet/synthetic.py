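"""Synthetic gait and metabolic data with the statistical structure the
estimator assumes.

The generator emulates the measurement chain of a treadmill/stairmill/bike
protocol: stride-periodic 12-channel IMU waveforms whose shape and cadence
vary with activity and intensity, instantaneous energy expenditure tied
linearly to those waveform parameters and body mass, breath-by-breath gas
exchange lagged by first-order on-kinetics with multiplicative noise, and a
similarly lagged heart rate.  Everything is reproducible bit-for-bit from
``(seed, config)``.

By construction the instantaneous EE of each activity is affine in the binned
waveform features (channel gains are affine in the same normalized intensity
that drives the EE law, and every amplitude scales with body mass), so a ridge
model on stride features can represent the ground truth exactly — parameter
recovery, not realism, is the design goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._errors import ParameterError
from .io import ImuRecording, BreathRecords, SubjectInfo
from .model import basal_power, random_rotation
from .respirometry import BROCKWAY_COEFFS, SpeedEEMap
from .series import EESeries

RATE_HZ = 100.0
REFERENCE_MASS = 70.0  # kg; waveform amplitudes are expressed at this mass
N_HARMONICS = 4
TREADMILL_RUN_SPEED = 2.0  # m/s; treadmill activity resolves walk below, run above

# Shank accel XYZ, shank gyro XYZ, thigh accel XYZ, thigh gyro XYZ
SHANK_SAGITTAL_GYRO = 4  # gyro about the mediolateral (Y) axis
GRAVITY_CHANNELS = (2, 8)  # vertical accelerometer axes carry +g at calibration
ACCEL_CHANNELS = (0, 1, 2, 6, 7, 8)
GYRO_CHANNELS = (3, 4, 5, 9, 10, 11)


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Anthropometric sampling distributions (truncated normals)."""

    age_mean: float = 34.8
    age_sd: float = 11.6
    age_range: tuple = (18.0, 70.0)
    mass_mean: float = 74.3
    mass_sd: float = 13.1
    mass_range: tuple = (40.0, 140.0)
    height_mean: float = 1.73
    height_sd: float = 0.07
    height_range: tuple = (1.45, 2.05)
    male_fraction: float = 15.0 / 24.0
    cadence_factor_sd: float = 0.02
    waveform_jitter_sd: float = 0.02
    standing_ratio_mean: float = 1.30
    standing_ratio_sd: float = 0.05


@dataclass(frozen=True)
class SubjectProfile:
    """A sampled subject: anthropometrics plus gait idiosyncrasy.

    ``cadence_factor`` multiplies every cadence law; ``waveform_jitter_sd``
    perturbs the Fourier coefficients of each activity's waveform (seeded by
    ``jitter_seed`` so the perturbation is a stable trait of the subject);
    ``standing_ratio`` ties quiet-standing EE to the basal rate.
    """

    info: SubjectInfo
    cadence_factor: float = 1.0
    waveform_jitter_sd: float = 0.02
    jitter_seed: int = 0
    standing_ratio: float = 1.30

    @property
    def standing_ee(self) -> float:
        """Quiet-standing EE in Watts (ratio × basal rate)."""
        return self.standing_ratio * basal_power(self.info)


def sample_subjects(n: int, seed: int,
                    config: CohortConfig = CohortConfig()) -> list[SubjectProfile]:
    """Draw ``n`` reproducible subjects from the cohort distributions."""
    if n < 1:
        raise ParameterError("need n >= 1 subjects")
    rng = np.random.default_rng(seed)

    def trunc(mean, sd, lo, hi):
        while True:  # rejection sampling; acceptance is high for these ranges
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                return float(x)

    out = []
    for _ in range(n):
        sex = "male" if rng.random() < config.male_fraction else "female"
        info = SubjectInfo(
            height=trunc(config.height_mean, config.height_sd, *config.height_range),
            mass=trunc(config.mass_mean, config.mass_sd, *config.mass_range),
            age=trunc(config.age_mean, config.age_sd, *config.age_range),
            sex=sex,
        )
        out.append(SubjectProfile(
            info=info,
            cadence_factor=float(rng.normal(1.0, config.cadence_factor_sd)),
            waveform_jitter_sd=config.waveform_jitter_sd,
            jitter_seed=int(rng.integers(0, 2**31 - 1)),
            standing_ratio=float(rng.normal(config.standing_ratio_mean,
                                            config.standing_ratio_sd)),
        ))
    return out


# ---------------------------------------------------------------------------
# Activity templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityTemplate:
    """Stride-normalized waveforms and the laws tying intensity to gait and EE.

    ``intensity`` means treadmill speed (m/s) for walk/run, cadence (steps/min)
    for stair, resistance (W) for bike.  A normalized intensity
    ``fn(u) = (f(u) − f_lo) / (f_hi − f_lo)`` drives both the per-channel
    amplitude gains (``gain0 + gain1·fn``) and the EE law
    (``mass · (ee_lo + (ee_hi − ee_lo)·fn)``), making EE affine in the binned
    waveform features.
    """

    name: str
    fourier_cos: np.ndarray  # (12, H) base waveform coefficients
    fourier_sin: np.ndarray
    gain0: np.ndarray  # (12,)
    gain1: np.ndarray
    f_exponent: float  # f(u) = u ** f_exponent
    f_range: tuple  # (f_lo, f_hi) over the default intensity grid
    ee_range: tuple  # (ee_lo, ee_hi) in W/kg
    cadence_coeffs: tuple  # stride duration T(u) = c0 + c1·u, seconds
    intensities: tuple  # default steady grid

    def fn(self, u):
        f = np.asarray(u, dtype=float) ** self.f_exponent
        return (f - self.f_range[0]) / (self.f_range[1] - self.f_range[0])

    def cadence(self, u: float) -> float:
        """Stride duration in seconds at intensity ``u``."""
        return self.cadence_coeffs[0] + self.cadence_coeffs[1] * float(u)

    def ee_per_mass(self, u):
        """Instantaneous EE law in W/kg; strictly increasing in intensity."""
        lo, hi = self.ee_range
        return lo + (hi - lo) * self.fn(u)

    def subject_coeffs(self, subject: SubjectProfile) -> tuple[np.ndarray, np.ndarray]:
        """Fourier coefficients with the subject's idiosyncratic perturbation."""
        if subject.waveform_jitter_sd <= 0:
            return self.fourier_cos, self.fourier_sin
        name_key = sum(ord(c) * 131 ** k for k, c in enumerate(self.name)) % (2**31)
        rng = np.random.default_rng((subject.jitter_seed, name_key))
        jc = 1.0 + subject.waveform_jitter_sd * rng.standard_normal(self.fourier_cos.shape)
        js = 1.0 + subject.waveform_jitter_sd * rng.standard_normal(self.fourier_sin.shape)
        return self.fourier_cos * jc, self.fourier_sin * js

    def waveform(self, phases: np.ndarray, u: float,
                 subject: SubjectProfile) -> np.ndarray:
        """All 12 channels over stride phases in [0, 1); shape (n, 12)."""
        cos_c, sin_c = self.subject_coeffs(subject)
        h = np.arange(1, N_HARMONICS + 1)
        arg = 2.0 * math.pi * np.outer(phases, h)  # (n, H)
        base = np.cos(arg) @ cos_c.T + np.sin(arg) @ sin_c.T  # (n, 12)
        gain = (self.gain0 + self.gain1 * self.fn(u)) * (subject.info.mass / REFERENCE_MASS)
        return base * gain


def _template_waveforms(name: str, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    decay = 1.0 / np.arange(1, N_HARMONICS + 1) ** 2
    scale = np.where(np.isin(np.arange(12), ACCEL_CHANNELS), 2.0, 1.2)
    cos_c = rng.normal(size=(12, N_HARMONICS)) * decay * scale[:, None]
    sin_c = rng.normal(size=(12, N_HARMONICS)) * decay * scale[:, None]
    # The segmentation channel needs one dominant peak per stride, well above
    # the detector's prominence floor even for light subjects.
    cos_c[SHANK_SAGITTAL_GYRO] = [0.0, 0.2, 0.05, 0.0]
    sin_c[SHANK_SAGITTAL_GYRO] = [2.5, 0.25, 0.10, 0.05]
    return cos_c, sin_c


def default_templates(seed: int = 7) -> dict[str, ActivityTemplate]:
    """The four default activities, EE-calibrated so the steady grid at the
    reference mass stays inside the observed 179–1295 W envelope."""
    rng = np.random.default_rng(seed)
    specs = {
        # name: (f_exponent, intensities, ee_range W/kg, cadence c0+c1*u)
        "walk": (2.0, (0.75, 1.25, 1.75), (2.7, 6.0), (1.25, -0.12)),
        "run": (1.0, (2.25, 2.75, 3.25), (9.0, 18.0), (0.95, -0.06)),
        "stair": (1.0, (40.0, 60.0, 80.0), (6.4, 10.8), (1.8, -0.01)),
        "bike": (1.0, (20.0, 70.0, 150.0), (3.0, 9.5), (0.75, 0.0)),
    }
    out = {}
    for name, (p, grid, ee, cad) in specs.items():
        cos_c, sin_c = _template_waveforms(name, rng)
        f_lo, f_hi = grid[0] ** p, grid[-1] ** p
        gain0 = rng.uniform(0.7, 1.1, size=12)
        gain1 = rng.uniform(0.2, 0.8, size=12)
        out[name] = ActivityTemplate(name, cos_c, sin_c, gain0, gain1, p,
                                     (f_lo, f_hi), ee, cad, grid)
    return out


def default_condition_grid() -> list[tuple[str, float]]:
    """The 12 steady conditions: 4 activities × 3 intensities."""
    grid = []
    for name, tpl in default_templates().items():
        grid.extend((name, u) for u in tpl.intensities)
    return grid


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Steady:
    intensity: float
    duration: float


@dataclass(frozen=True)
class Sinusoid:
    lo: float
    hi: float
    duration: float
    period: float = 30.0


@dataclass(frozen=True)
class Steps:
    """Discrete intensity steps: up through ``levels`` then back down, each
    transition a linear ``ramp_s`` ramp followed by a ``hold_s`` hold."""

    levels: tuple
    duration: float | None = None  # None → exactly one full period
    ramp_s: float = 2.0
    hold_s: float = 8.0

    @property
    def period(self) -> float:
        n_steps = 2 * len(self.levels) - 2 if len(self.levels) > 1 else 1
        return n_steps * (self.ramp_s + self.hold_s)


@dataclass(frozen=True)
class ProtocolSpec:
    """A sequence of intensity segments for one activity.

    ``activity`` may be a template name, ``"treadmill"`` (resolves walk below
    2 m/s, run at or above) or ``"standing"``.  Intensity 0 means standing.
    """

    activity: str
    segments: tuple

    def __post_init__(self) -> None:
        for seg in self.segments:
            dur = seg.duration if seg.duration is not None else getattr(seg, "period", None)
            if dur is None or dur <= 0:
                raise ParameterError("segment durations must be positive")

    @property
    def duration(self) -> float:
        return sum(s.duration if s.duration is not None else s.period
                   for s in self.segments)


def steady_protocol(activity: str, intensity: float, duration: float,
                    trailing_standing_s: float = 0.0) -> ProtocolSpec:
    segs = [Steady(intensity, duration)]
    if trailing_standing_s > 0:
        segs.append(Steady(0.0, trailing_standing_s))
    return ProtocolSpec(activity, tuple(segs))


def generate_protocol(spec: ProtocolSpec, dt: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Densify a protocol into (times, intensity) arrays sampled every ``dt``."""
    times, values = [], []
    t0 = 0.0
    for seg in spec.segments:
        dur = seg.duration if seg.duration is not None else seg.period
        t = np.arange(0.0, dur, dt)
        if isinstance(seg, Steady):
            v = np.full(t.size, float(seg.intensity))
        elif isinstance(seg, Sinusoid):
            mid = (seg.lo + seg.hi) / 2.0
            amp = (seg.hi - seg.lo) / 2.0
            v = mid - amp * np.cos(2.0 * math.pi * t / seg.period)
        elif isinstance(seg, Steps):
            levels = list(seg.levels)
            sequence = levels + levels[-2:0:-1] if len(levels) > 1 else levels
            step_len = seg.ramp_s + seg.hold_s
            v = np.empty(t.size)
            for i, ti in enumerate(t):
                pos = ti % seg.period
                k = int(pos // step_len)
                prev = sequence[k - 1] if k > 0 else sequence[-1]
                cur = sequence[k]
                within = pos - k * step_len
                if within < seg.ramp_s:
                    v[i] = prev + (cur - prev) * within / seg.ramp_s
                else:
                    v[i] = cur
        else:
            raise ParameterError(f"unknown segment type {type(seg).__name__}")
        times.append(t + t0)
        values.append(v)
        t0 += dur
    return np.concatenate(times), np.concatenate(values)


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Measurement imperfections applied on top of the deterministic chain."""

    accel_sd: float = 0.3  # m/s² additive white noise
    gyro_sd: float = 0.1  # rad/s
    breath_cv: float = 0.07  # multiplicative lognormal CV on breath EE
    breath_tau: float = 42.0  # s, VO2 on-kinetics
    breath_interval_mean: float = 4.0  # s (gamma-distributed intervals)
    hr_tau: float = 30.0  # s
    hr_sd: float = 2.0  # bpm
    hr_rest: float = 60.0  # bpm at zero relative intensity
    hr_gain: float = 7.0  # bpm per (W/kg)
    mounting_rotation_deg: float = 0.0  # fixed per-sensor misalignment
    rer: float = 0.85  # respiratory exchange ratio used to split EE into flows

    @classmethod
    def zero(cls) -> "NoiseConfig":
        """Noise-free variant (kinetic lags retained — they are physiology,
        not noise)."""
        return cls(accel_sd=0.0, gyro_sd=0.0, breath_cv=0.0, hr_sd=0.0,
                   mounting_rotation_deg=0.0)


@dataclass
class SessionData:
    """Everything one simulated recording session produces."""

    subject: SubjectProfile
    shank: ImuRecording
    thigh: ImuRecording
    ee_truth: EESeries
    breaths: BreathRecords
    hr_times: np.ndarray
    hr_bpm: np.ndarray
    stride_starts: np.ndarray  # sample indices of generated stride boundaries
    protocol_times: np.ndarray
    protocol_values: np.ndarray


def _resolve_activity(activity: str, u: float) -> str:
    if u <= 0:
        return "standing"
    if activity == "treadmill":
        return "walk" if u < TREADMILL_RUN_SPEED else "run"
    return activity


def simulate_session(subject: SubjectProfile, templates: dict, protocol: ProtocolSpec,
                     noise: NoiseConfig = NoiseConfig(), seed: int = 0,
                     rate_hz: float = RATE_HZ) -> SessionData:
    """Simulate one session of the full measurement chain.

    Strides are laid down one at a time with duration from the activity's
    cadence law at the stride-start intensity (times the subject's cadence
    factor); the 12 channels follow the stride-phase waveforms; instantaneous
    EE follows the activity's EE law at the per-sample intensity.  Breaths lag
    EE through first-order on-kinetics sampled at gamma-distributed intervals
    with multiplicative lognormal noise; heart rate lags a linear function of
    mass-normalized EE.  Zero-intensity spans produce no strides.
    """
    rng = np.random.default_rng(seed)
    times, values = generate_protocol(protocol, dt=1.0 / rate_hz)
    n = times.size
    mass = subject.info.mass
    channels = np.zeros((n, 12))
    ee = np.empty(n)
    stride_starts = []

    i = 0
    while i < n:
        u = values[i]
        act = _resolve_activity(protocol.activity, u)
        if act == "standing":
            j = i
            while j < n and _resolve_activity(protocol.activity, values[j]) == "standing":
                j += 1
            ee[i:j] = subject.standing_ee
            i = j
            continue
        tpl = templates[act]
        T = tpl.cadence(u) * subject.cadence_factor
        ns_full = max(2, int(round(T * rate_hz)))
        ns = min(ns_full, n - i)
        phases = np.arange(ns) / ns_full
        channels[i:i + ns] = tpl.waveform(phases, u, subject)
        seg_ee = mass * tpl.ee_per_mass(values[i:i + ns])
        ee[i:i + ns] = np.maximum(seg_ee, 0.5 * subject.standing_ee)
        stride_starts.append(i)
        i += ns

    # gravity on the vertical accelerometer axes (calibration pose)
    for ch in GRAVITY_CHANNELS:
        channels[:, ch] += 9.81

    # fixed mounting misalignment, one rotation per sensor for the session
    if noise.mounting_rotation_deg > 0:
        ang = math.radians(noise.mounting_rotation_deg)
        for a_sl, g_sl in (((0, 3), (3, 6)), ((6, 9), (9, 12))):
            rot = random_rotation(rng, ang)
            channels[:, a_sl[0]:a_sl[1]] = rot.apply(channels[:, a_sl[0]:a_sl[1]])
            channels[:, g_sl[0]:g_sl[1]] = rot.apply(channels[:, g_sl[0]:g_sl[1]])

    if noise.accel_sd > 0:
        for ch in ACCEL_CHANNELS:
            channels[:, ch] += rng.normal(0.0, noise.accel_sd, size=n)
    if noise.gyro_sd > 0:
        for ch in GYRO_CHANNELS:
            channels[:, ch] += rng.normal(0.0, noise.gyro_sd, size=n)

    shank = ImuRecording("shank", times, channels[:, 0:3], channels[:, 3:6])
    thigh = ImuRecording("thigh", times, channels[:, 6:9], channels[:, 9:12])

    # breath-by-breath gas exchange with first-order on-kinetics
    dt = 1.0 / rate_hz
    decay = math.exp(-dt / noise.breath_tau)
    y = np.empty(n)
    y[0] = subject.standing_ee
    for k in range(1, n):
        y[k] = ee[k - 1] + (y[k - 1] - ee[k - 1]) * decay
    breath_times = []
    t = float(rng.gamma(4.0, noise.breath_interval_mean / 4.0))
    while t < times[-1]:
        breath_times.append(t)
        t += float(rng.gamma(4.0, noise.breath_interval_mean / 4.0))
    breath_times = np.asarray(breath_times)
    breath_ee = np.interp(breath_times, times, y)
    if noise.breath_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise.breath_cv ** 2))
        breath_ee = breath_ee * rng.lognormal(-0.5 * sigma ** 2, sigma, breath_times.size)
    joules_per_ml = BROCKWAY_COEFFS[0] + BROCKWAY_COEFFS[1] * noise.rer
    vo2 = breath_ee / joules_per_ml
    breaths = BreathRecords(breath_times, vo2, noise.rer * vo2)

    # heart rate toward rest + gain · EE/mass, sampled at 1 Hz
    decay_hr = math.exp(-dt / noise.hr_tau)
    target = noise.hr_rest + noise.hr_gain * ee / mass
    h = np.empty(n)
    h[0] = noise.hr_rest + noise.hr_gain * subject.standing_ee / mass
    for k in range(1, n):
        h[k] = target[k - 1] + (h[k - 1] - target[k - 1]) * decay_hr
    hr_times = np.arange(0.0, times[-1], 1.0)
    hr_bpm = np.interp(hr_times, times, h)
    if noise.hr_sd > 0:
        hr_bpm = hr_bpm + rng.normal(0.0, noise.hr_sd, hr_times.size)

    return SessionData(subject, shank, thigh,
                       EESeries(times, ee, "truth"), breaths, hr_times, hr_bpm,
                       np.asarray(stride_starts, dtype=int), times, values)


def make_speed_ee_map(subject: SubjectProfile, templates: dict,
                      activities=("walk", "run")) -> SpeedEEMap:
    """Exact (speed, EE) pairs for the subject's steady treadmill conditions,
    standing included at speed 0."""
    speeds = [0.0]
    ee = [subject.standing_ee]
    for act in activities:
        tpl = templates[act]
        for u in tpl.intensities:
            speeds.append(float(u))
            ee.append(float(subject.info.mass * tpl.ee_per_mass(u)))
    return SpeedEEMap(np.asarray(speeds), np.asarray(ee))
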