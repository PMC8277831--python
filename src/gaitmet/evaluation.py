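"""Leave-one-out evaluation of the wearable estimator and its comparators on
synthetic cohorts: generate → preprocess → train → estimate → evaluate.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._errors import ParameterError
from .baselines import (CountsModel, activity_counts, counts_to_watts,
                        fit_hr_model, fit_met_regression, predict_hr)
from .features import assemble_features, select_training_strides
from .io import ImuRecording, SubjectInfo
from .metrics import (ConditionEvaluation, absolute_percent_error,
                      cumulative_error, relative_percent_error)
from .model import (ActivitySpecificModel, AugmentationConfig,
                    augment_rotations, basal_power, estimate_session,
                    fit_standing_scale, train_on_features)
from .preprocess import FilterSpec, butter_filter
from .respirometry import breath_series, fast_estimate, interpolated_ground_truth, \
    steady_state_average
from .segmentation import segment_by_gyro
from .series import EESeries
from .synthetic import (NoiseConfig, ProtocolSpec, SessionData, Sinusoid,
                        Steps, SubjectProfile, default_condition_grid,
                        default_templates, make_speed_ee_map, sample_subjects,
                        simulate_session, steady_protocol)

FEATURE_LOWPASS_HZ = 6.0


def _lowpass_recording(rec: ImuRecording, rate_hz: float,
                       cutoff: float = FEATURE_LOWPASS_HZ) -> ImuRecording:
    spec = FilterSpec("lowpass", (cutoff,), 4)
    ch = rec.channels()
    filt = np.column_stack([butter_filter(ch[:, j], rate_hz, spec) for j in range(6)])
    return ImuRecording(rec.sensor_location, rec.timestamps, filt[:, :3], filt[:, 3:])


def extract_stride_features(shank: ImuRecording, thigh: ImuRecording,
                            subject: SubjectInfo, rate_hz: float = 100.0,
                            lowpass_hz: float = FEATURE_LOWPASS_HZ):
    """Segment strides from the shank sagittal gyro and build feature rows.

    Returns ``(X, accepted_strides)``; channels are low-pass filtered before
    binning, matching the deployed pipeline.
    """
    strides = segment_by_gyro(shank.gyro[:, 1], rate_hz,
                              t0=float(shank.timestamps[0]))
    if not strides:
        return np.empty((0, 363)), []
    X, accepted, _ = assemble_features(strides, _lowpass_recording(shank, rate_hz),
                                       _lowpass_recording(thigh, rate_hz), subject)
    return X, accepted


# ---------------------------------------------------------------------------
# Cohort datasets
# ---------------------------------------------------------------------------

@dataclass
class ConditionData:
    """One subject × one steady condition, featurized."""

    activity: str
    intensity: float
    truth_ee: float  # Watts, the activity EE law (steady-state respirometry analog)
    X: np.ndarray  # accepted stride feature rows, time-ordered
    stride_times: np.ndarray
    session: SessionData | None = None


def simulate_steady_condition(subject: SubjectProfile, templates: dict,
                              activity: str, intensity: float, duration: float,
                              noise: NoiseConfig, seed: int,
                              trailing_standing_s: float = 0.0,
                              keep_session: bool = False) -> ConditionData:
    protocol = steady_protocol(activity, intensity, duration, trailing_standing_s)
    session = simulate_session(subject, templates, protocol, noise, seed)
    X, strides = extract_stride_features(session.shank, session.thigh, subject.info)
    truth = float(subject.info.mass * templates[activity].ee_per_mass(intensity))
    return ConditionData(activity, intensity, truth, X,
                         np.array([s.end_time for s in strides]),
                         session if keep_session else None)


def build_cohort(subjects: list[SubjectProfile], templates: dict,
                 conditions: list[tuple[str, float]], duration: float,
                 noise: NoiseConfig, seed: int,
                 keep_sessions: bool = False,
                 trailing_standing_s: float = 0.0) -> list[list[ConditionData]]:
    """Simulate and featurize every subject × condition; deterministic in seed."""
    cohort = []
    for si, subject in enumerate(subjects):
        per_subject = []
        for ci, (act, u) in enumerate(conditions):
            cond_seed = (seed * 100003 + si * 1009 + ci * 13) % (2**31)
            per_subject.append(simulate_steady_condition(
                subject, templates, act, u, duration, noise, cond_seed,
                trailing_standing_s=trailing_standing_s,
                keep_session=keep_sessions))
        cohort.append(per_subject)
    return cohort


def training_matrix(cohort: list[list[ConditionData]], subject_idx: list[int],
                    n_strides: int = 50):
    """Stack the last ``n_strides`` rows of every training condition."""
    rows, targets, activities = [], [], []
    for si in subject_idx:
        for cond in cohort[si]:
            if cond.X.shape[0] == 0:
                continue
            keep = np.asarray(select_training_strides(list(range(cond.X.shape[0])),
                                                      n_strides))
            rows.append(cond.X[keep])
            targets.append(np.full(keep.size, cond.truth_ee))
            activities.append(np.full(keep.size, cond.activity, dtype=object))
    if not rows:
        raise ParameterError("no training strides available")
    return (np.vstack(rows), np.concatenate(targets), np.concatenate(activities))


# ---------------------------------------------------------------------------
# Leave-one-subject-out parameter recovery
# ---------------------------------------------------------------------------

def run_loso(n_subjects: int = 13,
             conditions: list[tuple[str, float]] | None = None,
             condition_duration: float = 80.0,
             noise: NoiseConfig = NoiseConfig(), seed: int = 0,
             lam: float = 1.0, n_train_strides: int = 50,
             steady_window: float = 40.0) -> dict:
    """Leave-one-subject-out steady-state recovery on a synthetic cohort.

    Trains the ridge model on all subjects but one and scores the held-out
    subject's 12 steady conditions: the condition estimate is the mean
    per-stride prediction over the last ``steady_window`` seconds, compared to
    the generator's EE law.  Returns per-subject mean absolute percent errors.
    """
    templates = default_templates()
    conditions = conditions or default_condition_grid()
    subjects = sample_subjects(n_subjects, seed)
    cohort = build_cohort(subjects, templates, conditions, condition_duration,
                          noise, seed)
    per_subject_mape, per_condition = [], []
    for held in range(n_subjects):
        train_idx = [i for i in range(n_subjects) if i != held]
        X, y, _ = training_matrix(cohort, train_idx, n_train_strides)
        model = train_on_features(X, y, lam)
        errors = []
        for cond in cohort[held]:
            m = cond.stride_times >= condition_duration - steady_window
            if not m.any():
                continue
            est = float(np.mean(model.predict(cond.X[m])))
            err = abs(est - cond.truth_ee) / cond.truth_ee * 100.0
            errors.append(err)
            per_condition.append({"subject": held, "activity": cond.activity,
                                  "intensity": cond.intensity, "error_pct": err})
        per_subject_mape.append(float(np.mean(errors)))
    return {"per_subject_mape": per_subject_mape,
            "mean_mape": float(np.mean(per_subject_mape)),
            "per_condition": per_condition}


def training_size_sweep(sizes=(2, 4, 8, 12), n_test: int = 4,
                        condition_duration: float = 80.0,
                        noise: NoiseConfig = NoiseConfig(), seed: int = 0,
                        lam: float = 1.0, n_repeats: int = 3) -> dict:
    """Held-out error as the training cohort grows.

    Each repeat simulates ``max(sizes)`` training subjects and ``n_test``
    fixed test subjects; each sweep point trains on the first ``k`` training
    subjects so larger cohorts strictly contain smaller ones.  The reported
    value per size is the median held-out condition error averaged over the
    ``n_repeats`` independent cohort draws — averaging over draws isolates the
    training-set-size trend from the luck of which subjects a small cohort
    happens to contain.
    """
    templates = default_templates()
    conditions = default_condition_grid()
    medians = {k: [] for k in sizes}
    for rep in range(n_repeats):
        rep_seed = (seed * 7919 + rep * 104729) % (2**31)
        all_subjects = sample_subjects(max(sizes) + n_test, rep_seed)
        train_cohort = build_cohort(all_subjects[:max(sizes)], templates,
                                    conditions, condition_duration, noise,
                                    rep_seed)
        test_cohort = build_cohort(all_subjects[max(sizes):], templates,
                                   conditions, condition_duration, noise,
                                   rep_seed + 1)
        for k in sizes:
            X, y, _ = training_matrix(train_cohort, list(range(k)))
            model = train_on_features(X, y, lam)
            errors = []
            for per_subject in test_cohort:
                for cond in per_subject:
                    if cond.X.shape[0] == 0:
                        continue
                    est = float(np.mean(model.predict(cond.X)))
                    errors.append(abs(est - cond.truth_ee) / cond.truth_ee * 100.0)
            medians[k].append(float(np.median(errors)))
    return {k: float(np.mean(v)) for k, v in medians.items()}


def augmentation_experiment(seed: int, n_train: int = 4, n_test: int = 2,
                            condition_duration: float = 60.0,
                            test_rotation_deg: float = 15.0,
                            augmentation: AugmentationConfig | None = None,
                            noise: NoiseConfig = NoiseConfig(),
                            conditions: list[tuple[str, float]] | None = None) -> dict:
    """Does rotation augmentation buy robustness to sensor misalignment?

    Trains two models on the same cohort — one on the original recordings
    only, one with rotated copies added — and evaluates both on test subjects
    whose sensors are misaligned by ``test_rotation_deg``.  Returns the mean
    absolute percent error of each.
    """
    augmentation = augmentation or AugmentationConfig(seed=seed)
    templates = default_templates()
    conditions = conditions or [("walk", u) for u in (0.75, 1.25, 1.75)] + \
        [("run", u) for u in (2.25, 2.75, 3.25)]
    subjects = sample_subjects(n_train + n_test, seed)
    rows_plain, rows_aug, targets_plain, targets_aug = [], [], [], []
    for si, subject in enumerate(subjects[:n_train]):
        for ci, (act, u) in enumerate(conditions):
            cond_seed = (seed * 99991 + si * 211 + ci) % (2**31)
            cond = simulate_steady_condition(subject, templates, act, u,
                                             condition_duration, noise, cond_seed,
                                             keep_session=True)
            sets = augment_rotations([cond.session.shank, cond.session.thigh],
                                     AugmentationConfig(
                                         augmentation.copies_per_recording,
                                         augmentation.max_angle,
                                         (augmentation.seed + si * 211 + ci) % (2**31)))
            for k, (shank, thigh) in enumerate(sets):
                X, _ = extract_stride_features(shank, thigh, subject.info)
                if X.shape[0] == 0:
                    continue
                keep = np.asarray(select_training_strides(list(range(X.shape[0]))))
                rows_aug.append(X[keep])
                targets_aug.append(np.full(keep.size, cond.truth_ee))
                if k == 0:
                    rows_plain.append(X[keep])
                    targets_plain.append(np.full(keep.size, cond.truth_ee))
    model_plain = train_on_features(np.vstack(rows_plain), np.concatenate(targets_plain))
    model_aug = train_on_features(np.vstack(rows_aug), np.concatenate(targets_aug))

    test_noise = NoiseConfig(**{**asdict(noise),
                                "mounting_rotation_deg": test_rotation_deg})
    errors = {"plain": [], "augmented": []}
    for si, subject in enumerate(subjects[n_train:]):
        for ci, (act, u) in enumerate(conditions):
            cond_seed = (seed * 77773 + si * 307 + ci) % (2**31)
            cond = simulate_steady_condition(subject, templates, act, u,
                                             condition_duration, test_noise,
                                             cond_seed)
            if cond.X.shape[0] == 0:
                continue
            for name, model in (("plain", model_plain), ("augmented", model_aug)):
                est = float(np.mean(model.predict(cond.X)))
                errors[name].append(abs(est - cond.truth_ee) / cond.truth_ee * 100.0)
    return {name: float(np.mean(v)) for name, v in errors.items()}


# ---------------------------------------------------------------------------
# Full pipeline orchestration
# ---------------------------------------------------------------------------

def default_time_varying_protocols(duration: float = 180.0) -> dict[str, ProtocolSpec]:
    """The four treadmill time-varying conditions: standing↔walk steps,
    walking sinusoid, walk↔run steps, walk↔run sinusoid."""
    return {
        "steps_stand_walk": ProtocolSpec("treadmill",
                                         (Steps((0.0, 1.0), duration),)),
        "sinusoid_walk": ProtocolSpec("treadmill",
                                      (Sinusoid(1.0, 1.5, duration),)),
        "steps_walk_run": ProtocolSpec("treadmill",
                                       (Steps((1.0, 3.0), duration),)),
        "sinusoid_walk_run": ProtocolSpec("treadmill",
                                          (Sinusoid(1.0, 3.0, duration),)),
    }


@dataclass
class RunConfig:
    """All knobs of an end-to-end evaluation run; hashable for provenance."""

    n_subjects: int = 6
    condition_duration: float = 80.0
    recovery_standing_s: float = 90.0
    tv_duration: float = 180.0
    seed: int = 0
    lam: float = 1.0
    n_train_strides: int = 50
    steady_window: float = 40.0
    holdout: str = "subject"  # subject | condition | both
    methods: tuple = ("wearable", "activity_specific", "hr", "counts",
                      "fastresp", "breath")
    cumulative_definition: str = "total"
    include_time_varying: bool = True
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def config_hash(self) -> str:
        payload = json.dumps({**{k: v for k, v in asdict(self).items()}},
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _condition_mean_hr(session: SessionData, window: tuple) -> float:
    m = (session.hr_times >= window[0]) & (session.hr_times <= window[1])
    return float(np.mean(session.hr_bpm[m]))


def orchestrate_evaluation(config: RunConfig = RunConfig()) -> dict:
    """Leave-one-subject-out evaluation of every estimator with full metrics.

    For each fold the wearable ridge model, the activity-specific model, the
    heart-rate line, and the activity-monitor MET regression are fit on the
    training subjects; the held-out subject's steady conditions are scored by
    absolute, relative and cumulative error, and (optionally) the four
    time-varying conditions by error against speed-interpolated ground truth.
    Returns ``{"report": DataFrame, "summary": dict, "config_hash": str}``;
    deterministic given the config.
    """
    templates = default_templates()
    conditions = default_condition_grid()
    subjects = sample_subjects(config.n_subjects, config.seed)
    cohort = build_cohort(subjects, templates, conditions,
                          config.condition_duration, config.noise, config.seed,
                          keep_sessions=True,
                          trailing_standing_s=config.recovery_standing_s)
    counts_cfg = CountsModel(met_intercept=1.0, met_slope=0.0)  # threshold/epoch only
    rows = []

    steady_win = (config.condition_duration - config.steady_window,
                  config.condition_duration)

    if config.holdout in ("subject", "both"):
        for held in range(config.n_subjects):
            train_idx = [i for i in range(config.n_subjects) if i != held]
            rows += _evaluate_fold(cohort, subjects, templates, train_idx, held,
                                   conditions, counts_cfg, config, steady_win)
    if config.holdout in ("condition", "both"):
        for ci, (act, u) in enumerate(conditions):
            train_conditions = [c for c in range(len(conditions)) if c != ci]
            X, y, _ = _condition_training(cohort, train_conditions,
                                          config.n_train_strides)
            model = train_on_features(X, y, config.lam)
            for si in range(config.n_subjects):
                cond = cohort[si][ci]
                if cond.X.shape[0] == 0:
                    continue
                est = float(np.mean(model.predict(cond.X)))
                rows.append({"holdout": "condition", "subject": si,
                             "condition": f"{act}@{u:g}", "method": "wearable",
                             "metric": "absolute_pct",
                             "value": abs(est - cond.truth_ee) / cond.truth_ee * 100.0})

    report = pd.DataFrame(rows)
    summary = (report.groupby(["holdout", "method", "metric"])["value"]
               .mean().reset_index().to_dict("records"))
    return {"report": report, "summary": summary,
            "config_hash": config.config_hash(), "seed": config.seed}


def _condition_training(cohort, condition_idx, n_strides):
    rows, targets, acts = [], [], []
    for per_subject in cohort:
        for ci in condition_idx:
            cond = per_subject[ci]
            if cond.X.shape[0] == 0:
                continue
            keep = np.asarray(select_training_strides(list(range(cond.X.shape[0])),
                                                      n_strides))
            rows.append(cond.X[keep])
            targets.append(np.full(keep.size, cond.truth_ee))
            acts.append(np.full(keep.size, cond.activity, dtype=object))
    return np.vstack(rows), np.concatenate(targets), np.concatenate(acts)


def _evaluate_fold(cohort, subjects, templates, train_idx, held, conditions,
                   counts_cfg, config, steady_win):
    X, y, acts = training_matrix(cohort, train_idx, config.n_train_strides)
    model = train_on_features(X, y, config.lam)
    model.standing_scale = fit_standing_scale(
        [subjects[i].standing_ee for i in train_idx],
        [basal_power(subjects[i].info) for i in train_idx])
    scalar_cols = X[:, -3:]
    as_model = ActivitySpecificModel.fit(scalar_cols, y, acts, config.lam) \
        if "activity_specific" in config.methods else None

    hr_points, met_counts, met_ee, met_mass = [], [], [], []
    for i in train_idx:
        for cond in cohort[i]:
            hr_points.append((_condition_mean_hr(cond.session, steady_win),
                              cond.truth_ee))
            counts = activity_counts(cond.session.thigh, counts_cfg)
            met_counts.append(float(np.mean(counts) * 60.0 / counts_cfg.epoch_s))
            met_ee.append(cond.truth_ee)
            met_mass.append(subjects[i].info.mass)
    hr_model = fit_hr_model([p[0] for p in hr_points], [p[1] for p in hr_points])
    met_intercept, met_slope = fit_met_regression(met_counts, met_ee, met_mass)
    counts_model = CountsModel(met_intercept, met_slope,
                               counts_cfg.count_threshold, counts_cfg.epoch_s)

    subject = subjects[held]
    rows, rel_pairs = [], []
    for cond in cohort[held]:
        cond_name = f"{cond.activity}@{cond.intensity:g}"
        truth_series = EESeries(np.array(steady_win), np.full(2, cond.truth_ee),
                                "truth")
        estimates = {}
        m = cond.stride_times >= steady_win[0]
        if "wearable" in config.methods and m.any():
            estimates["wearable"] = float(np.mean(model.predict(cond.X[m])))
        if as_model is not None and m.any():
            estimates["activity_specific"] = float(np.mean(as_model.predict(
                cond.X[m][:, -3:], np.full(int(m.sum()), cond.activity))))
        if "hr" in config.methods:
            estimates["hr"] = float(predict_hr(
                hr_model, _condition_mean_hr(cond.session, steady_win)))
        if "counts" in config.methods:
            counts = activity_counts(cond.session.thigh, counts_model)
            cpm = float(np.mean(counts) * 60.0 / counts_model.epoch_s)
            estimates["counts"] = float(counts_to_watts(cpm, subject.info.mass,
                                                        counts_model))
        bser = breath_series(cond.session.breaths)
        if "fastresp" in config.methods and len(bser) >= 5:
            fit = fast_estimate(bser.window(0, config.condition_duration))
            if fit.success:
                estimates["fastresp"] = fit.y_ss
        if "breath" in config.methods and len(bser) >= 2:
            estimates["breath"] = steady_state_average(
                bser, config.condition_duration, config.steady_window)
        for method, est in estimates.items():
            err = abs(est - cond.truth_ee) / cond.truth_ee * 100.0
            rows.append({"holdout": "subject", "subject": held,
                         "condition": cond_name, "method": method,
                         "metric": "absolute_pct", "value": err})
            if method == "wearable":
                rel_pairs.append((
                    EESeries(np.array(steady_win), np.full(2, max(est, 1.0))),
                    truth_series, steady_win))
        # cumulative error for the wearable series vs per-breath truth
        if "wearable" in config.methods and len(bser) >= 2 \
                and config.recovery_standing_s >= 30.0:
            wear = estimate_session(model, cond.session.shank, cond.session.thigh,
                                    subject.info)
            if len(wear) >= 2:
                t_end = config.condition_duration
                ev = ConditionEvaluation(
                    cond_name, wear, bser, subject.standing_ee,
                    (0.0, t_end), (t_end, t_end + config.recovery_standing_s))
                try:
                    rows.append({"holdout": "subject", "subject": held,
                                 "condition": cond_name, "method": "wearable",
                                 "metric": "cumulative_pct",
                                 "value": cumulative_error(
                                     ev, config.cumulative_definition)})
                except Exception:
                    pass
    if rel_pairs:
        rows.append({"holdout": "subject", "subject": held, "condition": "all",
                     "method": "wearable", "metric": "relative_pct",
                     "value": relative_percent_error([rel_pairs])})

    if config.include_time_varying:
        speed_map = make_speed_ee_map(subject, templates)
        for ti, (name, protocol) in enumerate(
                default_time_varying_protocols(config.tv_duration).items()):
            tv_seed = (config.seed * 50021 + held * 101 + ti) % (2**31)
            session = simulate_session(subject, templates, protocol,
                                       config.noise, tv_seed)
            truth = interpolated_ground_truth(session.protocol_times,
                                              session.protocol_values, speed_map)
            window = (5.0, config.tv_duration - 5.0)
            est = estimate_session(model, session.shank, session.thigh,
                                   subject.info)
            if len(est) >= 2:
                rows.append({"holdout": "subject", "subject": held,
                             "condition": name, "method": "wearable",
                             "metric": "tv_absolute_pct",
                             "value": absolute_percent_error(est, truth, window)})
            if "hr" in config.methods:
                hr_est = EESeries(session.hr_times,
                                  np.maximum(predict_hr(hr_model, session.hr_bpm),
                                             1.0), "baseline")
                rows.append({"holdout": "subject", "subject": held,
                             "condition": name, "method": "hr",
                             "metric": "tv_absolute_pct",
                             "value": absolute_percent_error(hr_est, truth, window)})
            if "breath" in config.methods:
                bser = breath_series(session.breaths)
                if len(bser) >= 2:
                    rows.append({"holdout": "subject", "subject": held,
                                 "condition": name, "method": "breath",
                                 "metric": "tv_absolute_pct",
                                 "value": absolute_percent_error(bser, truth,
                                                                 window)})
    return rows
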