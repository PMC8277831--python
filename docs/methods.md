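# Methods

## The estimation problem

Whole-body energy expenditure (EE, Watts) cannot be measured instantaneously:
indirect calorimetry observes gas exchange, which lags metabolic demand with
first-order on-kinetics (time constant on the order of 30–60 s), and heart
rate lags similarly. Lower-limb kinematics, by contrast, change within a
stride of a change in work rate. `gaitmet` therefore estimates EE once per
gait cycle from inertial sensing of the shank and thigh, and treats the
respirometry chain as ground-truth machinery rather than as the estimator.

## Pipeline and parameters

**Filtering.** All filters are Butterworth, 4th order, applied forward and
backward (zero phase). Edge transients are bounded by odd signal extension at
both ends (the scipy `filtfilt`/`sosfiltfilt` convention). Defaults: 6 Hz
low-pass for the segmentation signal and for feature channels; 30–500 Hz
band-pass → rectify → 6 Hz low-pass → reference normalization for EMG
envelopes; insole force is cleaned by replacing negatives with the preceding
non-negative sample, then shifting each consecutive 10-s window's minimum
to 0 (order fixed as negatives-first; the trailing partial window is treated
like a full one).

**Stride segmentation.** Local maxima of the filtered shank sagittal
(mediolateral-axis) angular velocity, with prominence ≥ 0.3 rad/s
(configurable; prominence makes detection invariant to constant offsets and
rejects jitter peaks), kept greedily in descending height subject to ≥ 0.5 s
pairwise spacing. Consecutive kept peaks bound a stride; durations outside
[0.4, 2.5] s are discarded as implausible. An insole-force rising-crossing
detector (threshold 150 N) is provided as the laboratory alternative. A gap
of ≥ 8 s with no stride is labeled quiet standing; offline, a session's
leading gap is labeled standing from the session start (a real-time device
necessarily lags by the timeout — both behaviors are exposed).

**Features.** 12 channels × 30 contiguous-block bin means (block sizes
differing by at most one; binning commutes with affine transforms of the
signal) + height (m), mass (kg), stride duration (s) = 363 features, in a
fixed documented order. Standardization uses training-set means and SDs for
all 363 features, scalars included — treating the scalars like any other
input keeps a single λ meaningful; zero-variance features are masked to 0.
The last 50 strides of each training condition are used (early strides are
not at steady state).

**Model.** Ridge regression, λ = 1 on standardized features, bias
unpenalized, solved in closed form. Rotation augmentation draws, per copy
and per sensor, a uniformly random axis and an angle uniform on [0, 15°]
(5 copies by default); the magnitude distribution is a package choice — the
augmentation idea fixes neither. The quiet-standing heuristic returns
`standing_scale × basal(subject)` with basal from Mifflin–St Jeor
(10·mass + 6.25·height_cm − 5·age + {+5, −161} kcal/day; the equation is
pluggable since different basal equations circulate) converted at
4184/86400 W per kcal/day; `standing_scale` is the training-cohort mean of
measured standing EE over basal (≈ 1.3).

**Respirometry.** Brockway-type conversion with configurable coefficients
(16.58, 4.51) J/mL. Steady-state estimates average the last 3 min of 6-min
conditions and the last 2 min of 5-min conditions (time-weighted trapezoid).
The fast estimator fits y(t) = y_ss + (y₀ − y_ss)e^(−t/τ) by bounded
nonlinear least squares, initialized at y₀ = first breath, y_ss = mean of the
last quartile, τ = 30 s, τ ∈ [1, 300] s; y₀ is fit freely rather than pinned
to the previous condition. A constant series short-circuits to its own value;
optimizer failure returns a result object flagged unsuccessful rather than
raising. Time-varying ground truth interpolates subject-specific steady EE
piecewise-linearly against treadmill speed, clamped outside the mapped range
(standing at 0 m/s anchors the low end).

**Baselines.** Heart rate: one-weight-one-bias OLS on steady-state condition
means. Activity monitor: 0.25–2.5 Hz band-pass per axis, vector magnitude,
per-minute threshold counts, and a linear counts→METs regression
(1 MET = 4184/3600 W/kg). The vendor's exact filters, threshold and MET
coefficients are proprietary, so all constants are configuration; in the
evaluation pipeline the MET coefficients are calibrated by OLS on the
training split, and the monitor reads the thigh accelerometer since the
two-IMU setup has no pelvis sensor.

**Metrics.** Estimate and truth are linearly interpolated onto a common 1-s
grid. Absolute error: mean |est − truth|/truth × 100. Relative error: the
per-subject mean est − truth offset pooled across all of that subject's
condition grids is removed first. Cumulative EE: by default the total energy
(J) over the condition plus ∫max(0, EE − standing) over a 3-min recovery
window, with the error taken against per-breath respirometry; an alternative
"average power" definition is selectable, since the two readings of the
cumulative protocol differ and the package does not adjudicate. A linear
acceleration-cost rescaling (`acceleration_cost_bound`) bounds how much
speed-interpolated truth underestimates true cost during speed-varying
protocols: a 4–8 % cost increase measured at 0.15 m/s² average acceleration
rescales to ~2–4 % at the protocols' 0.07 m/s².

## The synthetic generator

The generator emulates the statistical structure the estimator assumes, not
biomechanical realism. Per activity (walk, run, stair, bike) a template
defines: 4-harmonic Fourier waveforms per channel over stride phase (with
1/h² amplitude decay, and a deliberately dominant fundamental on the shank
sagittal gyro so peak detection has one peak per cycle); a cadence law
(stride duration affine in intensity); and an EE law, strictly increasing in
a normalized intensity fₙ ∈ [0, 1] over the default grid. Channel amplitude
gains are affine in the same fₙ and all amplitudes scale with body mass, so
instantaneous EE = mass·(ee_lo + Δee·fₙ) is, **by construction, exactly
affine in the binned waveform features** — a ridge model can represent the
truth, and held-out error measures generalization, not model mismatch. EE
coefficients are calibrated once so the 12-condition steady grid at the
70-kg reference mass spans within the 179–1295 W envelope observed across
such protocols.

Cohorts are drawn from truncated normals (age 34.8 ± 11.6 y, mass
74.3 ± 13.1 kg, height 1.73 ± 0.07 m, 15:9 male:female). Subject
idiosyncrasy: cadence factor ~ N(1, 0.02), waveform-coefficient jitter
sd 2 % (a stable per-subject trait, seeded), standing/basal ratio
1.30 ± 0.05. Measurement noise defaults: accelerometer 0.3 m/s² and
gyroscope 0.1 rad/s additive white noise (representing soft-tissue artifact
more than sensor noise), breath EE multiplicative lognormal CV 7 % at
gamma-distributed intervals (mean 4 s), VO₂ on-kinetics τ = 42 s, heart rate
τ = 30 s toward 60 + 7·EE/mass bpm with 2 bpm noise, respiratory exchange
ratio 0.85 when splitting EE into V̇O₂/V̇CO₂. Strides are laid down with
integer sample counts at 100 Hz, so stride-count oracles quantize to the
realized stride length. The "zero-noise" configuration removes sensor and
breath noise but keeps the kinetic lags — lags are physiology, not noise.

What the generator does **not** emulate: realistic waveform morphology,
bilateral asymmetry, fatigue and drift, non-steady cadence within a
condition, anaerobic conditions, and soft-tissue nonlinearity. Passing tests
therefore demonstrate that the pipeline recovers the generator's structure —
segmentation, binning, standardization, ridge fitting, heuristics and
metrics are correct — not that the trained model transfers to human data.

## Evaluation design and problem sizes

Leave-one-subject-out on 13 subjects × 12 steady conditions is the primary
recovery check (mean absolute percent error over held-out conditions);
steady conditions run 80 s with the last 40 s scored, and time-varying
conditions 180 s — long enough for ≥ 50 strides per condition and several
lag constants, small enough to iterate quickly. The training-size sweep
reports the median held-out error at 2/4/8/12 training subjects, averaged
over three independent cohort draws so the trend is not confounded by which
subjects a small cohort happens to contain. The augmentation experiment
trains paired models (with/without rotated copies) on 4 subjects × 6
treadmill conditions and tests 2 subjects recorded with 15° sensor
misalignment.

In the synthetic grid, holding out an activity's *edge* intensity
(extrapolation beyond the training EE range) is consistently harder than
holding out the middle intensity; because EE is affine in the features here,
extrapolation degrades only through ridge shrinkage, so the effect is small
compared with what non-affine real data shows.

## Known limitations

- The generator's affine EE construction is favorable to the linear model by
  design; real stride-to-EE maps are not affine and real errors are larger.
- Breath and heart-rate simulation uses a single first-order lag; real
  on-kinetics show slow components and drift.
- The activity-monitor implementation follows the published description of
  count processing, not the proprietary firmware; its counts are not
  comparable to vendor counts.
- The per-breath series during short conditions never reaches steady state
  (τ = 42 s), so cumulative errors against per-breath truth include a
  protocol-induced component, as they do in practice.
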