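import numpy as np
import pytest

import gaitmet as gm
from gaitmet.synthetic import (NoiseConfig, ProtocolSpec, Sinusoid, Steady,
                               Steps, default_condition_grid,
                               default_templates, generate_protocol,
                               make_speed_ee_map, sample_subjects,
                               simulate_session, steady_protocol)


class TestSampleSubjects:
    def test_seed_determinism(self):
        a = sample_subjects(5, seed=11)
        b = sample_subjects(5, seed=11)
        assert [s.info for s in a] == [s.info for s in b]
        assert [s.jitter_seed for s in a] == [s.jitter_seed for s in b]

    def test_cohort_statistics_match_target(self):
        subjects = sample_subjects(4000, seed=1)
        masses = np.array([s.info.mass for s in subjects])
        # sample mean within 2 standard errors of the target 74.3 kg
        assert abs(masses.mean() - 74.3) < 2 * 13.1 / np.sqrt(4000)

    def test_truncation_bounds_respected(self):
        subjects = sample_subjects(500, seed=2)
        assert all(40.0 <= s.info.mass <= 140.0 for s in subjects)
        assert all(1.45 <= s.info.height <= 2.05 for s in subjects)


class TestGenerateProtocol:
    def test_standing_protocol_zero_speed(self):
        _, v = generate_protocol(steady_protocol("walk", 0.0, 30.0))
        assert np.all(v == 0.0)

    def test_sinusoid_attains_extremes_and_mean(self):
        spec = ProtocolSpec("treadmill", (Sinusoid(1.0, 3.0, 60.0, period=30.0),))
        _, v = generate_protocol(spec)
        assert v.min() == pytest.approx(1.0, abs=1e-6)
        assert v.max() == pytest.approx(3.0, abs=1e-6)
        assert v.mean() == pytest.approx(2.0, abs=1e-3)  # whole periods

    def test_step_sequence_total_period_sixty_seconds(self):
        steps = Steps((1.25, 1.75, 2.25, 2.75))
        assert steps.period == pytest.approx(60.0)
        t, v = generate_protocol(ProtocolSpec("treadmill", (steps,)))
        # after one full period the profile repeats
        assert v[0] == pytest.approx(v[-1], abs=0.3)
        assert v.max() == pytest.approx(2.75)

    def test_step_ramps_are_linear_over_two_seconds(self):
        t, v = generate_protocol(ProtocolSpec("treadmill",
                                              (Steps((0.0, 1.0), 40.0),)))
        ramp = v[(t >= 10.0) & (t <= 12.0)]  # second transition 0→… at t=10
        diffs = np.diff(ramp)
        assert np.allclose(diffs, diffs[0], atol=1e-9)


class TestSimulateSession:
    def test_standing_protocol_no_strides_breaths_converge(self, templates):
        subject = sample_subjects(1, seed=3)[0]
        session = simulate_session(subject, templates,
                                   steady_protocol("walk", 0.0, 240.0),
                                   NoiseConfig.zero(), seed=3)
        assert session.stride_starts.size == 0
        late = session.breaths.times > 200.0
        from gaitmet.respirometry import breath_series
        bs = breath_series(session.breaths)
        assert np.mean(bs.values[late]) == pytest.approx(subject.standing_ee,
                                                         rel=0.01)

    def test_steady_walk_stride_count_matches_cadence(self, templates):
        subject = sample_subjects(1, seed=4)[0]
        duration = 360.0
        session = simulate_session(subject, templates,
                                   steady_protocol("walk", 1.25, duration),
                                   NoiseConfig.zero(), seed=4)
        # the generator lays down integer-sample strides, so count against the
        # realized (quantized) stride length
        T = templates["walk"].cadence(1.25) * subject.cadence_factor
        realized = round(T * 100.0) / 100.0
        expected = duration / realized
        assert abs(session.stride_starts.size - expected) <= 1

    def test_default_grid_ee_within_printed_envelope(self, templates):
        reference = gm.SubjectProfile(gm.SubjectInfo(1.73, 70.0, 30.0, "male"))
        for act, u in default_condition_grid():
            ee = 70.0 * templates[act].ee_per_mass(u)
            assert 179.0 <= ee <= 1295.0, (act, u, ee)

    def test_bitwise_reproducibility(self, templates):
        subject = sample_subjects(1, seed=5)[0]
        a = simulate_session(subject, templates, steady_protocol("run", 2.75, 20.0),
                             NoiseConfig(), seed=9)
        b = simulate_session(subject, templates, steady_protocol("run", 2.75, 20.0),
                             NoiseConfig(), seed=9)
        assert np.array_equal(a.shank.gyro, b.shank.gyro)
        assert np.array_equal(a.breaths.vo2, b.breaths.vo2)
        assert np.array_equal(a.hr_bpm, b.hr_bpm)

    def test_breath_mean_tracks_truth_on_long_steady_condition(self, templates):
        subject = sample_subjects(1, seed=6)[0]
        session = simulate_session(subject, templates,
                                   steady_protocol("walk", 1.25, 300.0),
                                   NoiseConfig(), seed=6)
        truth = subject.info.mass * templates["walk"].ee_per_mass(1.25)
        from gaitmet.respirometry import breath_series
        bs = breath_series(session.breaths)
        late = bs.times > 180.0  # > 4τ into the condition
        n = int(late.sum())
        rel_err = abs(np.mean(bs.values[late]) - truth) / truth
        assert rel_err < 2 * 0.07 / np.sqrt(n) + 0.01  # CV-scaled tolerance

    def test_ee_law_strictly_increasing_in_intensity(self, templates):
        for tpl in templates.values():
            grid = np.linspace(tpl.intensities[0], tpl.intensities[-1], 20)
            ee = tpl.ee_per_mass(grid)
            assert np.all(np.diff(ee) > 0)


class TestSpeedEEMap:
    def test_standing_entry_is_subject_standing_ee(self, templates):
        subject = sample_subjects(1, seed=7)[0]
        m = make_speed_ee_map(subject, templates)
        assert m.speeds[0] == 0.0
        assert m.ee[0] == pytest.approx(subject.standing_ee)

    def test_map_monotone_over_walk_run(self, templates):
        subject = sample_subjects(1, seed=8)[0]
        m = make_speed_ee_map(subject, templates)
        assert np.all(np.diff(m.ee) > 0)

    def test_composition_identity_at_mapped_speed(self, templates):
        from gaitmet.respirometry import interpolated_ground_truth
        subject = sample_subjects(1, seed=9)[0]
        m = make_speed_ee_map(subject, templates)
        out = interpolated_ground_truth([0.0, 1.0], [1.25, 1.25], m)
        law = subject.info.mass * templates["walk"].ee_per_mass(1.25)
        assert np.allclose(out.values, law)
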