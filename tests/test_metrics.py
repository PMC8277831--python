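import numpy as np
import pytest

import gaitmet as gm
from gaitmet.metrics import (ConditionEvaluation, absolute_percent_error,
                             acceleration_cost_bound, cumulative_energy,
                             cumulative_error, relative_percent_error)
from gaitmet.series import EESeries


def const_series(value, t0=0.0, t1=600.0):
    return EESeries(np.array([t0, t1]), np.array([value, value]))


class TestAbsolutePercentError:
    def test_perfect_estimate_zero_error(self):
        truth = const_series(300.0)
        assert absolute_percent_error(truth, truth, (0, 100)) == 0.0

    def test_constant_ten_percent_offset(self):
        assert absolute_percent_error(const_series(110.0), const_series(100.0),
                                      (0, 60)) == pytest.approx(10.0)

    def test_symmetric_errors_average(self):
        t = np.arange(0.0, 11.0)
        est = EESeries(t, np.where(t < 5.5, 90.0, 110.0))
        err = absolute_percent_error(est, const_series(100.0), (0, 10))
        assert err == pytest.approx(10.0, abs=0.5)

    def test_nonpositive_truth_rejected(self):
        bad = EESeries([0.0, 10.0], [100.0, 100.0])
        bad.values = np.array([0.0, 100.0])  # corrupt after validation
        with pytest.raises(gm.DataError):
            absolute_percent_error(const_series(100.0), bad, (0, 10))


class TestRelativePercentError:
    def test_constant_offset_removed_entirely(self):
        conditions = [(const_series(t + 25.0), const_series(t), (0, 60))
                      for t in (100.0, 200.0, 400.0)]
        assert relative_percent_error([conditions]) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_example(self):
        # truth {100, 200}, est {120, 210} → offset 15 → adjusted {105, 195}
        # → errors {5%, 2.5%} → mean 3.75%
        conditions = [(const_series(120.0), const_series(100.0), (0, 60)),
                      (const_series(210.0), const_series(200.0), (0, 60))]
        assert relative_percent_error([conditions]) == pytest.approx(3.75)

    def test_zero_offset_reduces_to_absolute_error(self):
        est = const_series(110.0)
        truth = const_series(100.0)
        # offsets +10 and −10 cancel
        conditions = [(est, truth, (0, 60)),
                      (const_series(90.0), truth, (0, 60))]
        rel = relative_percent_error([conditions])
        abs1 = absolute_percent_error(est, truth, (0, 60))
        assert rel == pytest.approx(abs1)


class TestCumulativeEnergy:
    def test_recovery_at_standing_contributes_nothing(self):
        series = const_series(120.0, 0.0, 540.0)
        joules = cumulative_energy(series, (0, 360), (360, 540),
                                   standing_level=120.0)
        assert joules == pytest.approx(120.0 * 360.0)

    def test_hand_computed_total(self):
        # 360 s at 300 W plus 180 s of 50 W above standing → 117,000 J
        t = np.array([0.0, 360.0, 360.001, 540.0])
        v = np.array([300.0, 300.0, 170.0, 170.0])
        series = EESeries(t, v)
        joules = cumulative_energy(series, (0, 360), (360, 540),
                                   standing_level=120.0)
        assert joules == pytest.approx(117000.0, rel=1e-3)

    def test_scale_property_of_error(self):
        est = const_series(360.0, 0.0, 540.0)
        truth = const_series(300.0, 0.0, 540.0)
        ev = ConditionEvaluation("c", est, truth, standing_level=1000.0,
                                 condition_window=(0, 360))
        # recovery excess is zero for both (standing above both series)
        assert cumulative_error(ev) == pytest.approx(20.0)

    def test_additive_over_partition(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 361.0)
        series = EESeries(t, 250.0 + 50.0 * np.sin(t / 30.0) + rng.uniform(0, 1, t.size))
        whole = cumulative_energy(series, (0, 360), (360, 361), 1e9)
        left = cumulative_energy(series, (0, 180), (360, 361), 1e9)
        right = cumulative_energy(series, (180, 360), (360, 361), 1e9)
        assert whole == pytest.approx(left + right, rel=1e-9)

    def test_missing_standing_level_rejected(self):
        with pytest.raises(gm.ParameterError):
            cumulative_energy(const_series(300.0), (0, 360), (360, 540), None)

    def test_average_definition_available(self):
        est = const_series(330.0, 0.0, 540.0)
        truth = const_series(300.0, 0.0, 540.0)
        ev = ConditionEvaluation("c", est, truth, standing_level=1000.0,
                                 condition_window=(0, 360))
        assert cumulative_error(ev, definition="average") == pytest.approx(10.0)


class TestAccelerationCostBound:
    def test_linear_rescaling_to_protocol_acceleration(self):
        lo, hi = acceleration_cost_bound((4.0, 8.0), 0.15, 0.07)
        assert lo == pytest.approx(4.0 * 0.07 / 0.15)
        assert hi == pytest.approx(8.0 * 0.07 / 0.15)
        # rounding the rescaled range reproduces the ~2–4% headline bound
        assert (round(lo), round(hi)) == (2, 4)

    def test_metrics_invariant_to_time_unit_rescaling(self):
        est = const_series(110.0)
        truth = const_series(100.0)
        e_s = absolute_percent_error(est, truth, (0, 60))
        est_m = EESeries(est.times / 60.0, est.values)
        truth_m = EESeries(truth.times / 60.0, truth.values)
        e_min = absolute_percent_error(est_m, truth_m, (0, 1))
        assert e_s == pytest.approx(e_min)
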