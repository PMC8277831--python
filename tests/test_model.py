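import numpy as np
import pytest

import gaitmet as gm
from gaitmet.model import (AugmentationConfig, augment_rotations, basal_power,
                           fit_ridge, fit_standing_scale, random_rotation,
                           weight_saliency)


def ridge_normal_equations(X, y, lam):
    """Independent closed-form oracle: centered normal equations with
    unpenalized intercept."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    w = np.linalg.solve(Xc.T @ Xc + lam * np.eye(X.shape[1]), Xc.T @ yc)
    b = y.mean() - X.mean(axis=0) @ w
    return w, b


class TestFitRidge:
    def test_zero_targets_give_zero_model(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        model = fit_ridge(X, np.zeros(10))
        assert np.allclose(model.weights, 0.0, atol=1e-12)
        assert model.bias == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = fit_ridge(X, y, lam=1.0)
        w, b = ridge_normal_equations(X, y, 1.0)
        assert np.max(np.abs(model.weights - w)) < 1e-8
        assert abs(model.bias - b) < 1e-8

    def test_regularization_shrinks_weights(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + rng.normal(0, 0.1, 30)
        w1 = fit_ridge(X, y, lam=1.0).weights
        w0 = fit_ridge(X, y, lam=1e-8).weights
        assert np.linalg.norm(w1) <= np.linalg.norm(w0) + 1e-12

    def test_prediction_superposition(self, toy_model):
        model, X, _ = toy_model
        x1, x2 = X[0], X[1]
        lhs = model.predict(x1 + x2 - model.scaler.mean)
        rhs = model.predict(x1) + model.predict(x2) - model.bias
        assert lhs[0] == pytest.approx(rhs[0], abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(gm.ParameterError):
            fit_ridge(np.zeros((5, 3)), np.zeros(4))


class TestRotationAugmentation:
    def _recordings(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / 100.0
        return [gm.ImuRecording(loc, t, rng.normal(size=(n, 3)),
                                rng.normal(size=(n, 3)))
                for loc in ("shank", "thigh")]

    def test_zero_angle_copies_are_identical(self):
        recs = self._recordings()
        sets = augment_rotations(recs, AugmentationConfig(2, 0.0, seed=1))
        assert len(sets) == 3
        for copy in sets[1:]:
            for orig, rot in zip(recs, copy):
                assert np.allclose(rot.accel, orig.accel, atol=1e-12)

    def test_rotation_preserves_vector_norms(self):
        recs = self._recordings(1)
        sets = augment_rotations(recs, AugmentationConfig(3, np.pi / 6, seed=2))
        for copy in sets[1:]:
            for orig, rot in zip(recs, copy):
                assert np.allclose(np.linalg.norm(rot.accel, axis=1),
                                   np.linalg.norm(orig.accel, axis=1), atol=1e-9)
                assert np.allclose(np.linalg.norm(rot.gyro, axis=1),
                                   np.linalg.norm(orig.gyro, axis=1), atol=1e-9)

    def test_seed_determinism(self):
        recs = self._recordings(2)
        cfg = AugmentationConfig(4, np.pi / 12, seed=77)
        a = augment_rotations(recs, cfg)
        b = augment_rotations(recs, cfg)
        for ca, cb in zip(a, b):
            for ra, rb in zip(ca, cb):
                assert np.array_equal(ra.accel, rb.accel)
                assert np.array_equal(ra.gyro, rb.gyro)

    def test_angle_distribution_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            rot = random_rotation(rng, np.pi / 12)
            assert rot.magnitude() <= np.pi / 12 + 1e-12


class TestBasalHeuristic:
    def test_reference_male_rate(self, subject):
        # 10·70 + 6.25·175 − 5·30 + 5 = 1648.75 kcal/day → ×4184/86400 W
        assert basal_power(subject) == pytest.approx(1648.75 * 4184 / 86400,
                                                     abs=1e-9)
        assert basal_power(subject) == pytest.approx(79.842, abs=1e-3)

    def test_unit_scale_returns_basal(self, subject):
        assert gm.basal_standing_estimate(subject, 1.0) == basal_power(subject)

    def test_fitted_scale_is_mean_of_ratios(self):
        basal = np.array([80.0, 100.0])
        assert fit_standing_scale(basal * np.array([1.2, 1.4]), basal) == \
            pytest.approx(1.3)
        assert fit_standing_scale(basal, basal) == pytest.approx(1.0)

    def test_scale_invariance(self):
        ee = np.array([90.0, 120.0, 140.0])
        basal = np.array([70.0, 95.0, 100.0])
        assert fit_standing_scale(3 * ee, 3 * basal) == \
            pytest.approx(fit_standing_scale(ee, basal))

    def test_cohort_with_known_ratio_recovered(self):
        subjects = gm.sample_subjects(6, seed=9)
        basal = [basal_power(s.info) for s in subjects]
        standing = [1.3 * b for b in basal]
        assert fit_standing_scale(standing, basal) == pytest.approx(1.3)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(gm.ParameterError):
            fit_standing_scale([100.0], [0.0])
        with pytest.raises(gm.ParameterError):
            gm.basal_standing_estimate(
                gm.SubjectInfo(1.75, 70, 30, "male"), standing_scale=-1.0)


class TestWeightSaliency:
    def _model_with_weights(self, w):
        from gaitmet.features import FeatureScaler
        n = w.size
        scaler = FeatureScaler(np.zeros(n), np.ones(n), np.zeros(n, dtype=bool))
        return gm.RidgeEEModel(w, 0.0, 1.0, scaler)

    def test_weights_proportional_to_std_give_similarity_one(self):
        rng = np.random.default_rng(4)
        rows = rng.normal(0, np.linspace(1, 4, 363), size=(200, 363))
        std = rows[:, :360].std(axis=0)
        model = self._model_with_weights(np.concatenate([2.5 * std, np.zeros(3)]))
        report = weight_saliency(model, rows)
        assert report["cosine_similarity"] == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_weights_give_zero(self):
        rows = np.zeros((10, 363))
        rows[:5, 0] = 1.0  # only feature 0 varies
        w = np.zeros(363)
        w[1] = 5.0  # weight mass on a feature with zero std
        report = weight_saliency(self._model_with_weights(w), rows)
        assert report["cosine_similarity"] == pytest.approx(0.0, abs=1e-12)

    def test_shares_normalize(self, toy_model):
        model, X, _ = toy_model
        report = weight_saliency(model, X)
        assert report["channel_share"].sum() == pytest.approx(1.0, abs=1e-12)
        assert report["bin_share"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_weights_undefined_similarity(self):
        report = weight_saliency(self._model_with_weights(np.zeros(363)),
                                 np.ones((5, 363)))
        assert report["cosine_similarity"] is None


class TestActivitySpecificModel:
    def test_fits_separate_scalar_models(self):
        rng = np.random.default_rng(6)
        scalars = rng.uniform([1.6, 55, 0.8], [1.9, 95, 1.3], size=(60, 3))
        acts = np.array(["walk"] * 30 + ["run"] * 30)
        y = np.where(acts == "walk", 200 + 100 * scalars[:, 2],
                     600 + 300 * scalars[:, 2])
        model = gm.ActivitySpecificModel.fit(scalars, y, acts)
        pred = model.predict(scalars, acts)
        assert np.corrcoef(pred, y)[0, 1] > 0.99
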