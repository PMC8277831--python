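import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitmet as gm
from gaitmet._errors import StrideRejected
from gaitmet.features import (N_FEATURES, N_KINEMATIC, bin_stride, fit_scaler,
                              feature_names, select_training_strides)
from gaitmet.segmentation import StrideSegment


class TestBinStride:
    def test_constant_signal_gives_constant_bins(self):
        assert np.allclose(bin_stride(np.full(300, 2.5)), 2.5)

    def test_index_signal_block_means(self):
        bins = bin_stride(np.arange(300, dtype=float))
        assert np.allclose(bins, 10 * np.arange(30) + 4.5)

    def test_uneven_partition_with_31_samples(self):
        x = np.arange(31, dtype=float)
        bins = bin_stride(x)
        # partition rule: block sizes differ by at most one (the longer block first)
        blocks = np.array_split(x, 30)
        sizes = sorted(len(b) for b in blocks)
        assert sizes == [1] * 29 + [2]
        assert np.allclose(bins, [b.mean() for b in blocks])

    def test_short_stride_rejected_not_dropped(self):
        with pytest.raises(StrideRejected):
            bin_stride(np.zeros(29))

    @settings(deadline=None, max_examples=30)
    @given(a=st.floats(-10, 10), b=st.floats(-10, 10),
           n=st.integers(30, 200), seed=st.integers(0, 99))
    def test_commutes_with_affine_transforms(self, a, b, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        assert np.allclose(bin_stride(a * x + b), a * bin_stride(x) + b,
                           atol=1e-9)


class TestAssembleFeatures:
    def _recording(self, chans):
        n = chans.shape[0]
        t = np.arange(n) / 100.0
        return gm.ImuRecording("shank", t, chans[:, :3], chans[:, 3:])

    def test_feature_vector_length_and_names(self, subject):
        rng = np.random.default_rng(0)
        shank = self._recording(rng.normal(size=(200, 6)))
        thigh = self._recording(rng.normal(size=(200, 6)))
        strides = [StrideSegment(0, 100, 0.0, 1.0), StrideSegment(100, 200, 1.0, 2.0)]
        X, accepted, rejections = gm.assemble_features(strides, shank, thigh, subject)
        assert X.shape == (2, N_FEATURES)
        assert N_KINEMATIC == 360
        assert len(feature_names()) == N_FEATURES
        assert feature_names()[0] == "shank_accel_X_bin00"
        assert feature_names()[-3:] == ["height_m", "mass_kg", "stride_duration_s"]
        assert rejections == []

    def test_zero_recordings_give_zero_kinematics_plus_scalars(self, subject):
        zeros = self._recording(np.zeros((100, 6)))
        strides = [StrideSegment(0, 100, 0.0, 1.0)]
        X, _, _ = gm.assemble_features(strides, zeros, zeros, subject)
        assert np.allclose(X[0, :360], 0.0)
        assert np.allclose(X[0, 360:], [subject.height, subject.mass, 1.0])

    def test_row_order_follows_stride_order(self, subject):
        rng = np.random.default_rng(1)
        shank = self._recording(rng.normal(size=(300, 6)))
        thigh = self._recording(rng.normal(size=(300, 6)))
        strides = [StrideSegment(0, 100, 0.0, 1.0),
                   StrideSegment(100, 200, 1.0, 2.0),
                   StrideSegment(200, 300, 2.0, 3.0)]
        X, _, _ = gm.assemble_features(strides, shank, thigh, subject)
        Xr, _, _ = gm.assemble_features(strides[::-1], shank, thigh, subject)
        assert np.allclose(Xr, X[::-1])

    def test_stride_past_recording_rejected_with_reason(self, subject):
        short = self._recording(np.zeros((50, 6)))
        strides = [StrideSegment(0, 100, 0.0, 1.0)]
        X, accepted, rejections = gm.assemble_features(strides, short, short, subject)
        assert X.shape[0] == 0 and accepted == []
        assert "extends past recording" in rejections[0]


class TestScaler:
    def test_training_rows_standardized_to_unit_moments(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5, 3, size=(40, 8))
        scaler = fit_scaler(X)
        Z = scaler.transform(X)
        assert np.max(np.abs(Z.mean(axis=0))) < 1e-9
        assert np.allclose(Z.std(axis=0), 1.0)

    def test_test_value_at_training_mean_maps_to_zero(self):
        X = np.array([[1.0, 10.0], [3.0, 20.0]])
        scaler = fit_scaler(X)
        assert np.allclose(scaler.transform([[2.0, 15.0]]), 0.0)

    def test_degenerate_feature_maps_everything_to_zero(self):
        X = np.array([[7.0, 1.0], [7.0, 2.0], [7.0, 3.0]])
        scaler = fit_scaler(X)
        Z = scaler.transform([[123.0, 2.0], [7.0, 2.0]])
        assert np.allclose(Z[:, 0], 0.0)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 99))
    def test_standardize_destandardize_is_identity(self, seed):
        X = np.random.default_rng(seed).normal(size=(15, 6))
        scaler = fit_scaler(X)
        assert np.max(np.abs(scaler.inverse_transform(scaler.transform(X)) - X)) < 1e-12


class TestSelectTrainingStrides:
    def test_last_fifty_of_120(self):
        out = select_training_strides(list(range(120)), k=50)
        assert out == list(range(70, 120))

    def test_fewer_than_k_returns_all_with_warning(self):
        with pytest.warns(UserWarning, match="30 strides"):
            out = select_training_strides(list(range(30)), k=50)
        assert out == list(range(30))

    def test_output_is_suffix(self):
        strides = [f"s{i}" for i in range(80)]
        out = select_training_strides(strides, k=50)
        assert strides[-len(out):] == out
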