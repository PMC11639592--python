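"""Window arithmetic, the 14-feature bank, and the z-score scaler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spineimu.errors import DataError
from spineimu.features import (CHANNELS, FEATURES_PER_CHANNEL, FeatureMatrix,
                               LabeledStream, WindowSpec, apply_scaler,
                               build_dataset, count_windows,
                               extract_window_features, feature_names,
                               fit_scaler, inverse_scaler)
from spineimu.imu_stream import ImuStream


def fidx(channel, feat):
    return feature_names().index(f"{channel}__{feat}")


def window_from_channel(x):
    """Put signal x on acc_x, zeros elsewhere."""
    w = np.zeros((len(x), 6))
    w[:, 0] = x
    return w


class TestCountWindows:
    def test_single_window(self):
        assert count_windows(300, WindowSpec(300, 1)) == 1

    def test_ten_seconds_at_stride_one_gives_701(self):
        assert count_windows(1000, WindowSpec(300, 1)) == 701

    def test_stride_50(self):
        assert count_windows(1000, WindowSpec(300, 50)) == 15

    def test_short_record_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero windows"):
            assert count_windows(200, WindowSpec(300, 1)) == 0

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 60))
    def test_matches_brute_force_enumeration(self, n, length, stride):
        w = WindowSpec(length, stride)
        brute = sum(1 for start in range(0, n, stride) if start + length <= n)
        if n < length:
            with pytest.warns(UserWarning):
                assert count_windows(n, w) == brute == 0
        else:
            assert count_windows(n, w) == brute


class TestFeatureBank:
    def test_vector_length_and_names(self):
        names = feature_names()
        assert len(names) == 84 == len(CHANNELS) * len(FEATURES_PER_CHANNEL)
        assert len(FEATURES_PER_CHANNEL) == 14
        assert len(set(names)) == 84
        v = extract_window_features(np.zeros((300, 6)))
        assert v.shape == (84,)

    def test_constant_channel(self):
        v = extract_window_features(window_from_channel(np.full(300, 5.0)))
        expect = {"mean": 5.0, "std": 0.0, "rms": 5.0, "median": 5.0,
                  "skewness": 0.0, "kurtosis": 0.0, "waveform_length": 0.0,
                  "zero_crossings": 0.0, "slope_sign_changes": 0.0,
                  "mean_absolute_value": 5.0, "interquartile_range": 0.0,
                  "median_absolute_deviation": 0.0}
        for feat, val in expect.items():
            assert v[fidx("acc_x", feat)] == pytest.approx(val, abs=1e-12), feat

    def test_sinusoid_spectral_peak_and_zero_crossings(self):
        t = np.arange(300) / 100.0
        x = np.sin(2 * np.pi * 2.0 * t + 0.3)  # 2 Hz, phase avoids exact zeros
        v = extract_window_features(window_from_channel(x))
        assert v[fidx("acc_x", "spectral_peak_freq")] == pytest.approx(2.0)
        assert v[fidx("acc_x", "spectral_peak_index")] == 6.0  # 2 Hz * 300 / 100
        assert v[fidx("acc_x", "zero_crossings")] == 12.0  # 2 per cycle x 6 cycles

    def test_alternating_signal_wl_and_ssc(self):
        n = 300
        x = np.tile([1.0, -1.0], n // 2)
        v = extract_window_features(window_from_channel(x))
        assert v[fidx("acc_x", "waveform_length")] == 2.0 * (n - 1)
        assert v[fidx("acc_x", "slope_sign_changes")] == n - 2
        assert v[fidx("acc_x", "zero_crossings")] == n - 1

    def test_reversal_invariance(self, rng):
        """Reversing a window leaves WL, ZC, SSC, skew and spectra unchanged."""
        x = rng.normal(0, 1, 300)
        v_fwd = extract_window_features(window_from_channel(x))
        v_rev = extract_window_features(window_from_channel(x[::-1]))
        for feat in ("waveform_length", "zero_crossings", "slope_sign_changes",
                     "skewness", "mean", "std", "interquartile_range",
                     "spectral_peak_freq", "spectral_peak_index"):
            i = fidx("acc_x", feat)
            assert v_fwd[i] == pytest.approx(v_rev[i], abs=1e-9), feat

    def test_non_finite_rejected(self):
        w = np.zeros((300, 6))
        w[5, 2] = np.nan
        with pytest.raises(DataError):
            extract_window_features(w)

    def test_channel_major_order(self, rng):
        """A signal on gyr_y lands exactly in gyr_y's feature block."""
        w = np.zeros((300, 6))
        w[:, CHANNELS.index("gyr_y")] = rng.normal(0, 1, 300)
        v = extract_window_features(w)
        assert v[fidx("gyr_y", "std")] > 0
        assert v[fidx("acc_x", "std")] == 0.0


def make_labeled(n_samples, location="head", subject="S01", exercise="wall angel",
                 seed=0):
    rng = np.random.default_rng(seed)
    s = ImuStream("x", np.arange(n_samples), rng.normal(0, 1, (n_samples, 3)),
                  rng.normal(0, 1, (n_samples, 3)), rng.normal(0, 1, (n_samples, 3)))
    return LabeledStream(s, location, subject, exercise)


class TestBuildDataset:
    def test_ten_second_stream_gives_701_rows(self):
        fm = build_dataset([make_labeled(1000)], WindowSpec(300, 1))
        assert fm.X.shape == (701, 84)
        assert set(fm.labels) == {1}

    def test_short_stream_skipped_with_warning(self):
        streams = [make_labeled(1000), make_labeled(900, location="thorax")]
        with pytest.warns(UserWarning, match="skipped"):
            fm = build_dataset(streams, WindowSpec(300, 50))
        assert set(fm.labels) == {1}

    def test_row_order_deterministic(self):
        streams = [make_labeled(1000, subject="S02"),
                   make_labeled(1000, subject="S01", seed=1)]
        fm = build_dataset(streams, WindowSpec(300, 100))
        assert list(fm.groups[:8]) == ["S01"] * 8


class TestScaler:
    def test_exact_moments_two_points(self):
        X = np.array([[2.0], [4.0]])
        s = fit_scaler(X)
        assert s.mu[0] == 3.0 and s.sigma[0] == 1.0  # population std
        np.testing.assert_array_equal(apply_scaler(X, s), [[-1.0], [1.0]])

    def test_transformed_moments(self, rng):
        X = rng.normal(5, 3, (500, 7))
        Z = apply_scaler(X, fit_scaler(X))
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_not_idempotent(self, rng):
        X = rng.normal(5, 3, (50, 2))
        s = fit_scaler(X)
        once = apply_scaler(X, s)
        twice = apply_scaler(once, s)
        assert not np.allclose(once, twice)

    def test_inverse_roundtrip(self, rng):
        X = rng.normal(-2, 10, (100, 4))
        s = fit_scaler(X)
        np.testing.assert_allclose(inverse_scaler(apply_scaler(X, s), s), X,
                                   atol=1e-12)

    def test_zero_variance_column_floored(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            s = fit_scaler(X)
        assert s.sigma[0] == 1e-12

    def test_feature_names_roundtrip(self, tmp_path):
        fm = build_dataset([make_labeled(1000)], WindowSpec(300, 50))
        fm.save(tmp_path / "fm.csv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "fm.csv")
        assert list(back.columns) == feature_names()
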