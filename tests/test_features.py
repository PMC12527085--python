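import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_window_count, sort_percentile, two_pass_mean_sd
from sitseg.errors import DegenerateFeatureError, ParameterError
from sitseg.features import (FEATURE_COLUMNS, NormalizationParams, WindowSpec,
                             apply_normalization, compute_features,
                             fit_normalization, invert_normalization,
                             window_indices)
from sitseg.preprocess import CHANNEL_ORDER, ProcessedSignals

FS = 50.0


def _processed(channel_arrays):
    return ProcessedSignals(fs=FS, channels={
        c: np.asarray(channel_arrays.get(c, np.zeros(
            len(next(iter(channel_arrays.values()))))), float)
        for c in CHANNEL_ORDER})


class TestWindowSpec:
    def test_defaults(self):
        spec = WindowSpec()
        assert spec.length_n(FS) == 50
        assert spec.step_n(FS) == 5

    def test_invalid_overlap(self):
        with pytest.raises(ParameterError):
            WindowSpec(overlap_fraction=1.0)


class TestWindowIndices:
    def test_canonical_example(self):
        idx = window_indices(150, WindowSpec(), FS)
        assert len(idx) == 21
        assert tuple(idx[0]) == (0, 50)
        assert tuple(idx[-1]) == (100, 150)
        assert [s for s, _ in idx] == brute_force_window_count(150, 50, 5)

    @pytest.mark.parametrize("n,expected", [(50, 1), (49, 0)])
    def test_boundaries(self, n, expected):
        assert len(window_indices(n, WindowSpec(), FS)) == expected

    def test_consecutive_overlap_is_45_samples(self):
        idx = window_indices(500, WindowSpec(), FS)
        overlaps = idx[:-1, 1] - idx[1:, 0]
        assert np.all(overlaps == 45)


class TestComputeFeatures:
    def test_exactly_32_features(self):
        assert len(FEATURE_COLUMNS) == 32
        df = compute_features(_processed({"acc_x": np.random.default_rng(0)
                                          .normal(size=200)}), WindowSpec())
        assert [c for c in df.columns if c in FEATURE_COLUMNS] == \
            list(FEATURE_COLUMNS)

    def test_constant_window_degenerate_stats(self):
        df = compute_features(
            _processed({c: np.full(100, i + 1.0)
                        for i, c in enumerate(CHANNEL_ORDER)}), WindowSpec())
        for i, chan in enumerate(CHANNEL_ORDER):
            np.testing.assert_allclose(df[f"{chan}_mean"], i + 1.0)
            np.testing.assert_allclose(df[f"{chan}_sd"], 0.0, atol=1e-12)

    def test_ramp_matches_two_pass_oracle(self):
        ramp = np.arange(60, dtype=float)
        df = compute_features(_processed({"acc_x": ramp}), WindowSpec())
        for row, (start, _) in zip(df.itertuples(), [(0, 50), (5, 55)]):
            mean, sd = two_pass_mean_sd(list(ramp[start:start + 50]))
            assert row.acc_x_mean == pytest.approx(mean, abs=1e-12)
            assert row.acc_x_sd == pytest.approx(sd, abs=1e-12)

    def test_feature_count_independent_of_fs(self):
        ps = ProcessedSignals(fs=32.0, channels={
            c: np.zeros(64) for c in CHANNEL_ORDER})
        df = compute_features(ps, WindowSpec())
        assert sum(c in FEATURE_COLUMNS for c in df.columns) == 32

    def test_short_signal_yields_empty_matrix(self, caplog):
        df = compute_features(_processed({"acc_x": np.zeros(10)}),
                              WindowSpec())
        assert len(df) == 0
        assert list(df.columns[3:]) == list(FEATURE_COLUMNS)


def _fm(values_per_feature):
    n = len(next(iter(values_per_feature.values())))
    base = {c: np.zeros(n) + np.arange(n) for c in FEATURE_COLUMNS}
    base.update(values_per_feature)
    return pd.DataFrame({"window_start_s": np.arange(n) * 0.1,
                         "subject_id": "s", "trial_id": "t", **base})


class TestNormalization:
    def test_percentiles_of_0_to_100(self):
        fm = _fm({"acc_x_mean": np.arange(101.0)})
        params = fit_normalization(fm)
        assert params.p5["acc_x_mean"] == pytest.approx(
            sort_percentile(range(101), 5))
        assert params.p95["acc_x_mean"] == pytest.approx(95.0)
        assert params.p5["acc_x_mean"] == pytest.approx(5.0)

    def test_degenerate_feature_named(self):
        fm = _fm({"gyr_z_sd": np.full(101, 2.0)})
        with pytest.raises(DegenerateFeatureError, match="gyr_z_sd"):
            fit_normalization(fm)

    def test_pooling_equals_concatenation(self):
        rng = np.random.default_rng(0)
        a = _fm({"acc_x_mean": rng.normal(size=40)})
        b = _fm({"acc_x_mean": rng.normal(size=60)})
        pooled = fit_normalization([a, b])
        concat = fit_normalization(pd.concat([a, b], ignore_index=True))
        pd.testing.assert_series_equal(pooled.p5, concat.p5)
        pd.testing.assert_series_equal(pooled.p95, concat.p95)

    def test_forced_values(self):
        fm = _fm({"acc_x_mean": np.array([2.0, 6.0, 10.0] + list(
            np.linspace(2, 10, 98)))})
        params = fit_normalization(fm)
        lo, hi = params.p5["acc_x_mean"], params.p95["acc_x_mean"]
        probe = _fm({"acc_x_mean": np.array([lo, hi, (lo + hi) / 2])})[:3]
        out = apply_normalization(probe, params)
        np.testing.assert_allclose(
            out["acc_x_mean"].to_numpy()[:3], [-1.0, 1.0, 0.0], atol=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_round_trip_exact(self, seed):
        rng = np.random.default_rng(seed)
        fm = _fm({c: rng.normal(scale=10, size=50) for c in FEATURE_COLUMNS})
        params = fit_normalization(fm)
        back = invert_normalization(apply_normalization(fm, params), params)
        for c in FEATURE_COLUMNS:
            np.testing.assert_allclose(back[c], fm[c], atol=1e-11)

    def test_no_clipping_beyond_percentiles(self):
        fm = _fm({"acc_x_mean": np.arange(101.0)})
        params = fit_normalization(fm)
        out = apply_normalization(fm, params)
        assert out["acc_x_mean"].max() > 1.0
        assert out["acc_x_mean"].min() < -1.0

    def test_csv_round_trip(self, tmp_path):
        fm = _fm({"acc_x_mean": np.arange(101.0)})
        params = fit_normalization(fm)
        params.to_csv(tmp_path / "norm.csv")
        back = NormalizationParams.from_csv(tmp_path / "norm.csv")
        pd.testing.assert_series_equal(back.p5, params.p5, check_names=False)
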