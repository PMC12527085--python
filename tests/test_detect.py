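import numpy as np
import pandas as pd
import pytest

from sitseg.detect import (TrialWindows, WindowLabels, crossvalidate,
                           label_windows, oob_error_curve, predict_windows,
                           train_forest)
from sitseg.errors import ParameterError, SchemaError, TrainingError
from sitseg.features import FEATURE_COLUMNS, WindowSpec
from sitseg.signal_io import SIT, TRANSITION, LabelTrack


def _fm(starts):
    return pd.DataFrame({"window_start_s": starts, "subject_id": "s",
                         "trial_id": "t",
                         **{c: 0.0 for c in FEATURE_COLUMNS}})


class TestLabelWindows:
    def test_full_overlap_positive(self):
        track = LabelTrack([(10.0, 20.0, SIT)], duration_s=30.0)
        wl = label_windows(_fm([12.0]), track)
        assert wl.sit[0] == 1 and wl.transition[0] == 0

    def test_30_percent_overlap_negative(self):
        track = LabelTrack([(10.0, 10.3, TRANSITION)], duration_s=30.0)
        wl = label_windows(_fm([9.3]), track)  # overlap exactly 0.3 s
        assert wl.transition[0] == 0

    def test_exactly_half_overlap_positive(self):
        track = LabelTrack([(10.0, 20.0, SIT)], duration_s=30.0)
        wl = label_windows(_fm([9.5]), track)  # window [9.5, 10.5): 0.5 s in
        assert wl.sit[0] == 1


def _blobs(n=500, sep=6.0, d=8, seed=0):
    """Two well-separated Gaussian blobs; linearly separable in practice."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(size=(n, d))
    X[y == 1, :3] += sep
    return X, y


def _nearest_centroid_error(Xtr, ytr, Xte, yte):
    c0, c1 = Xtr[ytr == 0].mean(axis=0), Xtr[ytr == 1].mean(axis=0)
    pred = (np.linalg.norm(Xte - c1, axis=1) <
            np.linalg.norm(Xte - c0, axis=1)).astype(int)
    return np.mean(pred != yte)


class TestTrainForest:
    def test_separable_blobs_low_oob(self):
        X, y = _blobs()
        # independent sanity oracle: the task is trivially solvable
        Xte, yte = _blobs(seed=1)
        assert _nearest_centroid_error(X, y, Xte, yte) == 0.0
        tf = train_forest(X, y, n_trees=25, seed=0)
        assert tf.oob_error < 0.05

    def test_permuted_labels_hit_baseline(self):
        X, y = _blobs(n=600)
        rng = np.random.default_rng(1)
        y_perm = rng.permutation(y)
        tf = train_forest(X, y_perm, n_trees=25, seed=0)
        baseline = min(np.mean(y_perm), 1 - np.mean(y_perm))
        assert abs(tf.oob_error - baseline) <= 0.1

    def test_deterministic_given_seed(self):
        X, y = _blobs(n=200)
        a = train_forest(X, y, n_trees=10, seed=5)
        b = train_forest(X, y, n_trees=10, seed=5)
        assert a.oob_error == b.oob_error
        assert a.repeat_index == b.repeat_index
        assert a.repeat_oob_errors == b.repeat_oob_errors

    def test_best_of_repeats_selected(self):
        X, y = _blobs(n=300, sep=1.0)
        tf = train_forest(X, y, n_trees=5, n_repeats=5, seed=2)
        assert tf.oob_error == min(tf.repeat_oob_errors)
        assert len(tf.repeat_oob_errors) == 5

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(TrainingError):
            train_forest(X, np.zeros(10), n_trees=5)


class TestOobCurve:
    def test_curve_shape_and_plateau(self):
        X, y = _blobs(n=400)
        curve = oob_error_curve(X, y, max_trees=15, n_runs=3, seed=0)
        assert len(curve.mean) == 15
        assert np.all(curve.tree_counts == np.arange(1, 16))
        assert curve.mean[-1] <= curve.mean[0]

    def test_single_run_sd_zero(self):
        X, y = _blobs(n=200)
        curve = oob_error_curve(X, y, max_trees=5, n_runs=1, seed=0)
        np.testing.assert_allclose(curve.sd, 0.0)


class TestPredictWindows:
    def test_resubstitution_beats_oob(self):
        X, y = _blobs()
        tf = train_forest(X, y, n_trees=25, seed=0)
        resub = np.mean(predict_windows(tf, X) != y)
        assert resub <= tf.oob_error

    def test_empty_input(self):
        X, y = _blobs(n=100)
        tf = train_forest(X, y, n_trees=5, seed=0)
        assert len(predict_windows(tf, np.empty((0, X.shape[1])))) == 0

    def test_deterministic(self):
        X, y = _blobs(n=100)
        tf = train_forest(X, y, n_trees=5, seed=0)
        np.testing.assert_array_equal(predict_windows(tf, X),
                                      predict_windows(tf, X))

    def test_schema_mismatch(self):
        X, y = _blobs(n=100)
        tf = train_forest(X, y, n_trees=5, seed=0)
        with pytest.raises(SchemaError):
            predict_windows(tf, np.zeros((4, X.shape[1] + 1)))


def _toy_trials(n_subjects=6):
    """Tiny synthetic trials with informative features for CV wiring tests."""
    rng = np.random.default_rng(0)
    trials = []
    for i in range(n_subjects):
        n = 80
        starts = np.arange(n) * 0.1
        sit = (starts % 4.0) < 2.0
        fm = _fm(starts)
        for c in FEATURE_COLUMNS:
            fm[c] = rng.normal(0, 0.1, n)
        fm["acc_x_mean"] = sit + rng.normal(0, 0.05, n)
        track = LabelTrack([(0.0, 1.0, SIT)], duration_s=10.0)
        trials.append(TrialWindows(
            subject_id=f"S{i}", trial_id="T0", features=fm,
            labels=WindowLabels(transition=sit.astype(int) ^ 1,
                                sit=sit.astype(int)),
            label_track=track))
    return trials


class TestCrossvalidate:
    def test_subject_partition(self):
        trials = _toy_trials(6)
        cv = crossvalidate(trials, k=3, seed=0, transition_trees=5,
                           sit_trees=5, n_repeats=1)
        held_out = [u for fold in cv.folds for u in fold.test_units]
        assert sorted(held_out) == sorted({t.subject_id for t in trials})
        assert all(len(fold.test_units) == 2 for fold in cv.folds)
        assert set(cv.predictions) == {t.key for t in trials}

    def test_no_leakage_structurally(self):
        trials = _toy_trials(6)
        cv = crossvalidate(trials, k=3, seed=0, transition_trees=5,
                           sit_trees=5, n_repeats=1)
        from sitseg.features import fit_normalization
        for fold in cv.folds:
            assert not set(fold.train_units) & set(fold.test_units)
            train = [t for t in trials if t.subject_id in fold.train_units]
            expected = fit_normalization([t.features for t in train])
            pd.testing.assert_series_equal(
                fold.detector.normalization.p5, expected.p5)

    def test_same_seed_same_folds(self):
        trials = _toy_trials(6)
        a = crossvalidate(trials, k=3, seed=4, transition_trees=5,
                          sit_trees=5, n_repeats=1)
        b = crossvalidate(trials, k=3, seed=4, transition_trees=5,
                          sit_trees=5, n_repeats=1)
        assert [f.test_units for f in a.folds] == \
            [f.test_units for f in b.folds]
        for key in a.predictions:
            np.testing.assert_array_equal(a.predictions[key]["sit"],
                                          b.predictions[key]["sit"])

    def test_too_few_groups(self):
        with pytest.raises(ParameterError):
            crossvalidate(_toy_trials(3), k=10)
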