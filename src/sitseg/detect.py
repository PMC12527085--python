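"""Window labeling, twin random-forest training and cross-validation.

Two bagged-tree classifiers are trained on the same 32-feature windows:

* the *Transition* model detects stand-to-sit and sit-to-stand postural
  transitions (default ensemble size 35 trees);
* the *Sit* model detects the seated state itself (default 25 trees).

Ensemble sizes were chosen from out-of-bag (OOB) error curves, which this
module can recompute (:func:`oob_error_curve`). Training repeats each fit
five times with independent bootstrap streams and keeps the repeat with the
smallest OOB error. Cross-validation is subject-grouped by default so that
no subject contributes windows to both the training and test side of a fold,
and normalization percentiles are refit on each fold's training split only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ParameterError, SchemaError, TrainingError
from .features import (FEATURE_COLUMNS, NormalizationParams, WindowSpec,
                       apply_normalization, fit_normalization)
from .signal_io import SIT, TRANSITION, LabelTrack

logger = logging.getLogger(__name__)

DEFAULT_TRANSITION_TREES = 35
DEFAULT_SIT_TREES = 25
DEFAULT_N_REPEATS = 5

# fixed tags mixed into SeedSequence entropy so the per-repeat, per-fold and
# per-run streams are distinct but reproducible from one master seed
_TAG_REPEAT, _TAG_RUN, _TAG_FOLD = 101, 202, 303


@dataclass
class WindowLabels:
    """Binary per-window targets aligned to a feature matrix's rows."""

    transition: np.ndarray
    sit: np.ndarray

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=int)
        self.sit = np.asarray(self.sit, dtype=int)
        if self.transition.shape != self.sit.shape:
            raise ParameterError("label arrays must have equal length")


def label_windows(features: pd.DataFrame, track: LabelTrack,
                  spec: WindowSpec = WindowSpec(),
                  min_overlap: float = 0.5) -> WindowLabels:
    """Label each window positive for a class iff at least ``min_overlap``
    of its time span lies inside that class's intervals (inclusive)."""
    starts = features["window_start_s"].to_numpy(dtype=float)
    length = spec.length_s

    def occupancy(label: str) -> np.ndarray:
        cover = np.zeros(len(starts))
        for s, e in track.intervals_for(label):
            cover += np.clip(np.minimum(e, starts + length) - np.maximum(s, starts),
                             0.0, None)
        return cover

    thresh = min_overlap * length - 1e-9
    return WindowLabels(
        transition=(occupancy(TRANSITION) >= thresh).astype(int),
        sit=(occupancy(SIT) >= thresh).astype(int),
    )


# ---------------------------------------------------------------------------
# forests


@dataclass
class TrainedForest:
    """A fitted forest plus its OOB diagnostics and training metadata."""

    model: RandomForestClassifier
    oob_error: float
    repeat_index: int
    repeat_oob_errors: list
    n_trees: int
    seed: int
    feature_names: tuple | None = FEATURE_COLUMNS  # None: positional matrix


@dataclass
class DetectorPair:
    """The Transition and Sit forests trained on the same windows."""

    transition: TrainedForest
    sit: TrainedForest
    normalization: NormalizationParams | None = None


@dataclass
class OobCurve:
    """OOB error as a function of ensemble size, over repeated runs."""

    tree_counts: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    runs: np.ndarray  # shape (n_runs, max_trees)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_trees": self.tree_counts,
                             "oob_error_mean": self.mean,
                             "oob_error_sd": self.sd})

    def plot(self, ax=None, **kwargs):
        """Mean OOB error vs ensemble size with a +/-1 SD band."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.tree_counts, self.mean, **kwargs)
        ax.fill_between(self.tree_counts, self.mean - self.sd,
                        self.mean + self.sd, alpha=0.3)
        ax.set_xlabel("number of grown trees")
        ax.set_ylabel("out-of-bag classification error")
        return ax


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
        if missing:
            raise SchemaError(f"feature matrix missing columns {missing}")
        return features[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float32)
    return np.asarray(features, dtype=np.float32)


def _oob_vote_error_curve(forest: RandomForestClassifier, X: np.ndarray,
                          y: np.ndarray) -> np.ndarray:
    """OOB misclassification rate after 1..n_estimators trees.

    For each tree, samples outside its bootstrap draw receive that tree's
    vote; the error at ensemble size k is the majority-vote error (ties
    count as class 0) over all samples with at least one vote so far.
    """
    n = len(y)
    votes = np.zeros((n, 2))
    has_vote = np.zeros(n, dtype=bool)
    errors = np.empty(len(forest.estimators_))
    for i, (est, sampled) in enumerate(
            zip(forest.estimators_, forest.estimators_samples_)):
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        oob_idx = np.flatnonzero(oob)
        if len(oob_idx):
            pred = est.predict(X[oob_idx]).astype(int)
            votes[oob_idx, pred] += 1.0
            has_vote |= oob
        if has_vote.any():
            maj = (votes[:, 1] > votes[:, 0]).astype(int)
            errors[i] = np.mean(maj[has_vote] != y[has_vote])
        else:
            errors[i] = np.nan
    return errors


def _fit_one(X: np.ndarray, y: np.ndarray, n_trees: int, rs: int,
             class_weight=None) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        min_samples_leaf=1,
        class_weight=class_weight,
        n_jobs=1,
        random_state=rs,
    )
    forest.fit(X, y)
    return forest


def train_forest(features, labels, n_trees: int,
                 n_repeats: int = DEFAULT_N_REPEATS, seed: int = 0,
                 class_weight=None) -> TrainedForest:
    """Train ``n_repeats`` forests and keep the one with smallest OOB error.

    Deterministic given ``seed``; the chosen repeat's index and all repeat
    OOB errors are recorded. Ties favor the earliest repeat.
    """
    X = _as_matrix(features)
    names = tuple(FEATURE_COLUMNS) if isinstance(features, pd.DataFrame) \
        else None
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise TrainingError(f"{len(X)} feature rows vs {len(y)} labels")
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    repeat_seeds = np.random.SeedSequence([int(seed), _TAG_REPEAT]).generate_state(
        n_repeats)
    best = None
    oob_errors = []
    for r in range(n_repeats):
        forest = _fit_one(X, y, n_trees, int(repeat_seeds[r]), class_weight)
        err = float(_oob_vote_error_curve(forest, X, y)[-1])
        oob_errors.append(err)
        if best is None or err < best[1]:
            best = (forest, err, r)
    model, err, r = best
    return TrainedForest(model=model, oob_error=err, repeat_index=r,
                         repeat_oob_errors=oob_errors, n_trees=n_trees,
                         seed=int(seed), feature_names=names)


def oob_error_curve(features, labels, max_trees: int, n_runs: int = 10,
                    seed: int = 0) -> OobCurve:
    """Mean +/- SD OOB error versus ensemble size over independent runs.

    Each run grows one ``max_trees`` forest and scores the OOB error after
    every tree, so the whole curve costs one fit per run.
    """
    X = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("labels contain a single class")
    run_seeds = np.random.SeedSequence([int(seed), _TAG_RUN]).generate_state(n_runs)
    runs = np.empty((n_runs, max_trees))
    for r in range(n_runs):
        forest = _fit_one(X, y, max_trees, int(run_seeds[r]))
        runs[r] = _oob_vote_error_curve(forest, X, y)
    return OobCurve(
        tree_counts=np.arange(1, max_trees + 1),
        mean=runs.mean(axis=0),
        sd=runs.std(axis=0, ddof=0),
        runs=runs,
    )


def predict_windows(trained: TrainedForest, features) -> np.ndarray:
    """Majority vote over trees, one 0/1 per window; exact ties break to 0."""
    n_expected = trained.model.n_features_in_
    if isinstance(features, pd.DataFrame):
        names = trained.feature_names or FEATURE_COLUMNS
        missing = [c for c in names if c not in features.columns]
        if missing:
            raise SchemaError(f"prediction input missing columns {missing}")
        X = features[list(names)].to_numpy(dtype=np.float32)
    else:
        X = np.asarray(features, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != n_expected:
            raise SchemaError(
                f"expected {n_expected} feature columns, got shape {X.shape}")
    if len(X) == 0:
        return np.empty(0, dtype=int)
    # leaves are grown pure, so predict_proba equals the tree-vote fraction
    proba = trained.model.predict_proba(X)[:, list(trained.model.classes_).index(1)]
    return (proba > 0.5).astype(int)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class TrialWindows:
    """One trial's (unnormalized) feature matrix, targets and ground truth."""

    subject_id: str
    trial_id: str
    features: pd.DataFrame
    labels: WindowLabels
    label_track: LabelTrack
    fs: float = 50.0

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.trial_id)


@dataclass
class FoldResult:
    fold_index: int
    train_units: list
    test_units: list
    detector: DetectorPair
    predictions: dict = field(default_factory=dict)
    # key -> dict(transition=..., sit=...) held-out window predictions


@dataclass
class CvResult:
    folds: list

    @property
    def predictions(self) -> dict:
        out = {}
        for fold in self.folds:
            out.update(fold.predictions)
        return out


def crossvalidate(trials, k: int = 10, grouping: str = "subject",
                  seed: int = 0,
                  transition_trees: int = DEFAULT_TRANSITION_TREES,
                  sit_trees: int = DEFAULT_SIT_TREES,
                  n_repeats: int = DEFAULT_N_REPEATS) -> CvResult:
    """Subject- or trial-grouped k-fold cross-validation of both forests.

    Normalization percentiles are refit on each fold's training rows only and
    applied to both splits, so held-out windows never influence training in
    any way. Held-out predictions cover every trial exactly once.
    """
    trials = list(trials)
    if grouping == "subject":
        units = sorted({t.subject_id for t in trials})
        unit_of = lambda t: t.subject_id
    elif grouping == "trial":
        units = sorted({t.key for t in trials})
        unit_of = lambda t: t.key
    else:
        raise ParameterError(f"unknown grouping {grouping!r}")
    if len(units) < k:
        raise ParameterError(f"{len(units)} {grouping} units < k={k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _TAG_FOLD]))
    order = list(rng.permutation(len(units)))
    fold_units = [sorted(units[i] for i in chunk)
                  for chunk in np.array_split(order, k)]

    folds = []
    for f, test_units in enumerate(fold_units):
        test_set = set(test_units)
        train = [t for t in trials if unit_of(t) not in test_set]
        test = [t for t in trials if unit_of(t) in test_set]
        norm = fit_normalization([t.features for t in train])
        train_X = pd.concat([apply_normalization(t.features, norm)
                             for t in train], ignore_index=True)
        y_trans = np.concatenate([t.labels.transition for t in train])
        y_sit = np.concatenate([t.labels.sit for t in train])
        fold_seed = int(np.random.SeedSequence(
            [int(seed), _TAG_FOLD, f]).generate_state(1)[0])
        pair = DetectorPair(
            transition=train_forest(train_X, y_trans, transition_trees,
                                    n_repeats=n_repeats, seed=fold_seed),
            sit=train_forest(train_X, y_sit, sit_trees,
                             n_repeats=n_repeats, seed=fold_seed + 1),
            normalization=norm,
        )
        preds = {}
        for t in test:
            tx = apply_normalization(t.features, norm)
            preds[t.key] = {
                "transition": predict_windows(pair.transition, tx),
                "sit": predict_windows(pair.sit, tx),
            }
        folds.append(FoldResult(fold_index=f,
                                train_units=sorted({unit_of(t) for t in train}),
                                test_units=list(test_units),
                                detector=pair, predictions=preds))
        logger.info("fold %d/%d: OOB transition=%.4f sit=%.4f", f + 1, k,
                    pair.transition.oob_error, pair.sit.oob_error)
    return CvResult(folds=folds)
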