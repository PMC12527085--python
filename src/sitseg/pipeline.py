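"""End-to-end glue: recordings -> windows -> detectors -> sit phases -> report.

These helpers compose the stage modules without adding behavior of their
own; the command-line interface and the test-suite acceptance checks both
run the pipeline through this module so they cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import DetectorPair, TrialWindows, label_windows, train_forest
from .errors import ParameterError
from .evaluate import EvalReport, aggregate_reports, evaluate_trial
from .features import (WindowSpec, apply_normalization, compute_features,
                       fit_normalization)
from .preprocess import preprocess_recording
from .segment import (SitPhases, merge_sit_phases, walking_from_labels,
                      windows_to_intervals)
from .signal_io import SIT, WALKING, ImuRecording, LabelTrack, \
    complement_intervals


def trial_windows(rec: ImuRecording, track: LabelTrack,
                  spec: WindowSpec = WindowSpec(),
                  min_overlap: float = 0.5,
                  acc_cutoff_hz: float = 0.5,
                  gyr_cutoff_hz: float = 4.0) -> TrialWindows:
    """Preprocess one recording and attach window features and targets."""
    processed = preprocess_recording(rec, acc_cutoff_hz, gyr_cutoff_hz)
    fm = compute_features(processed, spec, rec.subject_id, rec.trial_id)
    labels = label_windows(fm, track, spec, min_overlap)
    return TrialWindows(subject_id=rec.subject_id, trial_id=rec.trial_id,
                        features=fm, labels=labels, label_track=track,
                        fs=rec.fs)


def featurize_cohort(cohort, spec: WindowSpec = WindowSpec(),
                     min_overlap: float = 0.5) -> list:
    """Window features + targets for every (recording, labels) trial."""
    return [trial_windows(ct.recording, ct.labels, spec, min_overlap)
            for ct in cohort]


def fit_cohort_normalization(trials, scope: str = "pooled"):
    """P5/P95 params pooled over all trials, or one set per subject.

    Returns a single :class:`NormalizationParams` for ``scope="pooled"`` or
    a dict ``subject_id -> NormalizationParams`` for ``scope="per_subject"``.
    """
    if scope == "pooled":
        return fit_normalization([t.features for t in trials])
    if scope == "per_subject":
        out = {}
        for sid in sorted({t.subject_id for t in trials}):
            out[sid] = fit_normalization(
                [t.features for t in trials if t.subject_id == sid])
        return out
    raise ParameterError(f"unknown normalization scope {scope!r}")


def normalized_features(trial: TrialWindows, norm) -> pd.DataFrame:
    params = norm[trial.subject_id] if isinstance(norm, dict) else norm
    return apply_normalization(trial.features, params)


def train_detector_pair(trials, norm, transition_trees: int = 35,
                        sit_trees: int = 25, n_repeats: int = 5,
                        seed: int = 0) -> DetectorPair:
    """Train both forests on the pooled, normalized windows of ``trials``."""
    X = pd.concat([normalized_features(t, norm) for t in trials],
                  ignore_index=True)
    y_trans = np.concatenate([t.labels.transition for t in trials])
    y_sit = np.concatenate([t.labels.sit for t in trials])
    return DetectorPair(
        transition=train_forest(X, y_trans, transition_trees,
                                n_repeats=n_repeats, seed=seed),
        sit=train_forest(X, y_sit, sit_trees,
                         n_repeats=n_repeats, seed=seed + 1),
        normalization=None if isinstance(norm, dict) else norm,
    )


def segment_trial(transition_pred, sit_pred, trial: TrialWindows,
                  spec: WindowSpec = WindowSpec(),
                  gap_s: float = 1.5,
                  walking_mode: str = "labels",
                  walking_kwargs: dict | None = None) -> SitPhases:
    """Turn one trial's window predictions into final sit phases."""
    starts = trial.features["window_start_s"].to_numpy(float)
    sit_iv = windows_to_intervals(sit_pred, starts, spec)
    trans_iv = windows_to_intervals(transition_pred, starts, spec)
    if walking_mode == "labels":
        walking = walking_from_labels(trial.label_track)
        no_walking = complement_intervals(trial.label_track, WALKING)
    elif walking_mode == "detector":
        # recompute the processed channels; the stand-in detector needs them
        raise ParameterError(
            "walking_mode='detector' requires calling "
            "segment.detect_walking on ProcessedSignals explicitly")
    else:
        raise ParameterError(f"unknown walking mode {walking_mode!r}")
    return merge_sit_phases(sit_iv, trans_iv, no_walking, gap_s)


@dataclass
class PipelineEvaluation:
    per_trial: dict          # (subject_id, trial_id) -> EvalReport
    pooled: EvalReport
    phases: dict             # (subject_id, trial_id) -> SitPhases


def evaluate_predictions(trials, predictions: dict,
                         spec: WindowSpec = WindowSpec(),
                         gap_s: float = 1.5) -> PipelineEvaluation:
    """Segment and score per-trial window predictions against ground truth.

    ``predictions`` maps ``(subject_id, trial_id)`` to dicts with
    ``transition`` and ``sit`` 0/1 arrays (e.g. ``CvResult.predictions``).
    """
    per_trial, phases = {}, {}
    for t in trials:
        pred = predictions[t.key]
        sp = segment_trial(pred["transition"], pred["sit"], t, spec, gap_s)
        truth = t.label_track.intervals_for(SIT)
        per_trial[t.key] = evaluate_trial(
            sp.intervals, truth, t.label_track.duration_s, spec, t.fs)
        phases[t.key] = sp
    return PipelineEvaluation(
        per_trial=per_trial,
        pooled=aggregate_reports(per_trial.values()),
        phases=phases,
    )
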