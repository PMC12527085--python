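"""From window predictions to final sit phases.

Positive windows are expanded to their full 1 s spans and unioned into
detection intervals. The merge stage then applies four rules, in order:

(a) detections of the same class separated by less than 1.5 s are
    concatenated (strict inequality; the gap constant was tuned empirically
    on ambulatory recordings and is exposed as a parameter);
(b) Transition detections outside a no-Walking segment are discarded;
(c) Sit detections with no Transition detection in the same no-Walking
    segment are discarded;
(d) surviving Sit detections within one no-Walking segment are concatenated
    into a single sit phase spanning from the earliest to the latest.

A detection straddling a segment boundary is assigned to the no-Walking
segment holding the majority of its duration (ties to the earlier segment);
Sit detections are first clipped to the no-Walking portions since a final
sit phase must lie inside a no-Walking segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import WindowSpec, window_indices
from .preprocess import ProcessedSignals
from .signal_io import WALKING, LabelTrack

logger = logging.getLogger(__name__)

DEFAULT_GAP_S = 1.5

_EPS = 1e-9


def union_intervals(intervals) -> list:
    """Union of half-open intervals: sorted, disjoint, abutments merged."""
    ivs = sorted((float(s), float(e)) for s, e in intervals if e > s)
    out: list = []
    for s, e in ivs:
        if out and s <= out[-1][1] + _EPS:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def windows_to_intervals(predictions, window_start_s,
                         spec: WindowSpec = WindowSpec()) -> list:
    """Each positive window contributes its full span; overlaps are unioned."""
    predictions = np.asarray(predictions, dtype=int)
    starts = np.asarray(window_start_s, dtype=float)
    pos = starts[predictions == 1]
    return union_intervals((s, s + spec.length_s) for s in pos)


def concatenate_close(intervals, gap_s: float = DEFAULT_GAP_S) -> list:
    """Merge consecutive intervals whose gap is strictly below ``gap_s``."""
    ivs = union_intervals(intervals)
    out: list = []
    for s, e in ivs:
        # strict "less than", with a 1 ns guard so a gap of exactly gap_s
        # is never merged by floating-point rounding
        if out and s - out[-1][1] < gap_s - _EPS:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def walking_from_labels(track: LabelTrack) -> list:
    """Pass provided Walking annotations through verbatim (preferred mode)."""
    return track.intervals_for(WALKING)


def detect_walking(processed: ProcessedSignals,
                   spec: WindowSpec = WindowSpec(),
                   threshold_deg_s: float = 40.0,
                   min_duration_s: float = 2.0,
                   gap_s: float = DEFAULT_GAP_S) -> list:
    """Stand-in walking detector (NOT the validated gait algorithm).

    Marks walking where the windowed mean of the 4 Hz-filtered gyroscope
    magnitude exceeds ``threshold_deg_s``, concatenates close bouts and
    drops bouts shorter than ``min_duration_s``. Intended only to make the
    pipeline self-contained when no Walking annotations are supplied.
    """
    logger.warning("using the stand-in walking detector, not a validated "
                   "gait-detection algorithm")
    fs = processed.fs
    idx = window_indices(processed.n_samples, spec, fs)
    if len(idx) == 0:
        return []
    length, step = spec.length_n(fs), spec.step_n(fs)
    w = np.lib.stride_tricks.sliding_window_view(
        processed["lp_gyr_mag"], length)[::step][: len(idx)]
    pos = w.mean(axis=1) > threshold_deg_s
    ivs = windows_to_intervals(pos.astype(int), idx[:, 0] / fs, spec)
    ivs = concatenate_close(ivs, gap_s)
    return [(s, e) for s, e in ivs if e - s >= min_duration_s]


@dataclass
class SitPhase:
    start_s: float
    end_s: float
    segment_index: int          # which no-Walking segment produced it
    n_sit_detections: int
    n_transition_detections: int

    @property
    def interval(self) -> tuple:
        return (self.start_s, self.end_s)


@dataclass
class SitPhases:
    phases: list
    no_walking_segments: list

    @property
    def intervals(self) -> list:
        return [p.interval for p in self.phases]


def _majority_segment(interval, segments) -> int | None:
    """Index of the segment holding the largest share of the interval
    (ties to the earlier segment); None if it overlaps no segment."""
    s, e = interval
    best, best_ov = None, 0.0
    for i, (gs, ge) in enumerate(segments):
        ov = max(0.0, min(e, ge) - max(s, gs))
        if ov > best_ov + _EPS:
            best, best_ov = i, ov
    return best


def merge_sit_phases(sit_track, transition_track, no_walking_segments,
                     gap_s: float = DEFAULT_GAP_S) -> SitPhases:
    """Apply merge rules (a)-(d) and emit final sit phases.

    ``sit_track`` and ``transition_track`` are interval lists; the returned
    phases are disjoint and each lies within exactly one no-Walking segment.
    """
    segments = union_intervals(no_walking_segments)
    # (a) concatenate close detections within each track
    sit = concatenate_close(sit_track, gap_s)
    trans = concatenate_close(transition_track, gap_s)
    # (b) discard Transitions outside any no-Walking segment
    trans_seg = [_majority_segment(iv, segments) for iv in trans]
    active_segments = {g for g in trans_seg if g is not None}
    # (c) clip Sit detections to no-Walking portions, then keep only pieces
    # whose segment also holds a surviving Transition
    kept: dict = {}
    for s, e in sit:
        for g, (gs, ge) in enumerate(segments):
            cs, ce = max(s, gs), min(e, ge)
            if ce - cs > _EPS and g in active_segments:
                kept.setdefault(g, []).append((cs, ce))
    # (d) concatenate surviving Sit detections per segment into one phase
    phases = []
    for g in sorted(kept):
        pieces = kept[g]
        phases.append(SitPhase(
            start_s=min(p[0] for p in pieces),
            end_s=max(p[1] for p in pieces),
            segment_index=g,
            n_sit_detections=len(pieces),
            n_transition_detections=sum(1 for t in trans_seg if t == g),
        ))
    return SitPhases(phases=phases, no_walking_segments=segments)
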