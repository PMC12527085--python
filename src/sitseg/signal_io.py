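"""Reading, writing and validating IMU recordings and activity-interval labels.

The on-disk dialects are deliberately plain:

* IMU CSV — one header line, columns ``t,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z``,
  time in seconds, acceleration in g, angular velocity in deg/s.
* Label CSV — columns ``start_s,end_s,label`` with label one of
  ``SIT``, ``TRANSITION``, ``WALKING``.

Intervals are half-open ``[start, end)`` in seconds throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

SIT = "SIT"
TRANSITION = "TRANSITION"
WALKING = "WALKING"
VALID_LABELS = frozenset({SIT, TRANSITION, WALKING})

IMU_COLUMNS = ("t", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

#: conversion factors into the package's native units (g, deg/s)
_ACC_FACTORS = {"g": 1.0, "m/s2": 1.0 / 9.80665, "m/s^2": 1.0 / 9.80665}
_GYR_FACTORS = {"deg/s": 1.0, "rad/s": 180.0 / math.pi}

_TIME_TOL = 1e-6  # tolerated deviation of each timestamp step from 1/fs, seconds


@dataclass
class ImuRecording:
    """One trial's synchronized six-axis ankle signals at a fixed rate.

    Accelerations are in g, angular velocities in deg/s; ``t`` holds uniform
    sample timestamps in seconds.
    """

    subject_id: str
    trial_id: str
    fs: float
    t: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    gyr_x: np.ndarray
    gyr_y: np.ndarray
    gyr_z: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise IntegrityError(f"sampling rate must be positive, got {self.fs}")
        arrays = [self.t, self.acc_x, self.acc_y, self.acc_z,
                  self.gyr_x, self.gyr_y, self.gyr_z]
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise IntegrityError(f"channel lengths differ: {sorted(lengths)}")
        n = lengths.pop()
        if n < 1:
            raise IntegrityError("recording must contain at least one sample")
        if n > 1:
            dt = np.diff(np.asarray(self.t, dtype=float))
            if np.any(dt <= 0):
                raise IntegrityError("timestamps must be strictly increasing")
            dev = np.max(np.abs(dt - 1.0 / self.fs))
            if dev > _TIME_TOL:
                raise IntegrityError(
                    f"timestamps deviate from a uniform 1/fs grid by up to {dev:.3g} s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        """Trial duration under half-open sample semantics (n / fs)."""
        return self.n_samples / self.fs


@dataclass
class LabelTrack:
    """Activity intervals ``(start_s, end_s, label)`` over one trial.

    The constructor canonicalizes: intervals are validated, sorted by start,
    and overlapping or abutting intervals sharing a label are merged.
    """

    intervals: list = field(default_factory=list)
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        canon = []
        for start, end, label in self.intervals:
            if label not in VALID_LABELS:
                raise FormatError(f"unknown label {label!r}")
            if not end > start:
                raise FormatError(f"interval end {end} must exceed start {start}")
            if start < -_TIME_TOL or end > self.duration_s + _TIME_TOL:
                raise FormatError(
                    f"interval ({start}, {end}) outside trial [0, {self.duration_s}]"
                )
            canon.append((float(start), float(end), label))
        canon.sort(key=lambda iv: (iv[0], iv[1]))
        merged: list = []
        for iv in canon:
            for i in range(len(merged) - 1, -1, -1):
                s0, e0, lab0 = merged[i]
                if lab0 == iv[2] and iv[0] <= e0:
                    merged[i] = (s0, max(e0, iv[1]), lab0)
                    break
            else:
                merged.append(iv)
        merged.sort(key=lambda iv: (iv[0], iv[1]))
        self.intervals = merged

    def intervals_for(self, label: str) -> list:
        """Sorted, disjoint ``(start, end)`` pairs carrying ``label``."""
        return [(s, e) for s, e, lab in self.intervals if lab == label]

    def with_intervals(self, intervals) -> "LabelTrack":
        return replace(self, intervals=list(intervals))


def read_imu(path, subject_id: str = "", trial_id: str = "",
             fs: float | None = None,
             acc_units: str = "g", gyr_units: str = "deg/s") -> ImuRecording:
    """Read an IMU CSV, converting units into g and deg/s.

    ``fs`` is inferred from the timestamp column when not given.
    """
    if acc_units not in _ACC_FACTORS:
        raise FormatError(f"unknown acceleration units {acc_units!r}")
    if gyr_units not in _GYR_FACTORS:
        raise FormatError(f"unknown angular-velocity units {gyr_units!r}")
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"IMU file {path} is missing columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if fs is None:
        if len(t) < 2:
            raise FormatError(
                f"cannot infer sampling rate from a {len(t)}-sample file; pass fs"
            )
        fs = 1.0 / float(np.median(np.diff(t)))
    fa = _ACC_FACTORS[acc_units]
    fg = _GYR_FACTORS[gyr_units]
    return ImuRecording(
        subject_id=subject_id, trial_id=trial_id, fs=fs, t=t,
        acc_x=df["acc_x"].to_numpy(float) * fa,
        acc_y=df["acc_y"].to_numpy(float) * fa,
        acc_z=df["acc_z"].to_numpy(float) * fa,
        gyr_x=df["gyr_x"].to_numpy(float) * fg,
        gyr_y=df["gyr_y"].to_numpy(float) * fg,
        gyr_z=df["gyr_z"].to_numpy(float) * fg,
    )


def write_imu(rec: ImuRecording, path) -> None:
    """Write a recording in the IMU CSV dialect (native units, full precision)."""
    df = pd.DataFrame({
        "t": rec.t,
        "acc_x": rec.acc_x, "acc_y": rec.acc_y, "acc_z": rec.acc_z,
        "gyr_x": rec.gyr_x, "gyr_y": rec.gyr_y, "gyr_z": rec.gyr_z,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_labels(path, duration_s: float) -> LabelTrack:
    """Read a label CSV into a canonical :class:`LabelTrack`.

    An empty file (header only, or zero bytes) yields an empty track.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return LabelTrack([], duration_s)
    if df.empty:
        return LabelTrack([], duration_s)
    for col in ("start_s", "end_s", "label"):
        if col not in df.columns:
            raise FormatError(f"label file {path} is missing column {col!r}")
    rows = [(float(r.start_s), float(r.end_s), str(r.label))
            for r in df.itertuples()]
    return LabelTrack(rows, duration_s)


def write_labels(track: LabelTrack, path) -> None:
    df = pd.DataFrame(track.intervals, columns=["start_s", "end_s", "label"])
    df.to_csv(path, index=False, float_format="%.17g")


def complement_intervals(track: LabelTrack, label: str) -> list:
    """Maximal intervals of ``[0, duration)`` not covered by ``label``.

    With ``label=WALKING`` this yields the no-Walking segments that gate the
    sit-phase merge algorithm.
    """
    out = []
    cursor = 0.0
    for start, end in track.intervals_for(label):
        if start > cursor:
            out.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < track.duration_s:
        out.append((cursor, track.duration_s))
    return out
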