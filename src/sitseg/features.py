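"""Sliding-window feature extraction and percentile normalization.

Each trial is segmented into 1 s windows with 90 % overlap. Every window
contributes 32 features: mean and sample standard deviation of each of the
sixteen processed channels (raw and filtered acceleration and angular
velocity, per axis and magnitude).

Features are normalized with an affine map anchored at the 5th and 95th
percentiles of the pooled feature distribution,

    v_norm = (2 v - (P5 + P95)) / (P95 - P5),

so that v = P5 maps to -1 and v = P95 maps to +1. Values beyond the
percentiles map outside [-1, 1]; no clipping is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFeatureError, ParameterError
from .preprocess import CHANNEL_ORDER, ProcessedSignals

logger = logging.getLogger(__name__)

#: documented column order: raw-acc means, raw-acc SDs, raw-gyr means,
#: raw-gyr SDs, then the filtered equivalents.
FEATURE_COLUMNS = tuple(
    f"{chan}_{stat}"
    for group in (CHANNEL_ORDER[0:4], CHANNEL_ORDER[4:8],
                  CHANNEL_ORDER[8:12], CHANNEL_ORDER[12:16])
    for stat in ("mean", "sd")
    for chan in group
)

META_COLUMNS = ("window_start_s", "subject_id", "trial_id")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry (1 s windows, 90 % overlap by default)."""

    length_s: float = 1.0
    overlap_fraction: float = 0.9

    def __post_init__(self):
        if not 0 <= self.overlap_fraction < 1:
            raise ParameterError(
                f"overlap_fraction {self.overlap_fraction} must be in [0, 1)"
            )
        if self.length_s <= 0:
            raise ParameterError("window length must be positive")

    def length_n(self, fs: float) -> int:
        n = round(self.length_s * fs)
        if n < 2:
            raise ParameterError(f"window of {n} samples too short at fs={fs}")
        return n

    def step_n(self, fs: float) -> int:
        step = round(self.length_n(fs) * (1 - self.overlap_fraction))
        if step < 1:
            raise ParameterError("window step must be at least one sample")
        return step


def window_indices(n_samples: int, spec: WindowSpec, fs: float) -> np.ndarray:
    """All fully-contained window index pairs ``(start, end)``.

    Windows start at 0 and advance by ``step_n``; a trailing partial window is
    dropped. A signal shorter than one window yields an empty result.
    """
    length = spec.length_n(fs)
    step = spec.step_n(fs)
    if n_samples < length:
        logger.warning(
            "signal of %d samples shorter than one %d-sample window; no windows",
            n_samples, length,
        )
        return np.empty((0, 2), dtype=int)
    starts = np.arange(0, n_samples - length + 1, step)
    return np.column_stack([starts, starts + length])


def compute_features(processed: ProcessedSignals, spec: WindowSpec,
                     subject_id: str = "", trial_id: str = "") -> pd.DataFrame:
    """Per-window mean/SD features for all sixteen channels.

    Returns a DataFrame with the meta columns ``window_start_s``,
    ``subject_id``, ``trial_id`` followed by the 32 feature columns in
    :data:`FEATURE_COLUMNS` order. SD uses the n-1 denominator.
    """
    fs = processed.fs
    idx = window_indices(processed.n_samples, spec, fs)
    length = spec.length_n(fs)
    step = spec.step_n(fs)
    cols: dict = {}
    if len(idx) == 0:
        starts = np.empty(0)
        for chan in CHANNEL_ORDER:
            cols[f"{chan}_mean"] = starts.copy()
            cols[f"{chan}_sd"] = starts.copy()
    else:
        starts = idx[:, 0] / fs
        for chan in CHANNEL_ORDER:
            w = np.lib.stride_tricks.sliding_window_view(
                processed[chan], length)[::step][: len(idx)]
            cols[f"{chan}_mean"] = w.mean(axis=1)
            cols[f"{chan}_sd"] = w.std(axis=1, ddof=1)
    out = pd.DataFrame({
        "window_start_s": starts,
        "subject_id": subject_id,
        "trial_id": trial_id,
        **{name: cols[name] for name in FEATURE_COLUMNS},
    })
    return out


@dataclass
class NormalizationParams:
    """Per-feature 5th/95th percentiles anchoring the normalization map."""

    p5: pd.Series
    p95: pd.Series

    def __post_init__(self):
        for feat in self.p5.index:
            if not self.p95[feat] > self.p5[feat]:
                raise DegenerateFeatureError(feat)

    def to_csv(self, path) -> None:
        pd.DataFrame([self.p5, self.p95], index=["P5", "P95"]).to_csv(
            path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "NormalizationParams":
        df = pd.read_csv(path, index_col=0).astype(float)
        return cls(p5=df.loc["P5"], p95=df.loc["P95"])


def fit_normalization(feature_matrices) -> NormalizationParams:
    """Fit P5/P95 over the pooled rows of one or more feature matrices.

    Pooling several matrices is identical to fitting their concatenation.
    Percentiles use linear interpolation between order statistics.
    """
    if isinstance(feature_matrices, pd.DataFrame):
        feature_matrices = [feature_matrices]
    mats = [fm[list(FEATURE_COLUMNS)] for fm in feature_matrices]
    if not mats or sum(len(m) for m in mats) == 0:
        raise ParameterError("cannot fit normalization on an empty pool")
    pooled = pd.concat(mats, ignore_index=True) if len(mats) > 1 else mats[0]
    values = pooled.to_numpy(dtype=float)
    p5, p95 = np.percentile(values, [5, 95], axis=0)
    return NormalizationParams(
        p5=pd.Series(p5, index=list(FEATURE_COLUMNS)),
        p95=pd.Series(p95, index=list(FEATURE_COLUMNS)),
    )


def apply_normalization(features: pd.DataFrame,
                        params: NormalizationParams) -> pd.DataFrame:
    """Map each feature v to (2v - (P5+P95)) / (P95 - P5); meta columns pass through."""
    missing = [c for c in features.columns
               if c in FEATURE_COLUMNS and c not in params.p5.index]
    absent = [c for c in FEATURE_COLUMNS if c not in params.p5.index]
    if missing or absent:
        raise ParameterError(f"normalization params missing features {missing or absent}")
    out = features.copy()
    for col in FEATURE_COLUMNS:
        lo, hi = params.p5[col], params.p95[col]
        out[col] = (2.0 * features[col] - (lo + hi)) / (hi - lo)
    return out


def invert_normalization(features: pd.DataFrame,
                         params: NormalizationParams) -> pd.DataFrame:
    """Exact inverse of :func:`apply_normalization` (the map is affine)."""
    out = features.copy()
    for col in FEATURE_COLUMNS:
        lo, hi = params.p5[col], params.p95[col]
        out[col] = (features[col] * (hi - lo) + (lo + hi)) / 2.0
    return out
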