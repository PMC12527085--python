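"""Signal conditioning: zero-phase low-pass filtering and channel magnitudes.

Two filtered signal families are derived from each recording, both with
second-order zero-lag (forward-backward) Butterworth filters applied per axis:

* acceleration low-passed at 0.5 Hz — the slow, posture/gravity component
  that shifts when the wearer tilts into or out of a chair;
* angular velocity low-passed at 4 Hz — voluntary limb movement with
  higher-frequency content (including parkinsonian tremor at 4-6 Hz)
  attenuated.

Magnitudes of the raw axes are computed from the unfiltered data; magnitudes
of the filtered families are computed *after* filtering the axes (filter
first, magnitude second — the two orders are not equivalent because the
Euclidean norm is nonlinear).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import LengthError, ParameterError
from .signal_io import ImuRecording

#: fixed channel order used by the feature extractor
CHANNEL_ORDER = (
    "acc_x", "acc_y", "acc_z", "acc_mag",
    "gyr_x", "gyr_y", "gyr_z", "gyr_mag",
    "lp_acc_x", "lp_acc_y", "lp_acc_z", "lp_acc_mag",
    "lp_gyr_x", "lp_gyr_y", "lp_gyr_z", "lp_gyr_mag",
)

ACC_CUTOFF_HZ = 0.5
GYR_CUTOFF_HZ = 4.0


def lowpass_zero_lag(x: np.ndarray, fs: float, cutoff_hz: float,
                     order: int = 2) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase lag).

    The effective magnitude response of the double pass is |H(f)|^2 for the
    single-pass ``order``-degree filter. Edges are handled with reflective
    padding of length ``3 * (order + 1)`` samples.
    """
    if not 0 < cutoff_hz < fs / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fs / 2} Hz)"
        )
    x = np.asarray(x, dtype=float)
    padlen = 3 * (order + 1)
    if len(x) <= padlen:
        raise LengthError(
            f"signal of length {len(x)} too short for padlen {padlen}"
        )
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=fs)
    return sps.filtfilt(b, a, x, padtype="even", padlen=padlen)


def magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of three equal-length axis signals."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not len(x) == len(y) == len(z):
        raise ParameterError("axis signals must have equal length")
    return np.sqrt(x * x + y * y + z * z)


@dataclass
class ProcessedSignals:
    """The sixteen per-sample channels consumed by the feature extractor."""

    fs: float
    channels: dict  # name -> np.ndarray, keys = CHANNEL_ORDER

    @property
    def n_samples(self) -> int:
        return len(self.channels[CHANNEL_ORDER[0]])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def preprocess_recording(rec: ImuRecording,
                         acc_cutoff_hz: float = ACC_CUTOFF_HZ,
                         gyr_cutoff_hz: float = GYR_CUTOFF_HZ,
                         order: int = 2) -> ProcessedSignals:
    """Compute raw and filtered axes plus their magnitudes for one recording."""
    lp = lambda x, fc: lowpass_zero_lag(x, rec.fs, fc, order=order)
    lp_acc = {ax: lp(getattr(rec, f"acc_{ax}"), acc_cutoff_hz) for ax in "xyz"}
    lp_gyr = {ax: lp(getattr(rec, f"gyr_{ax}"), gyr_cutoff_hz) for ax in "xyz"}
    channels = {
        "acc_x": np.asarray(rec.acc_x, float),
        "acc_y": np.asarray(rec.acc_y, float),
        "acc_z": np.asarray(rec.acc_z, float),
        "acc_mag": magnitude(rec.acc_x, rec.acc_y, rec.acc_z),
        "gyr_x": np.asarray(rec.gyr_x, float),
        "gyr_y": np.asarray(rec.gyr_y, float),
        "gyr_z": np.asarray(rec.gyr_z, float),
        "gyr_mag": magnitude(rec.gyr_x, rec.gyr_y, rec.gyr_z),
        "lp_acc_x": lp_acc["x"], "lp_acc_y": lp_acc["y"], "lp_acc_z": lp_acc["z"],
        "lp_acc_mag": magnitude(lp_acc["x"], lp_acc["y"], lp_acc["z"]),
        "lp_gyr_x": lp_gyr["x"], "lp_gyr_y": lp_gyr["y"], "lp_gyr_z": lp_gyr["z"],
        "lp_gyr_mag": magnitude(lp_gyr["x"], lp_gyr["y"], lp_gyr["z"]),
    }
    return ProcessedSignals(fs=rec.fs, channels=channels)
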