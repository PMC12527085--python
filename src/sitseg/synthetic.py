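"""Synthetic ankle-IMU trials with ground-truth activity labels.

The generator emulates short free-living-style trials (3/4/5 min) in which a
wearer starts seated, repeatedly stands up, walks about, and sits back down.
The signal model is deliberately phenomenological rather than biomechanical:

* orientation — the device tilt angle moves between a standing value (0 deg)
  and a seated value (default 40 deg) along a smooth cosine ramp during each
  postural transition; the accelerometer records the gravity projection of
  that tilt (so the 0.5 Hz-low-passed acceleration shows two plateaus joined
  by a slow ramp), and the gyroscope records its analytic rate (a pulse of a
  few tens of deg/s during each transition);
* gait — walking bouts add a sinusoidal shank oscillation at the subject's
  gait frequency (default 0.8-1.2 Hz) to the gyroscope (large amplitude) and
  accelerometer (small amplitude), with short cosine on/off envelopes;
* tremor — an optional 4-6 Hz sinusoid, off by default;
* noise — white Gaussian noise per channel.

Sitting and standing are quiet apart from noise/tremor, so the long-run raw
acceleration magnitude in quiet states stays at 1 g.

All step durations are quantized to the sample grid so labeled interval
measures match the script exactly, and all randomness descends from one
master seed through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .signal_io import SIT, TRANSITION, WALKING, ImuRecording, LabelTrack

TRANSITION_DOWN = "TRANSITION_DOWN"
TRANSITION_UP = "TRANSITION_UP"
STAND = "STAND"
WALK = "WALK"

STATES = frozenset({SIT, TRANSITION_DOWN, TRANSITION_UP, STAND, WALK})


@dataclass(frozen=True)
class ScriptStep:
    state: str
    duration_s: float


@dataclass
class ActivityScript:
    """An ordered activity sequence for one trial.

    Trials start seated; every interior sit is entered through a
    stand-to-sit transition and left through a sit-to-stand transition.
    """

    steps: list

    def __post_init__(self):
        if not self.steps:
            raise ParameterError("empty script")
        for st in self.steps:
            if st.state not in STATES:
                raise ParameterError(f"unknown state {st.state!r}")
            if st.duration_s <= 0:
                raise ParameterError("step durations must be positive")
        if self.steps[0].state != SIT:
            raise ParameterError("trials must start seated")
        for i, st in enumerate(self.steps):
            if st.state == SIT:
                if i > 0 and self.steps[i - 1].state != TRANSITION_DOWN:
                    raise ParameterError(
                        "every sit after the first must follow a stand-to-sit"
                    )
                if i + 1 < len(self.steps) and \
                        self.steps[i + 1].state != TRANSITION_UP:
                    raise ParameterError(
                        "every non-final sit must be followed by a sit-to-stand"
                    )

    @property
    def total_duration_s(self) -> float:
        return sum(st.duration_s for st in self.steps)

    def count(self, state: str) -> int:
        return sum(1 for st in self.steps if st.state == state)


@dataclass(frozen=True)
class SimulationParams:
    """Generator configuration; defaults describe a low-noise cohort trial."""

    fs: float = 50.0
    n_sit_phases: int = 3
    sit_duration_range: tuple = (12.0, 25.0)
    transition_duration_range: tuple = (1.5, 3.0)
    stand_duration_range: tuple = (2.0, 6.0)
    min_walk_s: float = 3.0
    gait_freq_range: tuple = (0.8, 1.2)
    gait_gyro_amp_deg_s: float = 120.0
    gait_acc_amp_g: float = 0.15
    sit_tilt_deg: float = 40.0
    tremor_gyro_amp_deg_s: float = 0.0   # off by default
    tremor_acc_amp_g: float = 0.0
    tremor_freq_hz: float = 5.0
    tremor_freq_range: tuple = (4.0, 6.0)
    acc_noise_sd_g: float = 0.02
    gyr_noise_sd_deg_s: float = 1.0
    include_transitions_in_sit: bool = False

    def __post_init__(self):
        for name in ("gait_gyro_amp_deg_s", "gait_acc_amp_g",
                     "tremor_gyro_amp_deg_s", "tremor_acc_amp_g",
                     "acc_noise_sd_g", "gyr_noise_sd_deg_s"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        for f in (self.gait_freq_range[1], self.tremor_freq_hz,
                  self.tremor_freq_range[1]):
            if f >= self.fs / 2:
                raise ParameterError("component frequency above Nyquist")


def _quantize(duration_s: float, fs: float) -> float:
    return max(1, round(duration_s * fs)) / fs


def make_script(trial_duration_s: float, params: SimulationParams,
                rng: np.random.Generator) -> ActivityScript:
    """Randomized script: sit - up - mobility, repeated ``n_sit_phases`` times.

    The trial starts in the first sit phase (no initial stand-to-sit); every
    later sit is flanked by transitions, and consecutive sits are always
    separated by at least one walking bout so that distinct sit phases live
    in distinct no-Walking segments. Mobility blocks mix walking with
    optional quiet standing. Raises if the requested phases cannot fit.
    """
    fs = params.fs
    n = params.n_sit_phases
    if n < 1:
        raise ParameterError("need at least one sit phase")
    sits = [_quantize(rng.uniform(*params.sit_duration_range), fs)
            for _ in range(n)]
    ups = [_quantize(rng.uniform(*params.transition_duration_range), fs)
           for _ in range(n)]
    downs = [_quantize(rng.uniform(*params.transition_duration_range), fs)
             for _ in range(n - 1)]
    fixed = sum(sits) + sum(ups) + sum(downs)
    mobile_total = trial_duration_s - fixed
    if mobile_total < n * params.min_walk_s:
        raise ParameterError(
            f"{n} sit phases do not fit a {trial_duration_s} s trial: "
            f"{fixed:.1f} s of sitting/transitions leaves {mobile_total:.1f} s "
            f"for {n} walking bouts"
        )
    shares = rng.dirichlet(np.ones(n)) * (mobile_total - n * params.min_walk_s)
    blocks = [params.min_walk_s + s for s in shares]

    steps = []
    for i in range(n):
        if i > 0:
            steps.append(ScriptStep(TRANSITION_DOWN, downs[i - 1]))
        steps.append(ScriptStep(SIT, sits[i]))
        steps.append(ScriptStep(TRANSITION_UP, ups[i]))
        block = blocks[i]
        stand_lo = params.stand_duration_range[0]
        if block >= params.min_walk_s + stand_lo and rng.random() < 0.5:
            stand_d = _quantize(
                min(rng.uniform(*params.stand_duration_range),
                    block - params.min_walk_s), fs)
            walk_d = _quantize(block - stand_d, fs)
            if rng.random() < 0.5:
                steps.append(ScriptStep(STAND, stand_d))
                steps.append(ScriptStep(WALK, walk_d))
            else:
                steps.append(ScriptStep(WALK, walk_d))
                steps.append(ScriptStep(STAND, stand_d))
        else:
            steps.append(ScriptStep(WALK, _quantize(block, fs)))

    # absorb quantization drift into the final walking bout so the script
    # sums exactly to the requested trial duration
    total = sum(st.duration_s for st in steps)
    drift = _quantize(trial_duration_s, fs) - total
    for i in range(len(steps) - 1, -1, -1):
        if steps[i].state == WALK:
            new_d = steps[i].duration_s + drift
            if new_d <= 0:
                raise ParameterError("script packing failed: no room to adjust")
            steps[i] = ScriptStep(WALK, _quantize(new_d, fs))
            break
    return ActivityScript(steps)


def _cosine_ramp(tau: np.ndarray, duration: float) -> np.ndarray:
    """Smooth 0 -> 1 ramp over [0, duration]."""
    return 0.5 * (1.0 - np.cos(math.pi * np.clip(tau / duration, 0, 1)))


def synthesize(script: ActivityScript, params: SimulationParams,
               rng: np.random.Generator, subject_id: str = "sim",
               trial_id: str = "trial") -> tuple:
    """Render a script into an :class:`ImuRecording` and its ground truth.

    Returns ``(recording, label_track)``; the track carries SIT, TRANSITION
    and WALKING intervals exactly at the scripted boundaries (transitions are
    excluded from SIT unless ``include_transitions_in_sit``).
    """
    fs = params.fs
    counts = [round(st.duration_s * fs) for st in script.steps]
    n = int(sum(counts))
    t = np.arange(n) / fs
    theta = np.zeros(n)          # device tilt, deg
    dtheta = np.zeros(n)         # tilt rate, deg/s
    acc = np.zeros((3, n))
    gyr = np.zeros((3, n))

    tilt = params.sit_tilt_deg
    pos = 0
    intervals = []
    for st, c in zip(script.steps, counts):
        sl = slice(pos, pos + c)
        tau = (np.arange(c) + 0.5) / fs
        start_s, end_s = pos / fs, (pos + c) / fs
        if st.state == SIT:
            theta[sl] = tilt
            intervals.append((start_s, end_s, SIT))
        elif st.state == TRANSITION_DOWN:
            r = _cosine_ramp(tau, st.duration_s)
            theta[sl] = tilt * r
            dtheta[sl] = tilt * math.pi / (2 * st.duration_s) * np.sin(
                math.pi * tau / st.duration_s)
            intervals.append((start_s, end_s, TRANSITION))
        elif st.state == TRANSITION_UP:
            r = _cosine_ramp(tau, st.duration_s)
            theta[sl] = tilt * (1.0 - r)
            dtheta[sl] = -tilt * math.pi / (2 * st.duration_s) * np.sin(
                math.pi * tau / st.duration_s)
            intervals.append((start_s, end_s, TRANSITION))
        elif st.state == WALK:
            f = rng.uniform(*params.gait_freq_range) \
                if params.gait_freq_range[0] < params.gait_freq_range[1] \
                else params.gait_freq_range[0]
            phi = rng.uniform(0, 2 * math.pi)
            ramp = min(0.5, st.duration_s / 4)
            env = _cosine_ramp(tau, ramp) * _cosine_ramp(
                st.duration_s - tau, ramp)
            phase = 2 * math.pi * f * tau + phi
            ag, aa = params.gait_gyro_amp_deg_s, params.gait_acc_amp_g
            gyr[1, sl] += ag * env * np.sin(phase)
            gyr[0, sl] += 0.35 * ag * env * np.sin(phase + 1.3)
            gyr[2, sl] += 0.20 * ag * env * np.cos(phase)
            acc[0, sl] += aa * env * np.sin(phase)
            acc[2, sl] += 0.6 * aa * env * np.sin(2 * phase + 0.7)
            acc[1, sl] += 0.3 * aa * env * np.sin(phase + 2.1)
            intervals.append((start_s, end_s, WALKING))
        pos += c

    # gravity projection of the tilt (sagittal plane): x fore-aft, z vertical
    th = np.deg2rad(theta)
    acc[0] += np.sin(th)
    acc[2] += np.cos(th)
    gyr[1] += dtheta

    if params.tremor_gyro_amp_deg_s > 0 or params.tremor_acc_amp_g > 0:
        phi = rng.uniform(0, 2 * math.pi)
        tr = np.sin(2 * math.pi * params.tremor_freq_hz * t + phi)
        gyr[0] += params.tremor_gyro_amp_deg_s * tr
        gyr[2] += 0.5 * params.tremor_gyro_amp_deg_s * tr
        acc[0] += params.tremor_acc_amp_g * tr

    acc += rng.normal(0.0, params.acc_noise_sd_g, size=acc.shape)
    gyr += rng.normal(0.0, params.gyr_noise_sd_deg_s, size=gyr.shape)

    if params.include_transitions_in_sit:
        extra = [(s, e, SIT) for s, e, lab in intervals if lab == TRANSITION]
        intervals = intervals + extra

    rec = ImuRecording(subject_id=subject_id, trial_id=trial_id, fs=fs, t=t,
                       acc_x=acc[0], acc_y=acc[1], acc_z=acc[2],
                       gyr_x=gyr[0], gyr_y=gyr[1], gyr_z=gyr[2])
    track = LabelTrack(intervals, duration_s=n / fs)
    return rec, track


@dataclass(frozen=True)
class CohortTrial:
    recording: ImuRecording
    labels: LabelTrack


def subject_params(params: SimulationParams,
                   rng: np.random.Generator) -> SimulationParams:
    """Per-subject randomization: gait frequency and amplitude, seated tilt
    and (if enabled) tremor frequency are drawn once per subject."""
    f = rng.uniform(*params.gait_freq_range)
    return replace(
        params,
        gait_freq_range=(f, f),
        gait_gyro_amp_deg_s=params.gait_gyro_amp_deg_s * rng.uniform(0.7, 1.3),
        sit_tilt_deg=params.sit_tilt_deg * rng.uniform(0.8, 1.2),
        tremor_freq_hz=rng.uniform(*params.tremor_freq_range),
    )


def generate_cohort(n_subjects: int = 20,
                    trial_durations=(180.0, 240.0, 300.0),
                    params: SimulationParams | None = None,
                    master_seed: int = 0) -> list:
    """A reproducible cohort: ``n_subjects`` x ``len(trial_durations)`` trials.

    Every random draw descends from ``master_seed`` via SeedSequence
    spawning, so the same seed yields a byte-identical dataset.
    """
    if n_subjects < 1:
        raise ParameterError("need at least one subject")
    params = params or SimulationParams()
    cohort = []
    root = np.random.SeedSequence(int(master_seed))
    for i, subj_ss in enumerate(root.spawn(n_subjects)):
        subj_rng = np.random.default_rng(subj_ss.spawn(1)[0])
        sp = subject_params(params, subj_rng)
        sid = f"S{i + 1:02d}"
        for dur, trial_ss in zip(trial_durations,
                                 subj_ss.spawn(len(trial_durations))):
            rng = np.random.default_rng(trial_ss)
            script = make_script(float(dur), sp, rng)
            rec, track = synthesize(script, sp, rng, subject_id=sid,
                                    trial_id=f"T{int(dur)}s")
            cohort.append(CohortTrial(recording=rec, labels=track))
    return cohort
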