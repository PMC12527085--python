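"""Run configuration with documented defaults.

Defaults mirror the pipeline's published operating point: 1 s windows with
90 % overlap, 0.5 Hz / 4 Hz low-pass cutoffs, 35/25 trees, 10 folds,
5 training repeats and a 1.5 s concatenation gap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ParameterError
from .features import WindowSpec
from .synthetic import SimulationParams


@dataclass
class RunConfig:
    # signals & windows
    fs: float = 50.0
    window_length_s: float = 1.0
    window_overlap: float = 0.9
    acc_cutoff_hz: float = 0.5
    gyr_cutoff_hz: float = 4.0
    # normalization
    norm_scope: str = "pooled"            # "pooled" | "per_subject"
    # detectors
    transition_trees: int = 35
    sit_trees: int = 25
    n_repeats: int = 5
    k_folds: int = 10
    grouping: str = "subject"             # "subject" | "trial"
    min_overlap: float = 0.5
    # merge
    merge_gap_s: float = 1.5
    walking_mode: str = "labels"          # "labels" | "detector"
    walking_threshold_deg_s: float = 40.0
    walking_min_duration_s: float = 2.0
    # synthetic cohort
    n_subjects: int = 20
    trial_durations: tuple = (180.0, 240.0, 300.0)
    n_sit_phases: int = 3
    acc_noise_sd_g: float = 0.02
    gyr_noise_sd_deg_s: float = 1.0
    tremor_gyro_amp_deg_s: float = 0.0
    # randomness
    seed: int = 0

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(length_s=self.window_length_s,
                          overlap_fraction=self.window_overlap)

    @property
    def sim_params(self) -> SimulationParams:
        return SimulationParams(
            fs=self.fs,
            n_sit_phases=self.n_sit_phases,
            acc_noise_sd_g=self.acc_noise_sd_g,
            gyr_noise_sd_deg_s=self.gyr_noise_sd_deg_s,
            tremor_gyro_amp_deg_s=self.tremor_gyro_amp_deg_s,
        )

    def merged(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied; unknown keys error."""
        valid = {f.name for f in dataclasses.fields(self)}
        clean = {}
        for key, value in overrides.items():
            if value is None:
                continue
            if key not in valid:
                raise ParameterError(f"unknown configuration key {key!r}")
            clean[key] = value
        return dataclasses.replace(self, **clean)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} must hold a mapping")
        if "trial_durations" in data:
            data["trial_durations"] = tuple(data["trial_durations"])
        return cls().merged(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["trial_durations"] = list(self.trial_durations)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
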