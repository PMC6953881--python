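"""Pipeline configuration: every tunable threshold in one structure.

Defaults are the analysis conventions used throughout the package: 5-s
epochs, MVPA strictly above 100 mg, LPA 50-100 mg, 10-min bouts at 80%,
16-h valid days, at least 6 valid days with the first 6 kept, reliability
target 0.70 over up to 6 days. Configuration files (YAML) may override any
field; unknown keys are rejected so silent typos cannot change a dialect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # epoching / ENMO
    epoch_len: float = 5.0
    negatives: str = "truncate"  # or "absolute"
    abnormal_clip_g: float = 8.0
    # intensity cut-points (mg) and bouts
    lpa_low: float = 50.0
    mvpa_threshold: float = 100.0
    bout_min: float = 10.0
    bout_fraction: float = 0.8
    # day validity / analytical sample
    min_wear_hours: float = 16.0
    min_valid_days: int = 6
    k_keep: int = 6
    # reliability
    reliability_target: float = 0.70
    max_days: int = 6
    strict_target: bool = True
    # raw-signal non-wear detection
    nonwear_window_min: float = 60.0
    nonwear_step_min: float = 15.0
    nonwear_sd_mg: float = 13.0
    nonwear_range_mg: float = 50.0
    nonwear_axes_required: int = 2
    # epoch-only non-wear detection
    epoch_nonwear_sd_mg: float = 3.0
    epoch_nonwear_mean_mg: float = 3.0
    # autocalibration
    calib_still_sd_mg: float = 13.0
    calib_window_s: float = 10.0
    calib_max_iter: int = 100
    calib_tol_mg: float = 0.01
    # simulation
    seed: int = 0
    sim_fidelity: str = "epoch"  # construct | epoch | raw
    sim_n_subjects: int = 100
    sim_n_days: int = 7
    sim_start_date: str = "2010-03-01"
    sim_subject_sigma: float = 0.25
    sim_weekend_activity_factor: float = 0.7
    sim_noise_mg: float = 8.0
    sim_nonwear_per_day: float = 0.1
    sim_mu_construct: float = 50.0
    sim_sigma_between: float = 8.0
    sim_sigma_within: float = 10.0
    sim_weekend_shift: float = 0.0
    sim_sample_rate: float = 85.7
    sim_spike_rate: float = 0.0
    sim_axis_offsets: list[float] = field(default_factory=lambda: [0.0, 0.0, 0.0])
    sim_axis_gains: list[float] = field(default_factory=lambda: [1.0, 1.0, 1.0])

    def validate(self) -> None:
        def check(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise ConfigurationError(f"{name}: {msg}")

        check(self.epoch_len > 0, "epoch_len", "must be > 0")
        check(self.negatives in ("truncate", "absolute"), "negatives",
              "must be 'truncate' or 'absolute'")
        check(self.abnormal_clip_g > 0, "abnormal_clip_g", "must be > 0")
        check(0 < self.lpa_low < self.mvpa_threshold, "lpa_low",
              "must satisfy 0 < lpa_low < mvpa_threshold")
        check(self.bout_min > 0, "bout_min", "must be > 0")
        check(0 < self.bout_fraction <= 1, "bout_fraction", "must be in (0, 1]")
        check(0 < self.min_wear_hours <= 24, "min_wear_hours", "must be in (0, 24]")
        check(self.min_valid_days >= 2, "min_valid_days", "must be >= 2")
        check(2 <= self.k_keep <= self.min_valid_days, "k_keep",
              "must be in [2, min_valid_days]")
        check(0 < self.reliability_target < 1, "reliability_target", "must be in (0, 1)")
        check(self.max_days >= 1, "max_days", "must be >= 1")
        check(self.nonwear_axes_required in (1, 2, 3), "nonwear_axes_required",
              "must be 1, 2 or 3")
        check(self.sim_fidelity in ("construct", "epoch", "raw"), "sim_fidelity",
              "must be construct | epoch | raw")
        check(self.sim_n_subjects >= 1, "sim_n_subjects", "must be >= 1")
        check(self.sim_n_days >= 1, "sim_n_days", "must be >= 1")
        check(self.sim_sigma_within > 0, "sim_sigma_within", "must be > 0")
        check(self.sim_sample_rate > 0, "sim_sample_rate", "must be > 0")
        check(len(self.sim_axis_offsets) == 3, "sim_axis_offsets", "needs 3 entries")
        check(len(self.sim_axis_gains) == 3 and all(g > 0 for g in self.sim_axis_gains),
              "sim_axis_gains", "needs 3 positive entries")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {unknown}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def nondefault_fields(self) -> dict:
        """Fields deviating from the package defaults — logged at startup
        so every dialect choice is auditable."""
        default = PipelineConfig()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(default, f.name)
        }


def load_config(path: str | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return PipelineConfig.from_dict(data)
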