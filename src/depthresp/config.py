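"""Run configuration: every tunable of the pipeline in one place.

Defaults follow the published parameter choices where the method states
them (19 x 19 px unit areas slid every 10 px, 30 Hz resampling, 90%
cumulative-amplitude cutoff); the remaining knobs (smoothing window,
peak prominence, arm-width fraction, matching window) are this
package's own defaults and are logged on every run for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
import os

import yaml

from .errors import ValidationError

log = logging.getLogger("depthresp")

__all__ = ["RunConfig"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    unit_size: int = 19  # unit-area side, px
    stride: int = 10  # unit-area stride, px
    cutoff: float = 0.90  # cumulative amplitude-ratio crossing
    arm_width_fraction: float = 0.15  # of the shoulder-to-shoulder distance
    sample_rate_hz: float = 30.0  # uniform resampling clock
    window_s: float = 0.5  # smoothing window, s
    min_interval_s: float = 1.5  # min peak spacing (caps RR at 40 BPM)
    prominence_floor_mm: float = 0.5  # depth-signal peak prominence floor
    ref_prominence_floor_L: float = 0.05  # volume-signal prominence floor
    match_window_s: float = 2.0  # breath pairing window
    max_subject_depth_mm: float = 2000.0  # foreground segmentation threshold
    rr_error_threshold_bpm: float = 1.0
    alpha: float = 0.05  # significance level
    include_intercept: bool = True
    detector: str = "foreground"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unit_size < self.stride or self.stride < 1:
            raise ValidationError("need unit_size >= stride >= 1")
        if not 0 < self.cutoff <= 1:
            raise ValidationError("cutoff must be in (0, 1]")
        if not 0 <= self.arm_width_fraction < 0.5:
            raise ValidationError("arm_width_fraction must be in [0, 0.5)")
        for name in ("sample_rate_hz", "window_s", "min_interval_s", "match_window_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        """Load a YAML mapping; unknown keys are rejected, flag overrides win."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValidationError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def log_provenance(self) -> None:
        """Record the defaults the method statement leaves open."""
        log.info(
            "open-parameter provenance: window_s=%s min_interval_s=%s "
            "prominence_floor_mm=%s arm_width_fraction=%s match_window_s=%s",
            self.window_s,
            self.min_interval_s,
            self.prominence_floor_mm,
            self.arm_width_fraction,
            self.match_window_s,
        )
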