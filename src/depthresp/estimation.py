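"""Amplitude-to-volume calibration and per-breath TV/RR estimates.

Tidal volume is mapped from the depth excursion of a breath by a single
linear regression fitted against a reference (spirometer) volume:
TV = slope * amplitude + intercept, with the reference TV as the
objective variable and the depth amplitude as the explanatory variable.
A model is fitted per stratum (e.g. sex x clothing condition), pooled,
or per subject, depending on how the calibration pairs are grouped by
the caller.  Respiratory rate is the reciprocal of the peak-to-peak
interval, in breaths per minute.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
from scipy import stats

from .errors import FitError, SignalError, ValidationError
from .respsignal import BreathEvents

__all__ = [
    "CalibrationModel",
    "BreathEstimates",
    "fit_calibration",
    "estimate_tv",
    "estimate_rr",
    "breath_estimates",
]


@dataclasses.dataclass(frozen=True)
class CalibrationModel:
    """Linear amplitude (mm) -> tidal volume (L) mapping."""

    slope: float  # L per mm
    intercept: float  # L
    r_squared: float
    n: int
    label: str = "pooled"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("calibration needs at least 2 breaths")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValidationError("non-finite calibration coefficients")

    def to_json(self, path: str | os.PathLike, config_echo: dict | None = None) -> None:
        doc = {
            "slope_L_per_mm": self.slope,
            "intercept_L": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "label": self.label,
            "config": config_echo or {},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "CalibrationModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            slope=float(doc["slope_L_per_mm"]),
            intercept=float(doc["intercept_L"]),
            r_squared=float(doc["r_squared"]),
            n=int(doc["n"]),
            label=str(doc.get("label", "pooled")),
        )


@dataclasses.dataclass(frozen=True)
class BreathEstimates:
    """Per-breath quantities anchored at each breath's peak time.

    Only breaths with a defined peak-to-peak interval are kept (the
    leading breath of a recording has none), so tv, rr and peak time are
    parallel arrays.
    """

    peak_time_s: np.ndarray
    tv_L: np.ndarray
    rr_bpm: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        n = self.peak_time_s.size
        for arr in (self.tv_L, self.rr_bpm, self.amplitude):
            if arr.size != n:
                raise ValidationError("per-breath arrays must be parallel")
        if n and not np.all(self.rr_bpm > 0):
            raise ValidationError("rr_bpm must be positive")

    @property
    def n_breaths(self) -> int:
        return int(self.peak_time_s.size)


def fit_calibration(
    amplitudes_mm: np.ndarray,
    tv_ref_L: np.ndarray,
    label: str = "pooled",
    include_intercept: bool = True,
) -> CalibrationModel:
    """Ordinary least squares of reference TV on depth amplitude."""
    a = np.asarray(amplitudes_mm, float)
    v = np.asarray(tv_ref_L, float)
    if a.shape != v.shape or a.ndim != 1:
        raise ValidationError("amplitudes and volumes must be equal-length 1-D")
    if a.size < 2:
        raise FitError("need at least 2 calibration breaths")
    if np.var(a) == 0:
        raise FitError("zero amplitude variance; regression undefined")
    if include_intercept:
        res = stats.linregress(a, v)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    else:
        slope = float(np.dot(a, v) / np.dot(a, a))
        intercept = 0.0
        ss_res = float(np.sum((v - slope * a) ** 2))
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(float(slope), float(intercept), float(r2), a.size, label)


def estimate_tv(
    model: CalibrationModel,
    amplitudes_mm: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Per-breath tidal volume; negative predictions are clipped to zero
    (a negative volume is unphysical) and counted in the second return."""
    a = np.asarray(amplitudes_mm, float)
    tv = model.slope * a + model.intercept
    clipped = int(np.sum(tv < 0))
    return np.maximum(tv, 0.0), clipped


def estimate_rr(events: BreathEvents) -> np.ndarray:
    """Per-breath respiratory rate, 60 / peak-to-peak interval (BPM)."""
    if events.peaks.size < 2:
        raise SignalError("need at least 2 peaks for a rate")
    return 60.0 / events.intervals


def breath_estimates(
    events: BreathEvents,
    model: CalibrationModel | None = None,
) -> BreathEstimates:
    """Assemble per-breath estimates from segmented events.

    Each interval's rate is anchored at the interval's closing peak; the
    recording's first peak therefore carries no breath record.  Without
    a calibration model the TV column is NaN (rate-only run).
    """
    rr = estimate_rr(events)
    amp = events.amplitudes[1:]
    if model is not None:
        tv, _ = estimate_tv(model, amp)
    else:
        tv = np.full(amp.shape, np.nan)
    return BreathEstimates(events.peak_times[1:], tv, rr, amp)
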