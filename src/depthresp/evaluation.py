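"""Method-agreement statistics between estimated and reference breaths.

Breaths from the two instruments are paired greedily by nearest peak
time within a window (each breath used at most once).  Agreement is then
quantified three ways, mirroring standard method-comparison practice:

* mean absolute relative error (MARE) of tidal volume, percent;
* Bland-Altman analysis: mean difference (fixed bias) with its 95% t
  confidence interval, 1.96-SD limits of agreement, and the Pearson
  correlation of difference vs pair mean (proportional bias) with its
  two-sided p-value;
* respiratory-rate error counts: a breath counts as an error when the
  absolute rate difference strictly exceeds a threshold (1 BPM).
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError, ValidationError
from .estimation import BreathEstimates

__all__ = [
    "BreathPairSet",
    "AgreementReport",
    "match_breaths",
    "mean_absolute_relative_error",
    "bland_altman",
    "rr_error_count",
    "agreement_report",
]


@dataclasses.dataclass(frozen=True)
class BreathPairSet:
    """Matched per-breath estimates (est) and reference values (ref)."""

    est_tv_L: np.ndarray
    ref_tv_L: np.ndarray
    est_rr_bpm: np.ndarray
    ref_rr_bpm: np.ndarray
    match_dt_s: np.ndarray
    n_unmatched_est: int = 0
    n_unmatched_ref: int = 0

    def __post_init__(self) -> None:
        n = self.est_tv_L.size
        for arr in (self.ref_tv_L, self.est_rr_bpm, self.ref_rr_bpm, self.match_dt_s):
            if arr.size != n:
                raise ValidationError("pair arrays must be equal length")

    @property
    def n_pairs(self) -> int:
        return int(self.est_tv_L.size)


@dataclasses.dataclass(frozen=True)
class AgreementReport:
    mare_pct: float
    bias_L: float
    bias_ci_L: tuple[float, float]
    loa_L: tuple[float, float]
    prop_bias_r: float
    prop_bias_p: float
    fixed_bias_present: bool
    proportional_bias_present: bool
    degenerate: bool
    rr_errors: int
    rr_total: int
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "mare_pct": float(self.mare_pct),
            "bias_L": float(self.bias_L),
            "bias_ci_L": [float(v) for v in self.bias_ci_L],
            "loa_L": [float(v) for v in self.loa_L],
            "prop_bias_r": float(self.prop_bias_r),
            "prop_bias_p": float(self.prop_bias_p),
            "fixed_bias_present": bool(self.fixed_bias_present),
            "proportional_bias_present": bool(self.proportional_bias_present),
            "degenerate": bool(self.degenerate),
            "rr_errors": int(self.rr_errors),
            "rr_total": int(self.rr_total),
            "n_pairs": int(self.n_pairs),
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_text(self) -> str:
        lines = [
            f"matched breaths          : {self.n_pairs}",
            f"TV MARE                  : {self.mare_pct:.2f} %",
            f"TV bias (est - ref)      : {self.bias_L:+.4f} L",
            f"  95% CI of bias         : [{self.bias_ci_L[0]:+.4f}, "
            f"{self.bias_ci_L[1]:+.4f}] L"
            + ("  (degenerate: zero spread)" if self.degenerate else ""),
            f"  limits of agreement    : [{self.loa_L[0]:+.4f}, "
            f"{self.loa_L[1]:+.4f}] L",
            f"  fixed bias present     : {'yes' if self.fixed_bias_present else 'no'}",
            f"  proportional bias      : r = {self.prop_bias_r:+.3f}, "
            f"p = {self.prop_bias_p:.4f} "
            f"({'present' if self.proportional_bias_present else 'absent'})",
            f"RR errors (> 1 BPM)      : {self.rr_errors} / {self.rr_total}",
        ]
        return "\n".join(lines)


def match_breaths(
    est: BreathEstimates,
    ref: BreathEstimates,
    window_s: float = 2.0,
) -> BreathPairSet:
    """Greedy nearest-peak-time matching within *window_s* seconds.

    Candidate pairs are sorted by |dt| (ties by est then ref index for
    determinism) and accepted greedily, each breath at most once.
    """
    if est.n_breaths == 0 or ref.n_breaths == 0:
        raise EvaluationError("cannot match: empty breath list")
    cand = []
    for i, te in enumerate(est.peak_time_s):
        for j, tr in enumerate(ref.peak_time_s):
            dt = te - tr
            if abs(dt) <= window_s:
                cand.append((abs(dt), i, j, dt))
    cand.sort()
    used_e: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for _, i, j, dt in cand:
        if i in used_e or j in used_r:
            continue
        used_e.add(i)
        used_r.add(j)
        pairs.append((i, j, dt))
    if not pairs:
        raise EvaluationError("zero matched breaths within the window")
    pairs.sort()
    ei = np.array([p[0] for p in pairs])
    ri = np.array([p[1] for p in pairs])
    dts = np.array([p[2] for p in pairs])
    return BreathPairSet(
        est.tv_L[ei],
        ref.tv_L[ri],
        est.rr_bpm[ei],
        ref.rr_bpm[ri],
        dts,
        n_unmatched_est=est.n_breaths - len(pairs),
        n_unmatched_ref=ref.n_breaths - len(pairs),
    )


def mean_absolute_relative_error(pairs: BreathPairSet) -> float:
    """100 * mean(|est - ref| / ref) over the matched tidal volumes."""
    ref = pairs.ref_tv_L
    if np.any(ref <= 0):
        raise EvaluationError("non-positive reference TV; relative error undefined")
    return float(100.0 * np.mean(np.abs(pairs.est_tv_L - ref) / ref))


def bland_altman(
    pairs: BreathPairSet,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float], tuple[float, float], float, float, bool]:
    """Bland-Altman bias, its t-based CI, limits of agreement, and the
    proportional-bias correlation of difference vs pair mean.

    Returns (bias, ci, loa, r, p, degenerate).  With zero spread among
    the differences the CI collapses to the bias and the degenerate flag
    is set.
    """
    d = pairs.est_tv_L - pairs.ref_tv_L
    m = (pairs.est_tv_L + pairs.ref_tv_L) / 2.0
    n = d.size
    if n < 3:
        raise EvaluationError("Bland-Altman needs at least 3 pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        ci = (bias, bias)
        loa = (bias, bias)
        r, p = 0.0, 1.0
    else:
        tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
        half = float(tcrit * sd / np.sqrt(n))
        ci = (bias - half, bias + half)
        loa = (bias - 1.96 * sd, bias + 1.96 * sd)
        if np.std(m) == 0.0:
            r, p = 0.0, 1.0
        else:
            rr = stats.pearsonr(m, d)
            r, p = float(rr.statistic), float(rr.pvalue)
    return bias, ci, loa, r, p, degenerate


def rr_error_count(
    pairs: BreathPairSet,
    threshold_bpm: float = 1.0,
) -> tuple[int, int]:
    """Breaths whose |est RR - ref RR| strictly exceeds the threshold."""
    if pairs.n_pairs == 0:
        raise EvaluationError("no pairs to count")
    diff = np.abs(pairs.est_rr_bpm - pairs.ref_rr_bpm)
    return int(np.sum(diff > threshold_bpm)), int(pairs.n_pairs)


def agreement_report(
    pairs: BreathPairSet,
    alpha: float = 0.05,
    rr_threshold_bpm: float = 1.0,
) -> AgreementReport:
    """Full agreement summary over a matched pair set."""
    mare = mean_absolute_relative_error(pairs)
    bias, ci, loa, r, p, degenerate = bland_altman(pairs, alpha)
    errors, total = rr_error_count(pairs, rr_threshold_bpm)
    fixed = (not degenerate) and (ci[0] > 0 or ci[1] < 0)
    proportional = (not degenerate) and p < alpha
    return AgreementReport(
        mare_pct=mare,
        bias_L=bias,
        bias_ci_L=ci,
        loa_L=loa,
        prop_bias_r=r,
        prop_bias_p=p,
        fixed_bias_present=fixed,
        proportional_bias_present=proportional,
        degenerate=degenerate,
        rr_errors=errors,
        rr_total=total,
        n_pairs=pairs.n_pairs,
    )


def pairs_to_csv(pairs: BreathPairSet, path: str | os.PathLike) -> None:
    """Per-pair scatter data (mean, difference) for Bland-Altman plots."""
    d = pairs.est_tv_L - pairs.ref_tv_L
    m = (pairs.est_tv_L + pairs.ref_tv_L) / 2.0
    pd.DataFrame(
        {
            "est_tv_L": pairs.est_tv_L,
            "ref_tv_L": pairs.ref_tv_L,
            "mean_L": m,
            "diff_L": d,
            "est_rr_bpm": pairs.est_rr_bpm,
            "ref_rr_bpm": pairs.ref_rr_bpm,
            "match_dt_s": pairs.match_dt_s,
        }
    ).to_csv(path, index=False)
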