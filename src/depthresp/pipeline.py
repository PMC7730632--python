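"""End-to-end orchestration: landmarks -> ROI -> signal -> breaths ->
calibration -> agreement.

Each stage is the corresponding module function; this layer only wires
them together, carries the run configuration, and keeps every
intermediate artifact (shoulders, both ROI stages, the row-ratio
profile) on the result object so a failed run can be audited.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd

from . import body_landmarks as bl
from . import estimation as est
from . import evaluation as ev
from . import respsignal as rs
from . import roi as roi_mod
from .config import RunConfig
from .errors import FitError, SignalError
from .io_formats import DepthSequence, ReferenceTrace, align_by_trigger

log = logging.getLogger("depthresp")

__all__ = ["EstimateResult", "run_estimate", "run_calibrate", "run_evaluate",
           "reference_breaths"]


@dataclasses.dataclass(frozen=True)
class EstimateResult:
    """Everything a single-recording run produces."""

    shoulders: bl.ShoulderPair
    tentative_roi: roi_mod.ROIRect
    final_roi: roi_mod.ROIRect
    rows: roi_mod.RowWaveformSet
    grid: roi_mod.UnitGrid
    signal: rs.RespSignal
    events: rs.BreathEvents
    estimates: est.BreathEstimates

    def report_dict(self) -> dict:
        return {
            "shoulders": {
                "left": list(self.shoulders.left),
                "right": list(self.shoulders.right),
            },
            "tentative_roi": dataclasses.asdict(self.tentative_roi),
            "final_roi": dataclasses.asdict(self.final_roi),
            "n_breaths": self.estimates.n_breaths,
            "rr_bpm": self.estimates.rr_bpm.tolist(),
            "tv_L": [None if np.isnan(v) else v for v in self.estimates.tv_L],
            "amplitude_mm": self.estimates.amplitude.tolist(),
            "peak_time_s": self.estimates.peak_time_s.tolist(),
        }

    def write_artifacts(self, outdir: str | os.PathLike) -> None:
        """JSON report plus the row-ratio profile, the primary debugging
        surface for the ROI-bottom step."""
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(self.report_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        pd.DataFrame(
            {
                "row": np.arange(self.rows.row_amplitude.size),
                "bottom_edge_px": [
                    self.grid.row_bottom_edge(r)
                    for r in range(self.rows.row_amplitude.size)
                ],
                "amplitude_mm": self.rows.row_amplitude,
                "amplitude_ratio": self.rows.amplitude_ratio,
                "cumulative_ratio": self.rows.cumulative_ratio,
                "valid": self.rows.row_valid,
            }
        ).to_csv(os.path.join(outdir, "row_ratio_profile.csv"), index=False)


def _breath_windows(events: rs.BreathEvents, n_samples: int) -> list[tuple[int, int]]:
    """Valley-to-valley windows; the trailing partial breath runs to the
    end of the record so the last full excursion is still covered."""
    v = list(events.valleys)
    windows = list(zip(v[:-1], v[1:]))
    if v and v[-1] < n_samples - 1:
        windows.append((v[-1], n_samples))
    if not windows:
        raise SignalError("too few breaths to window the row waveforms")
    return [(int(a), int(b)) for a, b in windows]


def run_estimate(
    seq: DepthSequence,
    config: RunConfig = RunConfig(),
    model: est.CalibrationModel | None = None,
) -> EstimateResult:
    """Full single-recording pipeline on a depth sequence.

    Landmarks come from the initial frame only; the ROI they define is
    held for the whole recording.
    """
    config.log_provenance()
    frame0 = seq.frames[0]
    mask = bl.segment_foreground(frame0, config.max_subject_depth_mm)
    box = bl.detect_upper_body(
        frame0, detector=config.detector, max_subject_depth_mm=config.max_subject_depth_mm
    )
    shoulders = bl.detect_shoulders(mask, box)
    span = shoulders.right[1] - shoulders.left[1]
    arm_width = int(round(config.arm_width_fraction * span))
    tentative = roi_mod.build_tentative_roi(shoulders, seq.height, seq.width, arm_width)
    grid = roi_mod.build_unit_grid(tentative, config.unit_size, config.stride)
    units = roi_mod.extract_unit_waveforms(seq, grid, config.sample_rate_hz)

    tent_sig = rs.smooth(
        rs.roi_mean_signal(seq, tentative, config.sample_rate_hz), config.window_s
    )
    tent_events = rs.detect_breaths(
        tent_sig, config.min_interval_s, prominence_floor=config.prominence_floor_mm
    )
    windows = _breath_windows(tent_events, tent_sig.x.size)
    rows = roi_mod.compute_row_waveforms(units, windows)
    final = roi_mod.finalize_roi(tentative, rows, grid, config.cutoff)
    log.info("final ROI bottom %d px (tentative %d)", final.bottom, tentative.bottom)

    sig = rs.smooth(
        rs.roi_mean_signal(seq, final, config.sample_rate_hz), config.window_s
    )
    events = rs.detect_breaths(
        sig, config.min_interval_s, prominence_floor=config.prominence_floor_mm
    )
    estimates = est.breath_estimates(events, model)
    return EstimateResult(
        shoulders, tentative, final, rows, grid, sig, events, estimates
    )


def reference_breaths(
    ref: ReferenceTrace,
    offset_s: float,
    config: RunConfig = RunConfig(),
) -> est.BreathEstimates:
    """Segment the reference volume trace with the same detector used on
    the depth signal (prominence floor in liters), on the camera clock."""
    t = ref.time_s - offset_s
    keep = t >= 0
    if keep.sum() < 2:
        raise SignalError("reference trace ends before the camera starts")
    t0, t1 = t[keep][0], t[keep][-1]
    n = max(2, int(np.floor((t1 - t0) * config.sample_rate_hz)) + 1)
    tg = t0 + np.arange(n) / config.sample_rate_hz
    v = np.interp(tg, t[keep], ref.volume_L[keep])
    sig = rs.RespSignal(tg, v - v.mean(), config.sample_rate_hz)
    sig = rs.smooth(sig, config.window_s)
    events = rs.detect_breaths(
        sig, config.min_interval_s, prominence_floor=config.ref_prominence_floor_L
    )
    rr = est.estimate_rr(events)
    # the trace is already a volume: per-breath TV is the excursion itself
    return est.BreathEstimates(
        events.peak_times[1:], events.amplitudes[1:], rr, events.amplitudes[1:]
    )


def run_calibrate(
    seq: DepthSequence,
    ref: ReferenceTrace,
    config: RunConfig = RunConfig(),
    label: str = "pooled",
) -> tuple[est.CalibrationModel, EstimateResult]:
    """Align by trigger, segment both instruments, match breaths, and fit
    the amplitude -> TV regression."""
    result = run_estimate(seq, config)
    offset = align_by_trigger(seq, ref)
    ref_est = reference_breaths(ref, offset, config)
    model = fit_from_pairs(result.estimates, ref_est, config, label)
    return model, result


def fit_from_pairs(
    est_b: est.BreathEstimates,
    ref_b: est.BreathEstimates,
    config: RunConfig,
    label: str = "pooled",
) -> est.CalibrationModel:
    """Match two breath lists and fit OLS of reference TV on amplitude."""
    pairs = ev.match_breaths(
        dataclasses.replace(est_b, tv_L=est_b.amplitude),  # carry amplitude
        ref_b,
        config.match_window_s,
    )
    if pairs.n_pairs < 2:
        raise FitError("fewer than 2 matched breaths; cannot calibrate")
    return est.fit_calibration(
        pairs.est_tv_L, pairs.ref_tv_L, label, config.include_intercept
    )


def run_evaluate(
    estimates: est.BreathEstimates,
    reference: est.BreathEstimates,
    config: RunConfig = RunConfig(),
) -> tuple[ev.AgreementReport, ev.BreathPairSet]:
    """Match breaths and compute the full agreement report."""
    pairs = ev.match_breaths(estimates, reference, config.match_window_s)
    report = ev.agreement_report(
        pairs, alpha=config.alpha, rr_threshold_bpm=config.rr_error_threshold_bpm
    )
    return report, pairs


def cohort_tv_recovery(
    n_subjects: int = 10,
    seed: int = 0,
    pixel_sd_mm: float = 1.5,
    dropout_prob: float = 0.005,
    sway_amp_mm: float = 2.0,
    stratify: str = "sex",
    config: RunConfig = RunConfig(),
    fps: float = 30.0,
    include_deep: bool = True,
    trigger_lag_s: float = 0.3,
) -> dict:
    """Simulated calibration study with held-out evaluation.

    Each simulated subject contributes a normal-breathing session and
    (optionally) five deep breaths, as in the underlying protocol; both
    sessions enter one regression.  Matched (amplitude, reference-TV)
    pairs are split alternately into a calibration half and a held-out
    half; a model is fitted per stratum (``"sex"`` or ``"subject"``) on
    the calibration halves pooled within the stratum and assessed on the
    held-out halves.  Returns pooled MARE, RR error counts and the
    per-stratum models.
    """
    from . import simulate as sim

    cohort = sim.make_cohort(
        n_subjects,
        seed=seed,
        pixel_sd_mm=pixel_sd_mm,
        dropout_prob=dropout_prob,
        sway_amp_mm=sway_amp_mm,
    )
    per_member: list[tuple[str, ev.BreathPairSet]] = []
    for m in cohort:
        programs = [m.program]
        if include_deep:
            deep = m.program.deepened()
            # protocol: five deep breaths at the subject's own pace
            deep = dataclasses.replace(deep, duration_s=5.0 * deep.period_s)
            programs.append(deep)
        for program in programs:
            seq, truth = sim.render_sequence(m.scene, program, m.noise, fps=fps)
            ref = sim.synth_reference_trace(truth, trigger_lag_s=trigger_lag_s)
            result = run_estimate(seq, config)
            offset = align_by_trigger(seq, ref)
            ref_est = reference_breaths(ref, offset, config)
            pairs = ev.match_breaths(
                dataclasses.replace(
                    result.estimates, tv_L=result.estimates.amplitude
                ),
                ref_est,
                config.match_window_s,
            )
            key = m.sex if stratify == "sex" else f"s{m.subject_id}"
            per_member.append((key, pairs))

    models: dict[str, est.CalibrationModel] = {}
    abs_rel_err: list[float] = []
    rr_err = rr_tot = 0
    for key in sorted({k for k, _ in per_member}):
        amp_cal, tv_cal, amp_tst, tv_tst = [], [], [], []
        rr_est_tst, rr_ref_tst = [], []
        for k, p in per_member:
            if k != key:
                continue
            amp_cal.append(p.est_tv_L[0::2])
            tv_cal.append(p.ref_tv_L[0::2])
            amp_tst.append(p.est_tv_L[1::2])
            tv_tst.append(p.ref_tv_L[1::2])
            rr_est_tst.append(p.est_rr_bpm[1::2])
            rr_ref_tst.append(p.ref_rr_bpm[1::2])
        model = est.fit_calibration(
            np.concatenate(amp_cal), np.concatenate(tv_cal), key,
            config.include_intercept,
        )
        models[key] = model
        pred, _ = est.estimate_tv(model, np.concatenate(amp_tst))
        ref_tv = np.concatenate(tv_tst)
        abs_rel_err.extend(np.abs(pred - ref_tv) / ref_tv)
        d_rr = np.abs(np.concatenate(rr_est_tst) - np.concatenate(rr_ref_tst))
        rr_err += int(np.sum(d_rr > config.rr_error_threshold_bpm))
        rr_tot += d_rr.size
    return {
        "mare_pct": float(100.0 * np.mean(abs_rel_err)),
        "n_test_pairs": len(abs_rel_err),
        "rr_errors": rr_err,
        "rr_total": rr_tot,
        "models": models,
    }
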