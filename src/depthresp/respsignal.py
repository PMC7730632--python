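"""Respiratory displacement signal and breath segmentation.

The mean depth over the final ROI, negated and baseline-removed, is the
displacement signal: it *rises during inspiration* (the chest moves
toward the camera, so depth falls).  With this sign convention a signal
peak is end-inspiration and a valley end-expiration; a sensor that plots
raw depth sees the mirror image of the same curve.

Breaths are segmented by peak detection with a minimum spacing and an
adaptive prominence threshold, with the valley between consecutive
peaks taken as the intervening end-expiration.  The same detector is
applied to the reference volume trace (prominence then in liters), so
both instruments are processed identically.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .errors import SignalError, ValidationError
from .io_formats import DepthSequence
from .roi import ROIRect

__all__ = [
    "RespSignal",
    "BreathEvents",
    "roi_mean_signal",
    "smooth",
    "detect_breaths",
]


@dataclasses.dataclass(frozen=True)
class RespSignal:
    """Uniformly sampled displacement signal (mm; + = inspiration)."""

    t: np.ndarray
    x: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        x = np.asarray(self.x, float)
        if t.shape != x.shape or t.ndim != 1 or t.size < 2:
            raise ValidationError("t and x must be equal-length 1-D, size >= 2")
        if np.max(np.abs(np.diff(t) - 1.0 / self.sample_rate)) > 1e-9:
            raise ValidationError("time grid is not uniform at sample_rate")
        if not np.all(np.isfinite(x)):
            raise ValidationError("signal contains non-finite values")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)


@dataclasses.dataclass(frozen=True)
class BreathEvents:
    """Alternating valley/peak series with per-breath amplitude and interval.

    ``valleys[i]`` precedes ``peaks[i]``; ``amplitudes[i] = x[peaks[i]] -
    x[valleys[i]]`` (mm or L depending on the signal); ``intervals`` are
    the peak-to-peak durations in seconds, one fewer than the peaks.
    """

    peaks: np.ndarray  # sample indices of end-inspiration
    valleys: np.ndarray  # sample indices of end-expiration
    amplitudes: np.ndarray
    intervals: np.ndarray
    peak_times: np.ndarray  # seconds, same clock as the source signal

    def __post_init__(self) -> None:
        p, v = np.asarray(self.peaks), np.asarray(self.valleys)
        if p.size == 0:
            raise SignalError("no respiration detected")
        if p.size != v.size:
            raise ValidationError("each peak needs its preceding valley")
        merged = np.empty(p.size + v.size, dtype=p.dtype)
        merged[0::2], merged[1::2] = v, p
        if not np.all(np.diff(merged) > 0):
            raise ValidationError("peaks and valleys must strictly alternate")
        if not np.all(np.asarray(self.amplitudes) > 0):
            raise ValidationError("breath amplitudes must be positive")
        if self.intervals.size and not np.all(np.asarray(self.intervals) > 0):
            raise ValidationError("breath intervals must be positive")
        if self.intervals.size != p.size - 1:
            raise ValidationError("need exactly len(peaks) - 1 intervals")

    @property
    def n_breaths(self) -> int:
        return int(self.peaks.size)


def roi_mean_signal(
    seq: DepthSequence,
    roi: ROIRect,
    sample_rate: float = 30.0,
) -> RespSignal:
    """Mean valid-pixel depth of *roi* per frame, negated, de-meaned and
    linearly resampled onto a uniform clock."""
    if roi.bottom > seq.height or roi.right > seq.width:
        raise ValidationError("ROI extends outside the frame")
    patch = seq.frames[:, roi.top : roi.bottom, roi.left : roi.right].astype(float)
    valid = patch > 0
    counts = valid.sum(axis=(1, 2))
    if np.any(counts == 0):
        bad = int(np.flatnonzero(counts == 0)[0])
        raise SignalError(f"ROI fully invalid in frame {bad}")
    means = (patch * valid).sum(axis=(1, 2)) / counts
    x_native = -means
    t0, t1 = seq.timestamps[0], seq.timestamps[-1]
    n = max(2, int(np.floor((t1 - t0) * sample_rate)) + 1)
    t = t0 + np.arange(n) / sample_rate
    x = np.interp(t, seq.timestamps, x_native)
    x = x - x.mean()
    return RespSignal(t, x, float(sample_rate))


def smooth(sig: RespSignal, window_s: float = 0.5) -> RespSignal:
    """Zero-phase moving average; window rounded to an odd number of
    samples, shrinking symmetrically at the edges (no padding bias)."""
    w = int(round(window_s * sig.sample_rate))
    if w < 1:
        raise ValidationError("smoothing window shorter than one sample")
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w)
    num = np.convolve(sig.x, kernel, mode="same")
    den = np.convolve(np.ones_like(sig.x), kernel, mode="same")
    return RespSignal(sig.t, num / den, sig.sample_rate)


def detect_breaths(
    sig: RespSignal,
    min_interval_s: float = 1.5,
    min_prominence: float | None = None,
    prominence_floor: float = 0.5,
) -> BreathEvents:
    """Segment *sig* into breaths.

    Peaks are local maxima separated by at least *min_interval_s* with
    prominence at least *min_prominence*; when the threshold is None it
    adapts to max(*prominence_floor*, 20% of the median peak-to-trough
    excursion of the signal).  The valley between consecutive peaks is
    the global minimum of that span; a leading valley before the first
    peak is kept when one exists, otherwise the first (incomplete)
    breath is dropped.
    """
    x = sig.x
    if x.size < 2 * min_interval_s * sig.sample_rate:
        raise SignalError("signal shorter than two breath intervals")
    distance = max(1, int(round(min_interval_s * sig.sample_rate)))
    if min_prominence is None:
        cand, props = sps.find_peaks(x, distance=distance, prominence=0.0)
        if cand.size == 0:
            raise SignalError("no respiration detected")
        excursion = float(np.median(props["prominences"]))
        min_prominence = max(prominence_floor, 0.2 * excursion)
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=min_prominence)
    if peaks.size == 0:
        raise SignalError("no respiration detected")

    valleys = []
    kept_peaks = []
    prev = None
    for pk in peaks:
        lo = 0 if prev is None else prev
        if pk - lo < 1:
            prev = pk
            continue
        v = lo + int(np.argmin(x[lo:pk]))
        if prev is None and v == 0:
            # a "valley" at the very first sample cannot be confirmed as
            # end-expiration (the record may start mid-breath): the first
            # breath is incomplete and is dropped
            prev = pk
            continue
        if x[pk] - x[v] <= 0:
            prev = pk
            continue
        valleys.append(v)
        kept_peaks.append(pk)
        prev = pk
    if not kept_peaks:
        raise SignalError("no complete valley-to-peak breath found")
    peaks = np.asarray(kept_peaks)
    valleys = np.asarray(valleys)
    amplitudes = x[peaks] - x[valleys]
    peak_times = sig.t[peaks]
    intervals = np.diff(peak_times)
    return BreathEvents(peaks, valleys, amplitudes, intervals, peak_times)
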