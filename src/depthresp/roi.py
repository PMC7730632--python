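"""Adaptive region-of-interest determination.

The tentative ROI hangs from the lower of the two shoulders, trimmed
inward from each shoulder by roughly an arm's width, and tentatively
reaches the bottom of the image.  It is tiled with small unit areas
(19 x 19 px by default, slid every 10 px) whose mean depth forms one
elemental waveform each.  Rows of units are averaged into row waveforms
W_i; each row's mean per-breath depth excursion yields its amplitude
ratio (share of the total breathing motion), and the running sum of the
ratios from the top of the ROI fixes the final bottom at the row where
it reaches the cutoff (90% by default).  Rows below that point move too
little to help and mostly add noise (thighs, chair, background).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .body_landmarks import ShoulderPair
from .errors import GeometryError, SignalError, ValidationError
from .io_formats import DepthSequence

__all__ = [
    "ROIRect",
    "UnitGrid",
    "UnitWaveforms",
    "RowWaveformSet",
    "build_tentative_roi",
    "build_unit_grid",
    "extract_unit_waveforms",
    "compute_row_waveforms",
    "finalize_roi",
]


@dataclasses.dataclass(frozen=True)
class ROIRect:
    """Rectangular region, half-open bounds, with its pipeline stage."""

    top: int
    bottom: int
    left: int
    right: int
    stage: str = "tentative"  # "tentative" | "final"

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise GeometryError(f"degenerate ROI {self}")
        if self.stage not in ("tentative", "final"):
            raise ValidationError(f"unknown ROI stage {self.stage!r}")

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left


@dataclasses.dataclass(frozen=True)
class UnitGrid:
    """Anchors of unit areas tiling an ROI on a regular stride."""

    roi: ROIRect
    unit_size: int = 19
    stride: int = 10

    def __post_init__(self) -> None:
        if self.unit_size < self.stride:
            raise ValidationError("unit_size must be >= stride")
        if self.roi.height < self.unit_size or self.roi.width < self.unit_size:
            raise GeometryError(
                f"ROI {self.roi.height}x{self.roi.width} smaller than one "
                f"{self.unit_size}x{self.unit_size} unit"
            )

    @property
    def n_rows(self) -> int:
        return (self.roi.height - self.unit_size) // self.stride + 1

    @property
    def n_cols(self) -> int:
        return (self.roi.width - self.unit_size) // self.stride + 1

    def unit_bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """(top, bottom, left, right) pixel bounds of unit (row, col)."""
        top = self.roi.top + row * self.stride
        left = self.roi.left + col * self.stride
        return top, top + self.unit_size, left, left + self.unit_size

    def row_bottom_edge(self, row: int) -> int:
        """Bottom pixel edge of the units in *row* (anchor + unit size)."""
        return self.roi.top + row * self.stride + self.unit_size


@dataclasses.dataclass(frozen=True)
class UnitWaveforms:
    """Mean depth (mm) of every unit per sample on a uniform clock.

    ``values[r, c, k]`` is unit (r, c) at sample k; ``validity[r, c]`` is
    False for units dominated by dropout, which are excluded everywhere
    downstream rather than silently zeroed.
    """

    values: np.ndarray  # [n_rows, n_cols, n_samples]
    validity: np.ndarray  # [n_rows, n_cols] bool
    sample_rate: float
    t: np.ndarray  # [n_samples] uniform grid, seconds

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] < 2:
            raise ValidationError("unit waveforms need >= 2 samples")
        if self.validity.shape != self.values.shape[:2]:
            raise ValidationError("validity shape mismatch")


@dataclasses.dataclass(frozen=True)
class RowWaveformSet:
    """Per-row averaged waveforms W_i and their amplitude-ratio profile.

    ``amplitude_ratio`` sums to 1 over valid rows; ``cumulative_ratio``
    is its running sum from the top row (NaN on invalid rows).
    """

    row_signals: np.ndarray  # [n_rows, n_samples]
    row_amplitude: np.ndarray  # [n_rows] mm, NaN for invalid rows
    amplitude_ratio: np.ndarray
    cumulative_ratio: np.ndarray
    row_valid: np.ndarray  # [n_rows] bool


def build_tentative_roi(
    shoulders: ShoulderPair,
    frame_height: int,
    frame_width: int,
    arm_width_px: int,
) -> ROIRect:
    """Tentative ROI from the shoulder pair.

    Top = the lower shoulder (larger row index); left/right = shoulder
    columns moved inward by *arm_width_px*; bottom = the image bottom,
    to be tightened later by the amplitude-ratio integration.
    """
    span = shoulders.right[1] - shoulders.left[1]
    if not 0 <= arm_width_px < span / 2:
        raise GeometryError(
            f"arm_width_px={arm_width_px} must be in [0, {span / 2}) "
            f"for a shoulder span of {span} px"
        )
    top = max(shoulders.left[0], shoulders.right[0])
    left = shoulders.left[1] + arm_width_px
    right = shoulders.right[1] - arm_width_px
    if left >= right:
        raise GeometryError("arm trimming collapsed the ROI")
    if top >= frame_height:
        raise GeometryError("shoulders at or below the image bottom")
    return ROIRect(top, frame_height, left, right, stage="tentative")


def build_unit_grid(roi: ROIRect, unit_size: int = 19, stride: int = 10) -> UnitGrid:
    """Tile *roi* with unit areas anchored every *stride* pixels."""
    return UnitGrid(roi, unit_size, stride)


def extract_unit_waveforms(
    seq: DepthSequence,
    grid: UnitGrid,
    sample_rate: float = 30.0,
    max_invalid_pixel_frac: float = 0.5,
    max_invalid_frame_frac: float = 0.1,
) -> UnitWaveforms:
    """Per-unit mean depth of valid (nonzero) pixels, resampled uniformly.

    Averaging runs on the native frames first, then each unit series is
    linearly interpolated onto a uniform *sample_rate* clock spanning the
    sequence.  A unit whose invalid-pixel fraction exceeds
    *max_invalid_pixel_frac* in more than *max_invalid_frame_frac* of the
    frames is flagged invalid.
    """
    roi = grid.roi
    if roi.bottom > seq.height or roi.right > seq.width or roi.top < 0 or roi.left < 0:
        raise GeometryError("unit grid extends outside the frame")
    n_rows, n_cols = grid.n_rows, grid.n_cols
    # crop to the ROI before the cumulative sums; unit bounds below are
    # therefore expressed relative to the ROI origin
    frames = seq.frames[:, roi.top : roi.bottom, roi.left : roi.right].astype(
        np.float64
    )
    valid = frames > 0

    # cumulative sums over each frame give O(1) unit sums
    csum = np.cumsum(np.cumsum(frames * valid, axis=1), axis=2)
    ccnt = np.cumsum(np.cumsum(valid.astype(np.float64), axis=1), axis=2)
    csum = np.pad(csum, ((0, 0), (1, 0), (1, 0)))
    ccnt = np.pad(ccnt, ((0, 0), (1, 0), (1, 0)))

    def box_sum(c: np.ndarray, t: int, b: int, l: int, r: int) -> np.ndarray:
        return c[:, b, r] - c[:, t, r] - c[:, b, l] + c[:, t, l]

    native = np.empty((n_rows, n_cols, seq.n_frames))
    invalid_frac = np.empty((n_rows, n_cols, seq.n_frames))
    for r in range(n_rows):
        for c in range(n_cols):
            t, b, l, rr = grid.unit_bounds(r, c)
            t, b = t - roi.top, b - roi.top
            l, rr = l - roi.left, rr - roi.left
            s = box_sum(csum, t, b, l, rr)
            n = box_sum(ccnt, t, b, l, rr)
            area = (b - t) * (rr - l)
            invalid_frac[r, c] = 1.0 - n / area
            with np.errstate(invalid="ignore", divide="ignore"):
                native[r, c] = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    validity = (
        (invalid_frac > max_invalid_pixel_frac).mean(axis=2) <= max_invalid_frame_frac
    )
    if not validity.any():
        raise SignalError("every unit area is invalid (all-dropout recording)")

    t0, t1 = seq.timestamps[0], seq.timestamps[-1]
    n_samples = max(2, int(np.floor((t1 - t0) * sample_rate)) + 1)
    t_uniform = t0 + np.arange(n_samples) / sample_rate
    values = np.empty((n_rows, n_cols, n_samples))
    for r in range(n_rows):
        for c in range(n_cols):
            y = native[r, c]
            if np.isnan(y).any():  # bridge occasional all-invalid frames
                good = ~np.isnan(y)
                if good.sum() >= 2:
                    y = np.interp(seq.timestamps, seq.timestamps[good], y[good])
                else:
                    values[r, c] = 0.0
                    continue
            values[r, c] = np.interp(t_uniform, seq.timestamps, y)
    return UnitWaveforms(values, validity, float(sample_rate), t_uniform)


def compute_row_waveforms(
    units: UnitWaveforms,
    breath_windows: list[tuple[int, int]],
) -> RowWaveformSet:
    """Row waveforms W_i and the amplitude-ratio profile.

    W_i is the mean over the valid units of row i.  The row amplitude is
    the mean over *breath_windows* of the within-window max - min of
    W_i; the windows come from one global breath segmentation on the
    tentative-ROI mean signal and are shared by every row.
    """
    if not breath_windows:
        raise SignalError("no breath windows supplied for row amplitudes")
    n_rows, _, n_samples = units.values.shape
    row_signals = np.full((n_rows, n_samples), np.nan)
    row_valid = units.validity.any(axis=1)
    for r in range(n_rows):
        if row_valid[r]:
            row_signals[r] = units.values[r, units.validity[r]].mean(axis=0)

    amp = np.full(n_rows, np.nan)
    for r in np.flatnonzero(row_valid):
        spans = []
        for start, end in breath_windows:
            start, end = int(start), int(end)
            if end <= start or end > n_samples:
                raise SignalError(f"bad breath window ({start}, {end})")
            seg = row_signals[r, start:end]
            spans.append(seg.max() - seg.min())
        amp[r] = float(np.mean(spans))

    total = np.nansum(amp)
    if not total > 0:
        raise SignalError("all row amplitudes are zero; no breathing motion")
    ratio = amp / total
    cumulative = np.full(n_rows, np.nan)
    cumulative[row_valid] = np.cumsum(ratio[row_valid])
    return RowWaveformSet(row_signals, amp, ratio, cumulative, row_valid)


def finalize_roi(
    tentative: ROIRect,
    rows: RowWaveformSet,
    grid: UnitGrid,
    cutoff: float = 0.90,
) -> ROIRect:
    """Fix the ROI bottom at the first row whose cumulative amplitude
    ratio reaches *cutoff*; top/left/right are unchanged.
    """
    if not 0 < cutoff <= 1:
        raise ValidationError("cutoff must be in (0, 1]")
    valid_idx = np.flatnonzero(rows.row_valid)
    cum = rows.cumulative_ratio[valid_idx]
    crossing = np.flatnonzero(cum >= cutoff - 1e-12)
    i_star = int(valid_idx[crossing[0]]) if crossing.size else int(valid_idx[-1])
    bottom = min(grid.row_bottom_edge(i_star), tentative.bottom)
    return ROIRect(tentative.top, bottom, tentative.left, tentative.right, stage="final")
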