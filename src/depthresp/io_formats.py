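"""Depth-sequence and reference-trace I/O, plus trigger-based time alignment.

The canonical depth interchange format is a directory of 16-bit grayscale
PNG frames named ``frame_%06d.png`` together with a ``timestamps.csv``
(columns ``frame``, ``time_s``).  Depth values are integer millimeters;
the value 0 is reserved for "no reading" (time-of-flight dropout).

The reference volume trace emulates a spirometer channel: a CSV with
columns ``time_s`` (seconds), ``volume_L`` (instantaneous lung volume,
liters) and ``trigger`` (binary flag; the 0-to-1 transition marks the
instant the depth camera started recording, which is how the two clocks
are synchronized).
"""

from __future__ import annotations

import dataclasses
import os
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "DepthSequence",
    "ReferenceTrace",
    "read_depth_sequence",
    "write_depth_sequence",
    "read_reference_trace",
    "write_reference_trace",
    "align_by_trigger",
]

_FRAME_RE = re.compile(r"frame_(\d{6})\.png$")


@dataclasses.dataclass(frozen=True)
class DepthSequence:
    """Timestamped stack of depth frames.

    Attributes
    ----------
    frames : (n_frames, height, width) uint16 array
        Depth in millimeters; 0 marks an invalid pixel.
    timestamps : (n_frames,) float array
        Seconds since sequence start, strictly increasing.
    """

    frames: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        ts = np.asarray(self.timestamps, dtype=float)
        if frames.ndim != 3:
            raise ValidationError("frames must be a 3-D [n, h, w] array")
        if frames.shape[0] < 2:
            raise ValidationError("a depth sequence needs at least 2 frames")
        if ts.shape != (frames.shape[0],):
            raise ValidationError("one timestamp per frame required")
        if not np.all(np.diff(ts) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        if frames.min() < 0:
            raise ValidationError("depth values must be >= 0")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps", ts)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclasses.dataclass(frozen=True)
class ReferenceTrace:
    """Spirometer-style volume time series with a camera-sync trigger flag."""

    time_s: np.ndarray
    volume_L: np.ndarray
    trigger: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.volume_L, dtype=float)
        g = np.asarray(self.trigger, dtype=int)
        if not (t.shape == v.shape == g.shape) or t.ndim != 1:
            raise ValidationError("time_s, volume_L, trigger must be equal-length 1-D")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("reference time_s must be strictly increasing")
        if not np.any(g == 1):
            raise ValidationError("reference trace has no trigger=1 sample")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "volume_L", v)
        object.__setattr__(self, "trigger", g)

    @property
    def trigger_onset_index(self) -> int:
        """Index of the first 0->1 transition (sample 0 if it starts high)."""
        g = self.trigger
        if g[0] == 1:
            return 0
        rising = np.flatnonzero((g[1:] == 1) & (g[:-1] == 0))
        return int(rising[0]) + 1


def write_depth_sequence(seq: DepthSequence, path: str | os.PathLike) -> None:
    """Write *seq* as a directory of 16-bit PNGs plus ``timestamps.csv``."""
    if seq.frames.max() > np.iinfo(np.uint16).max:
        raise ValidationError("depth exceeds the 16-bit range")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(out / f"frame_{i:06d}.png", frame.astype(np.uint16))
    pd.DataFrame(
        {"frame": np.arange(seq.n_frames), "time_s": seq.timestamps}
    ).to_csv(out / "timestamps.csv", index=False)


def read_depth_sequence(path: str | os.PathLike) -> DepthSequence:
    """Read a depth sequence written by :func:`write_depth_sequence`.

    Frames are ordered by their timestamp.  Raises :class:`FormatError`
    for a missing timestamps file or frame, :class:`ValidationError` for
    non-monotonic timestamps or mixed frame dimensions.
    """
    root = Path(path)
    ts_file = root / "timestamps.csv"
    if not ts_file.is_file():
        raise FormatError(f"missing timestamps file: {ts_file}")
    table = pd.read_csv(ts_file)
    for col in ("frame", "time_s"):
        if col not in table.columns:
            raise FormatError(f"timestamps.csv lacks column '{col}'")
    table = table.sort_values("time_s", kind="stable")
    frames = []
    shape = None
    for idx in table["frame"].astype(int):
        fpath = root / f"frame_{idx:06d}.png"
        if not fpath.is_file():
            raise FormatError(f"missing frame file: {fpath}")
        img = np.asarray(iio.imread(fpath))
        if img.ndim != 2:
            raise FormatError(f"{fpath} is not a single-channel image")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValidationError(
                f"frame {idx} has shape {img.shape}, expected {shape}"
            )
        frames.append(img.astype(np.uint16))
    return DepthSequence(np.stack(frames), table["time_s"].to_numpy(float))


def write_reference_trace(ref: ReferenceTrace, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"time_s": ref.time_s, "volume_L": ref.volume_L, "trigger": ref.trigger}
    ).to_csv(path, index=False)


def read_reference_trace(path: str | os.PathLike) -> ReferenceTrace:
    """Read a reference volume CSV (columns time_s, volume_L, trigger)."""
    table = pd.read_csv(path)
    for col in ("time_s", "volume_L", "trigger"):
        if col not in table.columns:
            raise FormatError(f"reference trace lacks column '{col}'")
    t = table["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("reference time_s not strictly increasing")
    return ReferenceTrace(
        t, table["volume_L"].to_numpy(float), table["trigger"].to_numpy(int)
    )


def align_by_trigger(seq: DepthSequence, ref: ReferenceTrace) -> float:
    """Offset (s) such that the first depth timestamp corresponds to the
    reference time of the first trigger onset; compare via
    ``ref.time_s - offset``.
    """
    onset = ref.trigger_onset_index
    return float(ref.time_s[onset] - seq.timestamps[0])
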