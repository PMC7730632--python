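"""Upper-body and shoulder localization on the initial depth frame.

The region of interest is anchored on the two shoulder points.  Because a
seated subject with lowered arms presents a characteristic silhouette —
a narrow neck descending onto a near-horizontal shoulder line — the
shoulders are found as the high-convexity vertices of the polygon-
approximated body contour, one in each lateral third of the upper-body
box.  No skeletal tracking or pose-estimation model is involved.

Two detector backends satisfy the upper-body contract:

* ``"foreground"`` (default): depth-threshold segmentation of the nearest
  connected component.  Fully self-contained; works on any depth frame.
* a user-supplied callable ``frame -> (top, bottom, left, right)``, e.g.
  wrapping a pretrained cascade classifier run on the infrared image.

Landmarks are computed once, on the initial frame only; the region of
interest derived from them is held fixed for the whole recording.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DetectionError, ValidationError

__all__ = [
    "BodyBox",
    "ShoulderPair",
    "segment_foreground",
    "detect_upper_body",
    "detect_shoulders",
]


@dataclasses.dataclass(frozen=True)
class BodyBox:
    """Half-open pixel bounds [top, bottom) x [left, right), row 0 = top."""

    top: int
    bottom: int
    left: int
    right: int

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise ValidationError(f"degenerate body box {self}")

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left


@dataclasses.dataclass(frozen=True)
class ShoulderPair:
    """Left/right shoulder pixels as (row, col); left.col < right.col."""

    left: tuple[int, int]
    right: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.left[1] < self.right[1]:
            raise ValidationError("left shoulder must have the smaller column")

    def mirrored(self, width: int) -> "ShoulderPair":
        l, r = self.left, self.right
        return ShoulderPair((r[0], width - 1 - r[1]), (l[0], width - 1 - l[1]))


def segment_foreground(frame: np.ndarray, max_subject_depth_mm: float) -> np.ndarray:
    """Binary mask of the nearest body: valid depth below the threshold,
    largest connected component only (ties broken toward the leftmost),
    holes from sensor dropout healed by a 3x3 morphological closing.
    """
    frame = np.asarray(frame)
    if max_subject_depth_mm <= 0:
        raise ValidationError("max_subject_depth_mm must be positive")
    raw = (frame > 0) & (frame < max_subject_depth_mm)
    if not raw.any():
        raise DetectionError("no foreground below the depth threshold")
    labels, n = ndimage.label(raw)
    if n > 1:
        areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        best_area = areas.max()
        candidates = [i + 1 for i, a in enumerate(areas) if a == best_area]
        if len(candidates) == 1:
            keep = candidates[0]
        else:  # tie: leftmost component by its minimum column
            min_cols = [np.flatnonzero((labels == c).any(axis=0))[0] for c in candidates]
            keep = candidates[int(np.argmin(min_cols))]
        raw = labels == keep
    return _close3(raw)


def _close3(mask: np.ndarray) -> np.ndarray:
    """3x3 morphological closing with edge replication, so regions that
    touch the frame border are not eroded there."""
    padded = np.pad(mask, 1, mode="edge")
    closed = ndimage.binary_closing(padded, structure=np.ones((3, 3), bool))
    return closed[1:-1, 1:-1]


def detect_upper_body(
    frame: np.ndarray,
    detector: str | Callable[[np.ndarray], tuple[int, int, int, int]] = "foreground",
    max_subject_depth_mm: float = 2000.0,
) -> BodyBox:
    """Locate the head-and-shoulders box on a single frame.

    With the ``"foreground"`` backend the box spans the rows of the
    silhouette above its vertical midpoint (head + shoulders), widened to
    the silhouette's full column extent.
    """
    if callable(detector):
        try:
            top, bottom, left, right = detector(frame)
        except Exception as exc:  # noqa: BLE001 - external detector contract
            raise DetectionError(
                f"external upper-body detector failed ({exc}); "
                "try the 'foreground' backend"
            ) from exc
        return BodyBox(int(top), int(bottom), int(left), int(right))
    if detector != "foreground":
        raise ValidationError(f"unknown detector backend {detector!r}")
    mask = segment_foreground(frame, max_subject_depth_mm)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    top, bottom = int(rows[0]), int(rows[-1]) + 1
    mid = (top + bottom) // 2
    if mid <= top:
        raise DetectionError("silhouette too short for an upper-body box")
    return BodyBox(top, mid, int(cols[0]), int(cols[-1]) + 1)


def _turn_angles(poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exterior (turn) angle and convexity flag at every polygon vertex.

    A vertex is convex when the contour turns outward there (the cross
    product of the incoming/outgoing edges matches the polygon's
    orientation); concave notches such as the neck-shoulder junction
    must not be mistaken for shoulders.
    """
    prev = np.roll(poly, 1, axis=0)
    nxt = np.roll(poly, -1, axis=0)
    v_in = poly - prev
    v_out = nxt - poly
    dot = (v_in * v_out).sum(axis=1)
    norm = np.linalg.norm(v_in, axis=1) * np.linalg.norm(v_out, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(dot / np.where(norm == 0, np.nan, norm), -1.0, 1.0)
    cross = v_in[:, 0] * v_out[:, 1] - v_in[:, 1] * v_out[:, 0]
    signed_area = 0.5 * float(
        np.sum(poly[:, 0] * nxt[:, 1] - nxt[:, 0] * poly[:, 1])
    )
    convex = cross * np.sign(signed_area) > 0
    return np.arccos(cosang), convex


def _left_shoulder(mask: np.ndarray, box: BodyBox, epsilon_frac: float) -> tuple[int, int]:
    """Highest-convexity polygon vertex in the left lateral third of *box*.

    The silhouette contour is simplified by Douglas-Peucker with
    tolerance ``epsilon_frac`` of the mask height; among the vertices in
    the left third (1 px margin, since contour coordinates sit half a
    pixel outside the mask) the one with the maximal turn angle wins,
    ties going to the vertex nearer the head (smaller row).
    """
    closed = _close3(mask)
    contours = measure.find_contours(closed.astype(float), 0.5)
    if not contours:
        raise DetectionError("no contour found")
    contour = max(contours, key=len)
    mask_rows = np.flatnonzero(closed.any(axis=1))
    eps = max(1.0, epsilon_frac * (mask_rows[-1] - mask_rows[0] + 1))
    poly = measure.approximate_polygon(contour, tolerance=eps)
    if len(poly) > 1 and np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    if len(poly) < 3:
        raise DetectionError("degenerate contour polygon")
    angles, convex = _turn_angles(poly)

    third = box.width / 3.0
    in_rows = (poly[:, 0] >= box.top - 1) & (poly[:, 0] <= box.bottom)
    in_cols = (poly[:, 1] >= box.left - 1) & (poly[:, 1] <= box.left + third)
    cand = np.flatnonzero(in_rows & in_cols & convex & np.isfinite(angles))
    if cand.size == 0:
        raise DetectionError("no shoulder candidate vertex on one side")
    best = min(cand, key=lambda i: (-angles[i], poly[i, 0]))
    return int(round(poly[best, 0])), int(round(poly[best, 1]))


def detect_shoulders(
    mask: np.ndarray,
    box: BodyBox,
    epsilon_frac: float = 0.02,
) -> ShoulderPair:
    """Shoulder points from the polygon-approximated silhouette contour.

    The left shoulder is the maximal-turn-angle vertex in the left
    lateral third of *box* (see :func:`_left_shoulder`); the right
    shoulder is found by the identical procedure on the horizontally
    mirrored mask, so the detector is mirror-symmetric by construction.
    """
    mask = np.asarray(mask, bool)
    sub = mask[box.top : box.bottom, box.left : box.right]
    if not sub.any():
        raise DetectionError("mask empty within the body box")
    width = mask.shape[1]
    left = _left_shoulder(mask, box, epsilon_frac)
    mirror_box = BodyBox(box.top, box.bottom, width - box.right, width - box.left)
    ml = _left_shoulder(np.flip(mask, axis=1), mirror_box, epsilon_frac)
    right = (ml[0], width - 1 - ml[1])
    if not left[1] < right[1]:
        raise DetectionError("shoulder candidates collapsed to one column")
    return ShoulderPair(left, right)
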