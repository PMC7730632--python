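"""Synthetic breathing-torso depth sequences with exact ground truth.

The simulator renders a seated subject facing a time-of-flight depth
camera: a head ellipse, neck, and torso trapezoid at a fixed camera
distance against a farther background.  Disjoint chest and abdomen
regions on the torso move toward the camera following sinusoidal
compartment waveforms; the two compartments may be phase-lagged
(thoracoabdominal asynchrony).  Optional degradations emulate the
error mechanisms seen with real recordings:

* whole-body depth sway (posture drift that cancels chest excursion),
* vertical sway in pixels,
* clothing smoothing of the displacement field (a shirt stretches over
  the moving surface, blurring its spatial detail),
* per-pixel Gaussian sensor noise and dropout (depth reads 0).

Projection is orthographic with a millimeter-per-pixel pitch derived
from the camera distance and a fixed horizontal field of view; the
pipeline consumes depth values, not reprojected geometry, so full
perspective rendering buys nothing here.  With that pitch, pixel area
(m^2) times displacement (mm) is liters directly, which makes the true
displaced volume — what a spirometer would read — an exact closed-form
function of time.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os

import numpy as np
from scipy import ndimage

from .body_landmarks import ShoulderPair
from .errors import SceneError, ValidationError
from .io_formats import DepthSequence, ReferenceTrace

__all__ = [
    "TorsoScene",
    "BreathingProgram",
    "NoiseModel",
    "GroundTruth",
    "render_sequence",
    "synth_reference_trace",
    "make_cohort",
    "CohortMember",
]

_HALF_FOV_RAD = math.radians(35.0)  # horizontal half field of view


@dataclasses.dataclass(frozen=True)
class TorsoScene:
    """Static geometry of the rendered subject, all lengths in pixels
    unless suffixed otherwise."""

    frame_height: int = 424
    frame_width: int = 512
    camera_distance_mm: float = 1000.0
    background_mm: float = 3000.0
    center_col: int | None = None
    head_center_row: int = 56
    head_rx: int = 34
    head_ry: int = 40
    neck_half_width: int = 16
    shoulder_row: int = 116
    torso_half_width_top: int = 78
    torso_half_width_bottom: int = 86
    hip_row: int = 380
    chest_row_span: tuple[int, int] = (126, 230)
    abdomen_row_span: tuple[int, int] = (240, 350)
    region_inset: int = 10
    # static surface relief: the body is not a plane, and its unevenness
    # also dithers the sensor's integer-millimeter quantization
    relief_amp_mm: float = 2.0
    relief_sigma_px: float = 4.0
    relief_seed: int = 0
    # seated subject: thighs/lap fill the frame below the abdomen at a
    # slightly larger depth than the torso front
    lap_depth_offset_mm: float = 180.0

    def __post_init__(self) -> None:
        if self.center_col is None:
            object.__setattr__(self, "center_col", self.frame_width // 2)
        if not self.shoulder_row < self.hip_row <= self.frame_height:
            raise SceneError("torso rows out of order or outside the frame")
        c0, c1 = self.chest_row_span
        a0, a1 = self.abdomen_row_span
        if not (self.shoulder_row <= c0 < c1 <= a0 < a1 <= self.hip_row):
            raise SceneError("chest/abdomen spans must be disjoint, chest above")
        if self.center_col + self.torso_half_width_bottom >= self.frame_width:
            raise SceneError("torso wider than the frame")

    @classmethod
    def scaled(cls, frame_height: int, frame_width: int, **overrides) -> "TorsoScene":
        """Scene with all default geometry scaled to a new frame size."""
        base = cls()
        fr = frame_height / base.frame_height
        fc = frame_width / base.frame_width
        f = min(fr, fc)
        fields = dict(
            frame_height=frame_height,
            frame_width=frame_width,
            head_center_row=round(base.head_center_row * fr),
            head_rx=max(4, round(base.head_rx * f)),
            head_ry=max(5, round(base.head_ry * f)),
            neck_half_width=max(3, round(base.neck_half_width * f)),
            shoulder_row=round(base.shoulder_row * fr),
            torso_half_width_top=round(base.torso_half_width_top * f),
            torso_half_width_bottom=round(base.torso_half_width_bottom * f),
            hip_row=round(base.hip_row * fr),
            chest_row_span=tuple(round(r * fr) for r in base.chest_row_span),
            abdomen_row_span=tuple(round(r * fr) for r in base.abdomen_row_span),
            region_inset=max(2, round(base.region_inset * f)),
        )
        fields.update(overrides)
        return cls(**fields)

    # -- derived geometry -------------------------------------------------

    @property
    def mm_per_px(self) -> float:
        return 2.0 * self.camera_distance_mm * math.tan(_HALF_FOV_RAD) / self.frame_width

    @property
    def px_area_m2(self) -> float:
        return (self.mm_per_px * 1e-3) ** 2

    def _torso_half_width_at(self, rows: np.ndarray) -> np.ndarray:
        frac = (rows - self.shoulder_row) / max(1, self.hip_row - self.shoulder_row)
        return (
            self.torso_half_width_top
            + frac * (self.torso_half_width_bottom - self.torso_half_width_top)
        )

    def body_mask(self) -> np.ndarray:
        """Head + neck + torso: the surface at camera distance."""
        h, w, cx = self.frame_height, self.frame_width, self.center_col
        rows, cols = np.mgrid[0:h, 0:w]
        head = (
            ((rows - self.head_center_row) / self.head_ry) ** 2
            + ((cols - cx) / self.head_rx) ** 2
        ) <= 1.0
        neck = (
            (rows >= self.head_center_row)
            & (rows < self.shoulder_row)
            & (np.abs(cols - cx) <= self.neck_half_width)
        )
        hw = self._torso_half_width_at(rows)
        torso = (
            (rows >= self.shoulder_row)
            & (rows < self.hip_row)
            & (np.abs(cols - cx) <= hw)
        )
        return head | neck | torso

    def lap_mask(self) -> np.ndarray:
        """Static thigh/lap surface below the torso."""
        h, w, cx = self.frame_height, self.frame_width, self.center_col
        rows, cols = np.mgrid[0:h, 0:w]
        return (
            (rows >= self.hip_row)
            & (np.abs(cols - cx) <= self.torso_half_width_bottom)
        )

    def silhouette_mask(self) -> np.ndarray:
        """Whole foreground subject: body plus lap."""
        return self.body_mask() | self.lap_mask()

    def _region_mask(self, span: tuple[int, int]) -> np.ndarray:
        h, w, cx = self.frame_height, self.frame_width, self.center_col
        rows, cols = np.mgrid[0:h, 0:w]
        hw = self._torso_half_width_at(rows) - self.region_inset
        return (
            (rows >= span[0]) & (rows < span[1]) & (np.abs(cols - cx) <= hw)
        )

    def chest_mask(self) -> np.ndarray:
        return self._region_mask(self.chest_row_span)

    def abdomen_mask(self) -> np.ndarray:
        return self._region_mask(self.abdomen_row_span)

    def relief_field(self) -> np.ndarray:
        """Static smooth depth relief (mm), zero mean, SD relief_amp_mm."""
        if self.relief_amp_mm == 0:
            return np.zeros((self.frame_height, self.frame_width))
        rng = np.random.default_rng(self.relief_seed)
        field = ndimage.gaussian_filter(
            rng.normal(size=(self.frame_height, self.frame_width)),
            self.relief_sigma_px,
        )
        return field * (self.relief_amp_mm / field.std())

    def true_shoulders(self) -> ShoulderPair:
        cx, r = self.center_col, self.shoulder_row
        hw = self.torso_half_width_top
        return ShoulderPair((r, cx - hw), (r, cx + hw))


@dataclasses.dataclass(frozen=True)
class BreathingProgram:
    """Compartmental breathing waveform parameters.

    Breath-to-breath depth varies naturally even at rest, so each breath
    carries a multiplicative amplitude factor drawn once (seeded) with
    fractional spread ``amp_variation``; both compartments share the
    factor (one breath, one depth).  The timing stays strictly periodic.
    """

    rr_bpm: float = 12.0
    chest_amp_mm: float = 4.0
    abdomen_amp_mm: float = 3.0
    phase_lag_deg: float = 0.0
    duration_s: float = 60.0
    pattern: str = "normal"  # "normal" | "deep"
    amp_variation: float = 0.1  # fractional SD of per-breath depth
    amp_seed: int = 0

    def __post_init__(self) -> None:
        if not 4.0 < self.rr_bpm < 40.0:
            raise ValidationError("rr_bpm must lie in (4, 40)")
        if self.chest_amp_mm < 0 or self.abdomen_amp_mm < 0:
            raise ValidationError("amplitudes must be >= 0")
        if not 0.0 <= self.phase_lag_deg <= 180.0:
            raise ValidationError("phase_lag_deg must lie in [0, 180]")
        if self.amp_variation < 0:
            raise ValidationError("amp_variation must be >= 0")

    def deepened(self) -> "BreathingProgram":
        """Deep-breathing variant: 2.5x amplitudes at 0.6x the rate."""
        return dataclasses.replace(
            self,
            rr_bpm=self.rr_bpm * 0.6,
            chest_amp_mm=self.chest_amp_mm * 2.5,
            abdomen_amp_mm=self.abdomen_amp_mm * 2.5,
            pattern="deep",
            amp_seed=self.amp_seed + 1,
        )

    @property
    def period_s(self) -> float:
        return 60.0 / self.rr_bpm

    @property
    def n_breaths(self) -> int:
        """Complete breaths within the programmed duration."""
        return int(np.floor(self.duration_s / self.period_s + 1e-9))

    def breath_factors(self) -> np.ndarray:
        """Per-breath amplitude factors, one per (possibly partial) breath."""
        n = max(1, int(np.ceil(self.duration_s / self.period_s)))
        if self.amp_variation == 0:
            return np.ones(n)
        rng = np.random.default_rng(self.amp_seed)
        return np.clip(rng.normal(1.0, self.amp_variation, n), 0.3, None)

    def _envelope(self, t: np.ndarray) -> np.ndarray:
        g = self.breath_factors()
        k = np.floor(np.asarray(t, float) / self.period_s).astype(int)
        return g[np.clip(k, 0, g.size - 1)]

    # s(t) in [0, 1]: 0 at end-expiration, 1 at end-inspiration
    def chest_phase(self, t: np.ndarray) -> np.ndarray:
        f = self.rr_bpm / 60.0
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * f * np.asarray(t, float)))

    def abdomen_phase(self, t: np.ndarray) -> np.ndarray:
        f = self.rr_bpm / 60.0
        lag = math.radians(self.phase_lag_deg)
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * f * np.asarray(t, float) - lag))

    def chest_displacement_mm(self, t: np.ndarray) -> np.ndarray:
        return self.chest_amp_mm * self._envelope(t) * self.chest_phase(t)

    def abdomen_displacement_mm(self, t: np.ndarray) -> np.ndarray:
        return self.abdomen_amp_mm * self._envelope(t) * self.abdomen_phase(t)


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Sensor and subject-motion degradations; all magnitudes >= 0."""

    pixel_sd_mm: float = 1.5
    dropout_prob: float = 0.005
    sway_amp_mm: float = 0.0
    sway_period_s: float = 30.0  # posture drift, well below the breathing band
    sway_breath_coupled: bool = False  # sway follows the breath phase,
    # moving the whole body away from the camera during inspiration and
    # thereby canceling part of the chest excursion (posture mechanism)
    vertical_sway_px: float = 0.0
    clothing_blur_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pixel_sd_mm",
            "dropout_prob",
            "sway_amp_mm",
            "sway_period_s",
            "vertical_sway_px",
            "clothing_blur_px",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


NoiseModel.NONE = NoiseModel(pixel_sd_mm=0.0, dropout_prob=0.0)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    times: np.ndarray  # frame times, s
    volume_L: np.ndarray  # true displaced volume per frame
    breath_tv_L: np.ndarray  # per complete breath, trough-to-crest
    peak_times_s: np.ndarray  # true end-inspiration instants
    rr_bpm: float
    shoulders: ShoulderPair
    chest_area_m2: float
    abdomen_area_m2: float
    program: BreathingProgram
    scene: TorsoScene

    def volume_at(self, t: np.ndarray) -> np.ndarray:
        """Exact displaced volume (L) at arbitrary times, camera clock."""
        p = self.program
        return (
            self.chest_area_m2 * p.chest_displacement_mm(t)
            + self.abdomen_area_m2 * p.abdomen_displacement_mm(t)
        )

    @property
    def volume_per_mm_L(self) -> float:
        """True volume displaced per mm of mean compartment excursion."""
        return self.chest_area_m2 + self.abdomen_area_m2

    def to_json(self, path: str | os.PathLike) -> None:
        doc = {
            "rr_bpm": self.rr_bpm,
            "breath_tv_L": self.breath_tv_L.tolist(),
            "peak_times_s": self.peak_times_s.tolist(),
            "shoulders": {"left": list(self.shoulders.left), "right": list(self.shoulders.right)},
            "chest_area_m2": self.chest_area_m2,
            "abdomen_area_m2": self.abdomen_area_m2,
            "chest_mask_rle": _rle_encode(self.scene.chest_mask()),
            "abdomen_mask_rle": _rle_encode(self.scene.abdomen_mask()),
            "mask_shape": [self.scene.frame_height, self.scene.frame_width],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
            fh.write("\n")


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Run lengths of the flattened mask, starting with a zero-run."""
    flat = np.asarray(mask, bool).ravel()
    edges = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat.size and flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def render_sequence(
    scene: TorsoScene,
    program: BreathingProgram,
    noise: NoiseModel | None = None,
    fps: float = 30.0,
) -> tuple[DepthSequence, GroundTruth]:
    """Render a breathing depth sequence and its ground truth.

    Depth inside the silhouette is the camera distance minus the local
    displacement (the surface moves toward the camera on inspiration);
    clothing blur smooths the displacement field, sway shifts the whole
    body, and sensor noise/dropout are applied last.
    """
    noise = NoiseModel.NONE if noise is None else noise
    chest = scene.chest_mask()
    abdomen = scene.abdomen_mask()
    if (chest & abdomen).any():
        raise SceneError("chest and abdomen region masks overlap")
    body = scene.body_mask()
    lap = scene.lap_mask()
    if not ((chest | abdomen) & ~body).sum() == 0:
        raise SceneError("region masks leak outside the torso")

    n_frames = int(round(program.duration_s * fps))
    if n_frames < 2:
        raise ValidationError("duration too short for a sequence")
    times = np.arange(n_frames) / fps
    rng = np.random.default_rng(noise.seed)

    chest_area = float(chest.sum()) * scene.px_area_m2
    abd_area = float(abdomen.sum()) * scene.px_area_m2

    d_c = program.chest_displacement_mm(times)  # mm, per frame
    d_a = program.abdomen_displacement_mm(times)
    if noise.sway_amp_mm <= 0:
        sway = np.zeros(n_frames)
    elif noise.sway_breath_coupled:
        sway = noise.sway_amp_mm * program.chest_phase(times)
    else:
        sway = noise.sway_amp_mm * np.sin(2.0 * np.pi * times / noise.sway_period_s)
    vshift = (
        np.round(
            noise.vertical_sway_px * np.sin(2.0 * np.pi * times / noise.sway_period_s)
        ).astype(int)
        if noise.vertical_sway_px > 0
        else np.zeros(n_frames, int)
    )

    frames = np.empty((n_frames, scene.frame_height, scene.frame_width), np.uint16)
    chest_f = chest.astype(float)
    abd_f = abdomen.astype(float)
    relief = scene.relief_field()
    if noise.clothing_blur_px > 0:  # clothing smooths the static surface too
        relief = ndimage.gaussian_filter(relief, noise.clothing_blur_px)
    for k in range(n_frames):
        disp = d_c[k] * chest_f
        disp += d_a[k] * abd_f
        if noise.clothing_blur_px > 0:
            disp = ndimage.gaussian_filter(disp, noise.clothing_blur_px)
            disp = np.where(body, disp, 0.0)
        depth = np.where(
            body,
            scene.camera_distance_mm + relief - disp + sway[k],
            np.where(
                lap,
                scene.camera_distance_mm + scene.lap_depth_offset_mm
                + relief + sway[k],
                scene.background_mm,
            ),
        )
        if vshift[k]:
            depth = np.roll(depth, vshift[k], axis=0)
            if vshift[k] > 0:
                depth[: vshift[k]] = scene.background_mm
            else:
                depth[vshift[k] :] = scene.background_mm
        if noise.pixel_sd_mm > 0:
            depth = depth + rng.normal(0.0, noise.pixel_sd_mm, depth.shape)
        depth = np.clip(np.rint(depth), 1, np.iinfo(np.uint16).max)
        if noise.dropout_prob > 0:
            depth[rng.random(depth.shape) < noise.dropout_prob] = 0
        frames[k] = depth.astype(np.uint16)

    volume = chest_area * d_c + abd_area * d_a
    period = program.period_s
    n_breaths = program.n_breaths
    # per-breath trough-to-crest of the exact volume, on a fine grid
    breath_tv = np.empty(n_breaths)
    peak_times = np.empty(n_breaths)
    for b in range(n_breaths):
        tgrid = np.linspace(b * period, min((b + 1) * period, times[-1]), 2001)
        v_b = (
            chest_area * program.chest_displacement_mm(tgrid)
            + abd_area * program.abdomen_displacement_mm(tgrid)
        )
        breath_tv[b] = float(v_b.max() - v_b.min())
        peak_times[b] = float(tgrid[int(np.argmax(v_b))])

    truth = GroundTruth(
        times=times,
        volume_L=volume,
        breath_tv_L=breath_tv,
        peak_times_s=peak_times,
        rr_bpm=program.rr_bpm,
        shoulders=scene.true_shoulders(),
        chest_area_m2=chest_area,
        abdomen_area_m2=abd_area,
        program=program,
        scene=scene,
    )
    return DepthSequence(frames, times), truth


def synth_reference_trace(
    truth: GroundTruth,
    sample_rate: float = 100.0,
    trigger_lag_s: float = 0.0,
    volume_noise_sd_L: float = 0.0,
    seed: int = 0,
) -> ReferenceTrace:
    """Spirometer-style volume trace on its own clock.

    The spirometer starts *trigger_lag_s* before the camera; the trigger
    flag rises at that lag on the trace's clock, marking camera time 0.
    """
    if trigger_lag_s < 0:
        raise ValidationError("trigger_lag_s must be >= 0")
    duration = trigger_lag_s + float(truth.times[-1])
    n = int(np.floor(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    v = truth.volume_at(t - trigger_lag_s)
    if volume_noise_sd_L > 0:
        v = v + np.random.default_rng(seed).normal(0.0, volume_noise_sd_L, n)
    trig = (t >= trigger_lag_s - 1e-12).astype(int)
    return ReferenceTrace(t, v, trig)


@dataclasses.dataclass(frozen=True)
class CohortMember:
    subject_id: int
    sex: str  # "male" | "female"
    clothing: str  # "undressed" | "tshirt"
    scene: TorsoScene
    program: BreathingProgram
    noise: NoiseModel


# chest-circumference priors (cm): male 103.5 +/- 10.2, female 87.4 +/- 13.4
_CHEST_CIRC_CM = {"male": (103.5, 10.2), "female": (87.4, 13.37)}


def make_cohort(
    n_subjects: int,
    seed: int = 0,
    clothing: str = "undressed",
    frame_height: int = 212,
    frame_width: int = 256,
    duration_s: float = 60.0,  # one minute of normal breathing per session
    pixel_sd_mm: float = 1.5,
    dropout_prob: float = 0.005,
    sway_amp_mm: float = 0.0,
) -> list[CohortMember]:
    """Reproducible simulated cohort, alternating male/female subjects.

    Torso widths derive from sex-specific chest-circumference priors
    (treating the torso as a cylinder seen face-on); breathing rate and
    compartment amplitudes vary across plausible resting ranges.  A
    T-shirt adds spatial smoothing of the displacement field.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    if clothing not in ("undressed", "tshirt"):
        raise ValidationError("clothing must be 'undressed' or 'tshirt'")
    rng = np.random.default_rng(seed)
    base = TorsoScene.scaled(frame_height, frame_width)
    members = []
    for i in range(n_subjects):
        sex = "male" if i % 2 == 0 else "female"
        mu, sd = _CHEST_CIRC_CM[sex]
        circ_cm = float(np.clip(rng.normal(mu, sd), 65.0, 130.0))
        diameter_mm = circ_cm * 10.0 / math.pi
        half_w = int(round(diameter_mm / base.mm_per_px / 2.0))
        half_w = int(np.clip(half_w, base.neck_half_width + 4, frame_width // 2 - 8))
        scene = dataclasses.replace(
            base,
            torso_half_width_top=half_w,
            torso_half_width_bottom=min(half_w + 4, frame_width // 2 - 6),
            relief_seed=int(rng.integers(0, 2**31 - 1)),
        )
        program = BreathingProgram(
            rr_bpm=float(rng.uniform(10.0, 18.0)),
            chest_amp_mm=float(rng.uniform(2.5, 6.0)),
            abdomen_amp_mm=float(rng.uniform(1.5, 5.0)),
            phase_lag_deg=0.0,
            duration_s=duration_s,
        )
        noise = NoiseModel(
            pixel_sd_mm=pixel_sd_mm,
            dropout_prob=dropout_prob,
            sway_amp_mm=sway_amp_mm,
            clothing_blur_px=2.0 if clothing == "tshirt" else 0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        members.append(CohortMember(i, sex, clothing, scene, program, noise))
    return members
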