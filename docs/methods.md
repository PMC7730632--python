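# Methods

`depthresp` estimates per-breath tidal volume (TV, liters) and
respiratory rate (RR, breaths per minute) of a seated subject from a
time-of-flight depth-camera recording of the chest and abdomen,
calibrated against a spirometer-style reference volume trace. This note
documents the model, the parameter choices, what the synthetic data
generator does and does not emulate, and the package's known limits.

## Measurement model

A depth camera facing a seated subject reports, per pixel, the distance
to the body surface in millimeters. During inspiration the chest and
abdominal walls move toward the camera; averaged over a suitable region
of interest (ROI), that depth excursion is approximately proportional
to the inhaled air volume. The pipeline is:

1. **Landmarks** (initial frame only). The subject is segmented from
   the background by a depth threshold (largest connected component,
   3×3 closing to heal sensor dropout). The upper-body box is either
   supplied by an external detector (a pluggable callable, e.g. a
   pretrained cascade classifier on the infrared image) or derived from
   the foreground silhouette. Shoulders are found on the
   Douglas–Peucker-approximated silhouette contour as the
   maximal-turn-angle *convex* vertex in each lateral third of the box
   — the corner where the neck's descent turns onto the shoulder line.
   The right shoulder is detected by running the left-shoulder
   procedure on the mirrored mask, which makes the detector
   mirror-symmetric by construction.
2. **Tentative ROI.** Top at the lower shoulder, sides an arm's width
   inside each shoulder (default 15% of the shoulder span per side),
   bottom provisionally at the image bottom.
3. **Adaptive ROI bottom.** The tentative ROI is tiled with 19×19 px
   unit areas slid every 10 px. Each unit's mean valid-pixel depth per
   frame, resampled to 30 Hz, is an elemental waveform; units in a row
   are averaged into the row waveform W_i. One global breath
   segmentation of the tentative-ROI mean signal provides
   valley-to-valley windows; each row's amplitude is its mean
   within-window excursion (max − min). Row amplitudes are normalized
   to an amplitude-ratio profile, and the running sum from the top row
   fixes the final ROI bottom at the first row where it reaches 90%.
   Rows that barely breathe (lap, chair, background) are thereby
   excluded.
4. **Respiratory signal.** Mean valid-pixel depth over the final ROI,
   negated (so the signal *rises* during inspiration), baseline-removed,
   resampled to a uniform 30 Hz grid, and smoothed with a 0.5 s
   zero-phase moving average. Breaths are local maxima with an adaptive
   prominence threshold and ≥ 1.5 s spacing; the valley between
   consecutive peaks is end-expiration. Per-breath amplitude is
   x[peak] − x[preceding valley]; a "valley" at the very first sample
   cannot be confirmed, so the leading incomplete breath is dropped.
5. **Calibration and estimation.** Ordinary least squares of reference
   TV on depth amplitude (reference TV as objective variable), fitted
   per stratum (sex × clothing), pooled, or per subject. TV is then
   slope·amplitude + intercept, clipped at zero with a warning count;
   RR per breath is 60 / peak-to-peak interval. The reference volume
   trace is processed with the *same* resample/smooth/segment chain
   (prominence floor in liters instead of millimeters).
6. **Agreement.** Breaths of the two instruments are paired greedily by
   nearest peak time within 2 s, after aligning clocks via the recorded
   trigger (the reference channel flags the instant the camera started).
   Reported statistics: mean absolute relative TV error (MARE, %);
   Bland–Altman bias with its t-based 95% CI and 1.96·SD limits of
   agreement; proportional bias as the Pearson correlation of
   difference vs pair mean with its two-sided p-value; and the count of
   breaths whose RR difference strictly exceeds 1 BPM.

## Parameters

| parameter | default | unit | note |
|---|---|---|---|
| `unit_size` | 19 | px | published value |
| `stride` | 10 | px | published value |
| `sample_rate_hz` | 30 | Hz | published value |
| `cutoff` | 0.90 | — | published value; first crossing, ≥ comparison with 1e−12 slack so that n equal rows cross exactly where exact arithmetic says |
| `arm_width_fraction` | 0.15 | of shoulder span | the method says only "inside the approximate arm's width" |
| `window_s` | 0.5 | s | smoothing window; passes the < 1 Hz respiratory band, suppresses sensor jitter |
| `min_interval_s` | 1.5 | s | caps detectable RR at 40 BPM |
| `prominence_floor_mm` | 0.5 | mm | adaptive threshold is max(floor, 20% of the median peak prominence) |
| `ref_prominence_floor_L` | 0.05 | L | same detector on the volume trace |
| `match_window_s` | 2.0 | s | breath pairing window |
| `max_subject_depth_mm` | 2000 | mm | foreground threshold |
| `include_intercept` | True | — | zero-intercept fit available; with-intercept gave uniformly lower held-out error on simulated cohorts |

All of these are `RunConfig` keys (YAML file + CLI flags); the ones the
method statement leaves open are logged at INFO level on every run.

## The synthetic torso

The generator renders an orthographic depth view of a seated subject:
head ellipse, neck, torso trapezoid at the camera distance (default
1000 mm), thighs/lap below the hips 180 mm farther, background at
3000 mm. Chest and abdomen regions on the torso move toward the camera
as phase-locked raised-cosine compartment waveforms; per-breath depth
varies by a seeded multiplicative factor (10% SD — resting breathing is
not metronomic, and without it all calibration amplitudes coincide and
the regression is undefined). With the fixed mm-per-pixel pitch
(derived from the camera distance and a 70° horizontal field of view),
pixel area in m² times displacement in mm is liters, so the true
displaced volume — what a spirometer would integrate — is known in
closed form at every instant; per-breath true TV is its trough-to-crest
excursion.

The torso carries a static smooth relief field (SD 2 mm): the body is
not a plane, and without relief the integer-millimeter sensor output
quantizes the ROI mean into discrete levels (every flat-region pixel
crosses the rounding threshold in the same frame). Degradations, all
optional and seeded: per-pixel Gaussian noise (default 1.5 mm) and
dropout (0.5%, pixels read 0), free-running whole-body depth sway
(posture drift; default period 30 s, clearly below the breathing band —
sway *inside* the breathing band is physically indistinguishable from
respiration and no detector could separate it), breath-coupled sway
(the body moves away from the camera during inspiration, canceling part
of the chest excursion — the posture mechanism behind deep-breathing
underestimation), vertical pixel sway, and clothing smoothing of the
displacement field (a shirt blurs the moving surface's spatial detail).

Simulated cohorts draw torso widths from sex-specific chest-
circumference priors (male 103.5 ± 10.2 cm, female 87.4 ± 13.4 cm,
treating the torso as a cylinder seen face-on), and vary resting rate
(10–18 BPM) and compartment amplitudes (chest 2.5–6 mm, abdomen
1.5–5 mm). Each subject contributes one minute of normal breathing and
five deep breaths (2.5× amplitude, 0.6× rate), both entering one
regression, mirroring the acquisition protocol.

**What the simulator does not emulate:** perspective projection and
lateral surface motion; garment dynamics beyond spatial smoothing;
irregular breath timing (rates are constant within a recording);
multi-person scenes; infrared imagery. Passing tests therefore show
that the algorithm recovers what it is designed to recover under
controlled torso-like geometry — they do not certify accuracy on real
recordings.

## What recovery on simulated cohorts shows

On noiseless recordings, per-breath RR is exact to within the sampling
grid and per-subject-calibrated held-out TV error is ≈ 0.1%. With
sensor noise, dropout and 2 mm posture sway, per-stratum calibration
recovers held-out TV with MARE in the low-to-mid teens — the same
band the method reports on real subjects. Two effects dominate that
number, both intrinsic to the single-ROI method rather than to the
simulation: (a) between-subject spread of the amplitude-to-volume
slope (the ROI-mean amplitude carries a subject-geometry factor that a
pooled regression cannot absorb), and (b) posture sway, which the depth
camera cannot distinguish from breathing along the optical axis and
which adds a per-breath amplitude error of roughly
sway_amplitude · 2π · breath_period / sway_period. Motion compensation
is explicitly out of scope here, as in the source method.

## Numerical choices and degenerate inputs

- Cumulative amplitude-ratio crossing uses ≥ cutoff − 1e−12; with ten
  equal rows the ninth row's running sum is 0.8999999999999999 in
  floating point and must still count as reaching 90%.
- Units with > 50% invalid pixels in > 10% of frames are flagged
  invalid and excluded (never silently zeroed); rows with no valid unit
  are dropped before normalization.
- The smoothing window is rounded to an odd sample count and shrinks
  symmetrically at the edges (no padding bias); constant signals pass
  through unchanged.
- Ties in the shoulder turn-angle score go to the vertex nearer the
  head; concave vertices (the neck-shoulder notch) are excluded.
- Morphological closing pads with edge replication so silhouettes
  touching the frame border are not eroded there.
- Zero amplitude variance (metronomic breathing) is a fit error, not a
  NaN slope; negative predicted volumes clip to zero with a counter.
- Bland–Altman with zero difference spread sets a degenerate flag and
  collapses the CI to the bias.

## Design choices where the method statement was open

- **Detector contract.** The original system used a pretrained cascade
  classifier on the infrared image; no trained model can be assumed
  present, so the default backend is depth-threshold foreground
  segmentation, with any external detector accepted as a callable.
- **Breath windows for row amplitudes** come from one global
  segmentation of the tentative-ROI mean signal, applied to every row;
  per-row peak detection is unstable for low-amplitude rows.
- **Leading breath** of every recording is dropped (no confirmed
  end-expiration before it); RR is anchored at each interval's closing
  peak.
- **Intercept** is included in the calibration regression by default
  (whether the original regression had one is unstated); the
  zero-intercept variant is available and measured uniformly worse on
  held-out simulated data.
- **Pairing** of estimated and reference breaths is greedy
  nearest-peak-time within 2 s — deterministic, with unmatched-breath
  accounting.
- **Problem sizes.** Tests and the acceptance script run quarter-size
  frames (212×256); geometry scales proportionally and all thresholds
  are scale-free. Cohort runs use 10 subjects, one minute of normal
  breathing plus five deep breaths each.

## Known limitations

- A single rectangular ROI cannot represent left/right-asymmetric
  thoracic motion, and a fixed ROI cannot follow posture change during
  deep breathing; both are documented failure modes of the method and
  are reproduced directionally by the simulator's mechanism knobs.
- Calibration transfers across subjects only up to the
  subject-geometry factor in the slope; per-subject calibration is
  strongly preferable when a reference instrument is available.
- The trigger-based alignment assumes both clocks run at the same rate;
  drift between instruments is not modeled or corrected.
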