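# Methods

## Model of immobility

swimscore treats immobility as a per-second binary state defined
operationally: second *s* is immobile when the mean per-frame Δ-area %
within that second is strictly below a threshold *c*. This assumes
(i) a single animal that stays inside the analysis region, (ii) enough
animal/background contrast for a global threshold to isolate the animal,
and (iii) that body-shape change — swimming strokes, struggling — is the
behaviorally relevant motion, so that changes in the binarized
silhouette's pixel count track mobility. Pure rigid translation changes
the rasterized area only marginally, which is acceptable for FST/TST
where a mobile animal continuously deforms; centroid tracking and
optical flow are deliberately out of scope.

Three per-frame features are supported: binarized area (default,
validated for both assays), major-axis length of the best-fit ellipse,
and frame-by-frame variation (XOR pixel count between consecutive
masks, normalized by the previous frame's area). The ratio uses the
previous *frame's* feature as denominator and the unsigned difference —
signed changes would cancel within a second and stop measuring motion
magnitude. A per-second denominator variant exists as a config escape
hatch but is not validated.

## Pipeline and parameters

1. **Video access** (`video_io`). Frames are cropped to the bounding
   rectangle of a user polygon and converted to 8-bit luminance with
   BT.709 weights (0.2125, 0.7154, 0.0721), recorded in every run log.
   Second *s* covers frames `[s·fps, (s+1)·fps)` from the window start,
   half-open, with window boundaries rounded to the nearest frame.
   Native fps is used throughout; 15 fps is the validated reference.
2. **Segmentation** (`segmentation`). Optional background subtraction
   (|frame − background|, which makes the method independent of coat
   color), Gaussian blur (`blur_sigma`, default 2 px — enough to
   suppress single-pixel sensor noise without eroding the silhouette),
   Otsu or manual global threshold, removal of components below
   `min_component_px` (default 50 px, rejects glare/ripple speckle),
   then largest-component selection. A frame with no acceptable
   component yields an *empty, flagged* mask, not an error.
   Background fill replaces the pixels inside a user-marked animal
   outline with the median of a 3-px ring just outside it — a simple,
   deterministic inpainting adequate for uniform lab backgrounds.
3. **Motion statistic** (`motion_metric`). Frames whose predecessor has
   zero area give an invalid (NaN) ratio; a second with no valid frame
   is invalid and inherits the previous second's label (leading invalid
   seconds default to mobile) and is flagged in the output.
   A value exactly equal to the threshold counts as **mobile** (strict
   `<`); the tie-break is arbitrary but fixed.
4. **Bout analytics** (`bout_analysis`). A bout is any maximal run of
   ≥ 1 s; no minimum-bout smoothing. Latency with zero immobile seconds
   is reported as absent (empty CSV cell), never 0 or the track length.
   Both the longest immobility and the longest mobility bout are
   reported. Blocks are consecutive, non-overlapping, last-may-be-short.

## Threshold calibration

Manual scorers react 1–3 s after a state change, so seconds adjacent to
manual-label transitions are systematically unreliable. Calibration
removes `k` seconds **on each side** of every label transition
(default k = 3; the per-side reading of "around the boundaries" is an
interpretation, fixed and documented), pools the kept seconds across
calibration videos (a 60% split of videos, deterministic in the seed),
and sweeps the threshold over exactly the distinct observed trace
values plus one sentinel below the minimum and one above the maximum.
This grid choice makes the trapezoidal AUC identical to the
Mann–Whitney pair-ordering probability (ties ½) and makes the optimum
cut-point — the argmax of Sensitivity × Specificity, ties broken toward
the smaller threshold — independent of any sweep step size. Shipped
defaults when no calibration is run: 2.5861 (FST), 0.7808 (TST).

Agreement statistics use the standard Bland–Altman construction with
the sample (n−1) SD for the 1.96-SD limits, and the product-moment
correlation with the two-sided p from the t transform on n−2 df.

## Synthetic fixtures: what they emulate, and what they do not

`synthetic_fixtures` renders a dark ellipse (intensity 40) on a bright
background (200) with Gaussian pixel noise (SD 5 by default on the
8-bit scale), at 15 fps, 160×120 px, following a known per-second
schedule — mirroring the validated acquisition setup (high-contrast
animal, uniform background, 15-fps 5-min recordings). During mobile
seconds the blob performs an integer-pixel random walk (amplitude
3 px/frame) and its horizontal semi-axis oscillates sinusoidally at
1 Hz with fractional amplitude 0.25 — area-preserving in the mean, and
producing per-second Δ-area % around 7, far above both shipped
thresholds. During immobile seconds the shape is frozen (not reset, so
no area jump at transitions) and only pixel noise remains, yielding
Δ-area % around 0.2, far below both thresholds. Simulated "human"
labels delay every true transition by an independent uniform 1–3-s lag,
resolving overtaking transitions chronologically.

Videos are written as uncompressed 8-bit grayscale AVI through the
package's own minimal RIFF writer, and read back through the matching
reader, so fixtures are bit-exact and decodable with no codec stack.

What the fixtures do **not** emulate: water ripples, reflections and
glare, tail-climbing artifacts, occlusion, non-elliptical posture, or
lighting drift. Passing the end-to-end tests therefore demonstrates the
correctness of the measurement chain on scenes satisfying the method's
stated assumptions — not segmentation robustness on difficult real
footage, which is governed by the blur/threshold/size parameters above.

## Numerical choices and degenerate inputs

- Otsu is skipped (empty flagged mask) on flat frames (intensity range
  < 1e-9) where it is undefined.
- ROC construction requires both classes among kept seconds and raises
  a named error otherwise; label CSVs are validated for gaps,
  duplicates and non-binary values with distinct error types.
- The calibration split size is `round(fraction · n)` clamped so both
  sets are non-empty; the shuffle is a seeded NumPy permutation.
- All randomness (fixture rendering, lag draws, splits) flows from
  explicit integer seeds; re-running any command with the same inputs
  and seed reproduces byte-identical outputs.

## Problem sizes used in the checks

End-to-end recovery runs on one rendered 300-s, 15-fps, 160×120 video
with 20-s alternating states and noise SD 5 (the generator's default
study conditions). The exclusion-window trend check uses 50 replicates
of scaled-down renders (80 s, 10 fps, 96×64-px frames with a smaller
ellipse) — the trend is a rank statistic on the per-second trace, so it
does not depend on the frame count per second. Exhaustive bout-summary
verification covers all 8190 binary tracks up to length 12.

## Known limitations

- Single-animal scenes only; no multi-arena batching in one video.
- Compressed containers need an external ffmpeg-backed imageio plugin;
  the built-in decoder covers uncompressed AVI only.
- The shipped thresholds were calibrated on mouse FST/TST footage at
  15 fps; other species, frame rates or optics warrant recalibration
  with the `calibrate` command.
- The background model is a single static frame; slow background drift
  (water ripple build-up) is not tracked.
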