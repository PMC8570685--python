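# swimscore

Automated, per-second scoring of rodent immobility in the **forced swim
test (FST)** and **tail suspension test (TST)** from video — for
behavioral neuroscientists who currently score these assays with a
stopwatch. Manual scoring is slow and has large observer-to-observer
variability; swimscore replaces it with a deterministic, calibratable
video-analysis pipeline plus the agreement statistics needed to validate
it against human scorers.

## Method

Each analyzed frame is cropped to a user-supplied region of interest,
binarized into an animal mask (optional background subtraction, Gaussian
blur, Otsu or manual global threshold, largest-connected-component
selection), giving the animal's area `A(t)` in pixels. The motion
statistic for frame *t* is the unsigned area change as a percentage of
the previous frame's area,

```
Δarea%(t) = 100 · |A(t) − A(t−1)| / A(t−1),
```

averaged over the frames of each second. A second is **immobile** when
its mean Δarea% falls strictly below a threshold *c*. Shipped defaults
are the recommended calibrated values `c = 2.5861` (FST) and
`c = 0.7808` (TST). Downstream analytics report % time immobile,
latency to the first immobility bout, longest immobility/mobility bouts,
block-wise immobility and a raster plot.

Thresholds can be recalibrated against manual per-second scores: videos
are split 60/40 into calibration/validation sets, `k` seconds on each
side of every manual-label transition are excluded (human scorers lag
state changes by 1–3 s; default `k = 3`), an ROC curve is built over all
observed Δarea% values (positive class = immobile, predicted positive
when the value < *c*; the trapezoidal AUC then equals the Mann–Whitney
pair-ordering probability), and the optimum cut-point maximizes
`Sensitivity(c) × Specificity(c)`. Bland–Altman bias with 95% limits of
agreement and Pearson correlation quantify automated-vs-manual
agreement.

Because no reference mouse videos are distributed, the package includes
a first-class synthetic fixture generator: a dark elliptical blob on a
bright noisy background following a known per-second mobility schedule,
written as uncompressed grayscale AVI together with ground-truth labels
and optional lag-simulated "human" labels.

## Worked example

```bash
swimscore simulate --seconds 120 --period 20 --seed 4 --out fixture.avi
swimscore analyze fixture.avi --test-type TST --block-length 30 --out results
```

prints

```
percent immobile: 50.00
latency to immobility (s): 20
longest immobility bout (s): 20
longest mobility bout (s): 20
outputs in results
```

The fixture alternates 20-s mobile/immobile blocks starting mobile, so
the true immobility fraction is 50%, the first immobile second is second
20, and every bout lasts 20 s — all recovered exactly. `results/`
contains the per-second trace and labels (`trace.csv`, `labels.csv`),
the bout summary and 30-s block counts (`summary.csv`, `blocks.csv`;
here blocks hold 10, 10, 20 and 20 immobile seconds), a raster plot and
a threshold-colored trace plot, and `run_log.json` with every resolved
parameter — including the TST default threshold 0.7808 that was applied
because no `--threshold` flag was given.

Calibration and agreement run the same way:

```bash
swimscore calibrate --video v1.avi --labels v1_manual.csv \
                    --video v2.avi --labels v2_manual.csv --k 3
swimscore agree auto_summaries.csv manual_summaries.csv --column percent_immobile
```

All commands are thin wrappers over library functions
(`swimscore.cli.run_analysis`, `swimscore.calibrate_pooled`,
`swimscore.agreement_report`, ...), so everything is scriptable.

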