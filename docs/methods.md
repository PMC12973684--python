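# Methods

## Problem and signal model

Inspired ambient air cools the nostril rim; expired air warms it. The
nostril-region surface temperature therefore oscillates at the respiratory
rate, which in calves lies between 0.2 and 1.0 Hz (12–60 breaths/min). A
regurgitation — the start of a rumination cycle — closes the glottis
briefly (apnea) and is followed by a compensatory deep inspiration, visible
as one unusually deep minimum in the thermal breathing signal within a few
seconds of the event. The package's task is to decide, from the depth of a
breath minimum alone, whether it is such a post-regurgitation deep
inhalation (PRDI) or an ordinary non-rumination inhalation (NRI).

## Signal chain

Processing order is fixed: band-pass → z-score → centered smoothing →
minima detection.

* **Band-pass.** 3rd-order Butterworth, default edges exactly at the
  physiological band (0.2–1.0 Hz), applied forward–backward
  (`sosfiltfilt`) with reflective (even) edge padding. The filter family
  and order are a design choice; zero phase is not — event depths are
  assigned to 3-second wall-clock windows, and a causal filter's group
  delay would bias that assignment. The pad length is one cycle of the low
  edge (~44 samples at 8.7 samples/s); shorter inputs are rejected with the
  required minimum named in the error.
* **Standardization.** Per recording (or per segment), z-score with the
  sample standard deviation (n−1). This removes baseline and scale
  differences across animals, ambient temperatures (field range roughly
  9–34 °C) and camera distances, so events can be pooled across
  recordings. Population vs sample denominator changes depths by <1 % at
  realistic lengths; the sample form was chosen and documented rather than
  left ambiguous.
* **Smoothing.** Centered moving average, window 9 samples ≈ 1.03 s at
  8.7 samples/s. Edges use the truncated centered window (never NaN or
  reflection): the output keeps the input length and no synthetic extrema
  are created at the boundaries.
* **Minima.** `scipy.signal.find_peaks` on the negated signal with a
  minimum separation of 0.6 s and minimum prominence of 0.2 z. Neither
  constraint is physiologically given a priori; 0.6 s is just above half
  the fastest breath period (1 s at 1 Hz) and 0.2 z sits above the
  post-smoothing noise floor. Both are exposed in the config. Of two
  candidate minima closer than the separation, the deeper survives.

Missing samples (frames where nostril segmentation failed) are linearly
interpolated across gaps up to 1.0 s; longer gaps raise, and the recording
should be split there — interpolating a long gap would fabricate breaths.

## Labeling and classification

Each annotated regurgitation at time *t* opens the half-open window
[*t*, *t*+3). Half-open avoids double counting at exact boundaries; an
event at *t*+3 exactly is NRI. Every breath minimum inside the union of
windows is PRDI. Prediction is a single threshold τ on depth with
ties-to-positive (`depth ≤ τ` ⇒ PRDI), matching the ROC convention.

## Evaluation

* **Mann–Whitney U.** Orientation U = #{(a,b): a&lt;b} + ½·#ties over
  (PRDI, NRI) depth pairs. The two-sided p-value is exact for
  n₊·n₋ ≤ 400 — permutation distribution of U with ties, computed by
  subset-sum dynamic programming over doubled midranks — and a tie- and
  continuity-corrected normal approximation above that. The exact path
  reproduces `scipy.stats.mannwhitneyu(method="exact")` to 1e-12 in the
  tie-free case (scipy is used only as a test oracle).
* **ROC/AUC.** Thresholds are the distinct observed depths; the
  trapezoidal AUC of this curve equals the tie-aware concordant-pair
  fraction U/(n₊·n₋) identically, which the tests assert to 1e-12.
* **Threshold sweep.** Candidate thresholds are the midpoints between
  consecutive distinct depths plus one candidate below the minimum and one
  above the maximum, so tie behaviour at candidates is unambiguous. At each
  candidate: sensitivity, specificity, G-mean, balanced accuracy (full
  precision internally; 2 decimals only in printed reports). The operating
  point is the midpoint of the maximal contiguous candidate run attaining
  the maxima of both G-mean and balanced accuracy simultaneously. When the
  two argmax sets are disjoint (possible under strong class imbalance), the
  balanced-accuracy plateau is used and the fallback is logged; when
  several runs tie in length, the earliest is taken.

The model/results API (`PRDIThresholdModel` → `PRDIThresholdResults`)
packages this: the fit sweeps and selects, the results object carries AUC,
U, p, per-class medians, the operating-point metrics, `summary()`,
`predict()` and plotting.

## Synthetic recordings

The simulator generates the conditions the method assumes, with ground
truth:

* **Breathing.** Sinusoid at `breath_rate_hz` (default 0.5 Hz) plus a
  0.2-amplitude second harmonic and per-breath log-normal amplitude jitter
  (σ = 0.1, settable to 0), so the pipeline cannot rely on exact
  sinusoidality. Default amplitude 0.5 °C around a 30 °C baseline.
* **Regurgitations.** Inter-event intervals from a truncated normal
  (mean 37.5 s, sd 9.73 s, floor 10 s — field statistics for calves). Each
  onset is snapped so that the deepened trough falls exactly a quarter
  breath period after apnea end; this guarantees the true PRDI time lies
  inside the 3-s window at physiological settings. If snapping would
  violate the minimum gap, the event is pushed to the next breath cycle
  (adds <0.1 s bias to the mean interval; the 200-replicate test checks the
  mean to ±2 s).
* **Apnea and PRDI.** Oscillation amplitude ramps to zero over 0.1 s and
  holds for `apnea_s` (default 1.0 s — the apnea duration is a modeling
  choice, not a measured value); the first inspiratory half-cycle after
  apnea end is scaled by `prdi_depth_factor` (default 2.0).
* **Drift and noise.** Drift is a 0.01-Hz sinusoid plus a scaled random
  walk (default total amplitude 0.2 °C), standing in for ambient and
  hand-held-camera variation; measurement noise is white Gaussian
  (default sd 0.1 °C).
* **Frames.** `render_frames` paints the thermal-grid footprint of a
  nostril ellipse (mask rendered at RGB resolution, default 1080×1440,
  downscaled by the same block mapping the extractor uses) with the series
  value over a 5 °C-cooler background, with optional per-frame mask jitter
  and pixel noise. Noiseless rendering round-trips through extraction to
  1e-6 °C.

What the simulator does *not* model: remastication jaw rhythm, head motion,
acoustics, and radiometric camera physics beyond additive offsets/noise.
Passing tests therefore show that the chain recovers events of the assumed
shape under drift and noise — not that the thresholds transfer to field
recordings, where mask quality, motion artifacts and physiological
variability are all harsher. Consistent with that, absolute synthetic depth
values (e.g. NRI median ≈ −0.85 z) need not match field values; the
relative structure (PRDI ≈ 2× deeper before smoothing) is what the
generator controls.

## Problem sizes and numerical choices

The packaged studies use 28–30 recordings of 120 s (the cohort/recording
scale of a realistic short-session field study) at 8.7 samples/s; at these
sizes the full pipeline runs in well under a second per cohort. Plateau
membership uses a 1e-12 tolerance; mask downscaling maps source-pixel
centres (`floor((r+0.5)·h/H)`); fs is re-estimated from timestamps and
falls back to the median frame interval when jitter exceeds 1 %. All
randomness flows through `numpy.random.SeedSequence` children of a single
seed, so every artifact is bit-reproducible.

## Known limitations

* Regurgitation annotations are taken as ground truth; the package does not
  detect regurgitations from video or audio.
* Recordings are processed offline; zero-phase filtering is incompatible
  with streaming operation by design.
* Mask→thermal registration is uniform scaling only; parallax between the
  RGB and thermal optical paths is out of scope.
* The Mask R-CNN nostril segmenter that produces real masks is upstream of
  this package; here masks are inputs (or synthesized).
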