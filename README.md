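# thermobreath

Non-contact detection of **post-regurgitation deep inhalation (PRDI)** in
cattle from nostril-temperature breathing signals.

Rumination is a key welfare indicator in cattle, but conventional detectors
(noseband pressure sensors, accelerometers) must be strapped to each animal.
A fully non-contact alternative is to film the muzzle with an infrared
camera: nostril-region surface temperature oscillates with breathing —
cooling on inspiration, warming on expiration. Each regurgitation (the start
of a rumination cycle) is accompanied by a brief apnea followed by a
compensatory deep inspiration, which shows up as an unusually deep minimum
in the thermal breathing signal. `thermobreath` implements the whole chain
that turns thermal frames into that decision, plus a seeded simulator so
every stage is testable without field footage.

## Method

1. **Extraction** — per frame, a binary nostril mask (possibly at RGB
   resolution) is downscaled onto the thermal grid and the masked pixels are
   reduced (mean by default) to one temperature sample, yielding a series at
   ~8.7 samples/s.
2. **Breathing signal** — zero-phase Butterworth band-pass over the bovine
   respiratory band (0.2–1.0 Hz, i.e. 12–60 breaths/min), per-recording
   z-score standardization, then a centered moving average (window 9 ≈
   1.03 s).
3. **Breath events** — local minima of the smoothed signal; each minimum's
   z-value is the breath's *depth* d (more negative = deeper inhalation).
4. **Labels** — every event inside a 3-s half-open window after an annotated
   regurgitation is PRDI; all others are NRI (non-rumination inhalation).
5. **Threshold model** — classify PRDI when d ≤ τ. The fit sweeps all
   effective τ, computes sensitivity, specificity,
   G-mean = √(sens·spec) and balanced accuracy = (sens+spec)/2, takes the
   plateau where both are maximal and reports its midpoint; discrimination
   is summarized by the ROC AUC, which equals the tie-aware Mann–Whitney
   concordance U/(n₊·n₋).

## Worked example

```python
import thermobreath as tb

# 28 two-minute synthetic recordings at default physiological conditions,
# analyzed end to end and pooled after per-recording standardization
events = tb.simulate_study(28, seed=1)
res = tb.fit_pooled(events)
print(res.summary())
```

```
PRDI depth-threshold model
==============================================
events (PRDI / NRI)           76 / 1576
median depth PRDI (z)         -1.14
median depth NRI (z)          -0.85
Mann-Whitney U                114898.0
p-value (two-sided)           8.74e-42
AUC                           0.96
----------------------------------------------
optimal threshold (z)         -1.02
plateau                       [-1.02, -1.02]
sensitivity                   0.87
specificity                   0.94
G-mean                        0.90
balanced accuracy             0.90
==============================================
```

PRDI minima are clearly deeper than NRI minima (medians −1.14 vs −0.85 z,
Mann–Whitney p ≪ 0.001); depth alone separates the classes with AUC 0.96 on
this synthetic cohort, and the selected threshold −1.02 sits between the two
class medians. `res.plot_roc()` and `res.plot_metric_curves()` draw the ROC
and the G-mean/balanced-accuracy curves.

The same chain is scriptable from a shell:

```bash
thermobreath simulate --seed 7 --out sim/           # series + ground truth
thermobreath analyze --series sim/series.csv \
    --annotations sim/regurgitations.csv --out events.csv
thermobreath evaluate --events events.csv --out metrics.json
thermobreath run --simulate --seed 7 --out run/     # composite, reproducible
```

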