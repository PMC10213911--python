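# icptools

Automated detection and classification of true Ca²⁺ events in
intracellular Ca²⁺ profiles (ICPs) — the per-cell time series of the
Fura-2 340/380 fluorescence ratio — recorded from mechanically injured
endothelium. Written for labs doing bulk tissue-level calcium imaging
(hundreds of ROIs, a few hundred frames at ~0.33 Hz) who need to separate
genuine Ca²⁺ activity from baseline noise and from coherent fluorescence
artifacts, and to sort cells by when they were active relative to the
injury.

## Method

For each profile, every interior local maximum `lmaxₖ` is paired with the
closest local minimum strictly to its left, `lminₖ`, and scored by its
**left prominence**

```
LPₖ = lmaxₖ − lminₖ
```

A candidate is a *true Ca²⁺ event* when `LPₖ ≥ lp_threshold` (inclusive;
default 0.024 a.u., working range 0.020–0.026). Because LP is defined on
extremum pairs, it needs no basal-noise segment — unlike the classical
`n·σ_bn` baseline-noise thresholds it is compared against.

Around the detector sit four supporting stages:

- **Preprocessing** — third-order Savitzky–Golay smoothing over an
  11-sample window; photobleaching compensation by subtracting the mean
  OLS slope of the 20 lowest-variability profiles.
- **Injury-time estimation** — the injury frame is
  `argmaxᵢ #{cells: ICP′(i) > th_diff} − k` with `th_diff = 0.040` and
  `k = 10` samples, computed on the unsmoothed traces.
- **Artifact rejection** — frames where the number of cells holding an
  above-threshold event reaches `th_art` (default 30 % of cells) are
  flagged (±1-frame dilation) and their events discarded; disabled for
  90 s after the injury, where genuine responses are equally coherent.
- **Classification** — basal region BR = frames before the injury,
  response region RR = injury onward. Each cell gets the binary code
  `2·RR_active + BR_active` (0 silent, 1 basal-only, 2 response-only,
  3 both). Events peaking within 90 s of the injury are anchored at the
  point where the trace has risen 20 % of their prominence, so an event
  whose onset precedes its peak is located by its onset.

Evaluation matches detections to expert marks within a symmetric ±ε
tolerance (ε = 10 s ≈ 3 samples) and reports sensitivity, specificity and
accuracy, plus `n·σ_bn` comparator detectors (per-profile or
lowest-noise-profile thresholds).

A seeded synthetic generator (`icptools.synth`) emulates the assay —
noise, bleach drift, basal transients/oscillations, a delayed biphasic
injury response in a fraction of cells, coherent artifacts — with exact
ground truth for every stage.

## Worked example

```
$ icptools simulate --seed 7 --out-dir demo
wrote 150x250 recording to demo

$ icptools detect --input demo/icp.csv --output demo/results.json
cells: 150  candidates: 6122  true events: 182  injury frame: 65  classes 0-3: [36, 21, 45, 48]
```

Of the 6,122 candidate (minimum, maximum) pairs found across 150 smoothed
profiles, 182 clear the 0.024 LP threshold and survive artifact checks.
The injury is placed at frame 65 (t = 195 s; this seed draws a 60 %
responder fraction with per-cell latencies, so the estimate sits a few
frames after the labelled contact frame 60). The 150 cells split into 36
silent, 21 basal-only, 45 response-only and 48 active-in-both.

```
$ icptools evaluate --input demo/icp.csv --gt demo/gt_marks.csv --output demo/metrics.csv
wrote 14 metric rows to demo/metrics.csv
```

`metrics.csv` holds one row per LP threshold (sweep 0.020–0.026) and per
σ_bn multiplier (1–13), each with max/min/mean sensitivity, specificity
and accuracy; on this dataset LP thresholding at 0.024 scores 1.0 on all
three.

The same operations are available as a library — sklearn-style:

```python
import icptools as it
truth = it.generate_recording(it.SynthConfig(seed=7))
est = it.IcpEventClassifier().fit(truth.recording)   # labels_, events_, injury_
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a default-regime synthetic recording (with a coherent
artifact), runs the full pipeline, scores detection against the
generator's ground truth under the ±10 s protocol, prints the run summary
and writes the results JSON.
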