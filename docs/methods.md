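# Methods notes

## Signal model and processing order

An ICP is modelled as baseline level + photobleaching drift + baseline
noise + event waveforms (+ artifact waveforms). The pipeline order is
read → smooth → bleach-compensate → detect → injury estimate → artifact
mask → rise-point shift → classify; smoothing and compensation can each
be switched off.

**Smoothing.** Savitzky–Golay, order 3, 11-sample window (33 s at
Ts = 3 s). Edges are evaluated from a full-width polynomial fitted at
each end of the trace rather than by signal extension, so no fabricated
pre/post-recording samples can create spurious boundary extrema. The
filter reproduces polynomials up to order 3 exactly; on the synthetic
templates it attenuates a 9 s-rise/30 s-decay transient's prominence by
~8 % and shifts its peak by ≤ 2 frames — both well inside the ±10 s
evaluation tolerance.

**Bleach compensation.** One global mean slope, not per-cell slopes: the
drift is a property of dye + illumination, and averaging the OLS slopes
of the 20 quietest profiles (smallest per-trace SD, which excludes
event-rich cells) is robust to events leaking into the fit. Compensation
subtracts `slope·(t − t₀)` anchored at the first frame, preserving
baseline levels; re-estimating on compensated traces returns ~0 (< 1e−9
a.u./s on pure common drift).

## Detection

Extrema use strict comparisons with plateaus collapsed to their leftmost
sample. This guarantees maxima and minima strictly alternate, so every
maximum (except possibly a leading one, which is dropped) has exactly one
closest left minimum and every minimum partners at most one maximum.
Tie/plateau handling is a package choice; real ratio data essentially
never ties, but the rule makes the detector deterministic and testable
against a brute-force scan.

The threshold is inclusive (`lp ≥ threshold`). Sub-threshold candidates
are retained with flags rather than deleted: they are the true negatives
of the evaluation accounting, and keeping them makes artifact filtering
auditable (filtering changes flags, never counts or scores).

Threshold selection from ground truth takes the lower edge of the modal
histogram bin (bin width 0.001 a.u.) of GT-matched candidate prominences.
Selection without ground truth is deliberately not automated — the
published criterion (candidate/GT histogram divergence below the mode) is
qualitative — so the CLI defaults to 0.024 and expects an explicit value
otherwise.

## Injury frame

`c(i) = #{cells j : ICPⱼ(i) − ICPⱼ(i−1) > th_diff}`; the injury frame is
the earliest argmax of `c` minus `k` samples (clamped at 0), with
`th_diff = 0.040` a.u. and `k = 10`. Two resolved ambiguities:

- The printed form subtracts `k·Ts` (seconds) from a frame index; the
  only dimensionally consistent reading — subtract `k` samples from the
  argmax frame — is used.
- The statistic lives in single-frame differences, which the 11-point
  smoother flattens about fivefold (a unit step's maximum smoothed
  difference is ~0.21). Injury estimation therefore runs on the
  *unsmoothed* traces; with smoothed input, `th_diff = 0.040` would
  require implausibly large steps.

The `k`-sample shift encodes the lag between pipette contact (the
operator's injury time) and the synchronized Ca²⁺ rise (descent, contact,
wave propagation). The synthetic generator states the same world: the
labelled injury frame is contact time and responders' rises begin
`k·Ts = 30 s` later plus a per-cell latency drawn uniformly from
[0, 15] s.

## Artifact rejection

Event frequency `f(i)` counts cells holding an above-threshold candidate
peaking at frame `i`. Frames with `f(i) ≥ th_art` are flagged and dilated
by ±1 frame (smoothing spreads a one-frame artifact across neighbours);
the dilated mask is then cleared inside the half-open disabled window
`[injury, injury + round(90 s / Ts))` — the exclusion is absolute because
right after the stimulus genuine responses are as coherent as artifacts.
`th_art` defaults to 0.30 × n_cells (configurable as a fraction or an
absolute count); no published value exists, and 30 % sits well above the
synchrony that biology produces outside the injury window in this assay
while well below the 50–80 % of cells a focus or perfusion artifact hits.

## Classification

BR is `[0, injury)` half-open; RR is `[injury, end)` with no 90-s cap
(the cap governs only rise-shifting and artifact-disable). An early
post-injury event whose 20 %-rise point falls before the injury frame
counts in BR: the shift exists precisely so that an event's onset, not
its peak, fixes its location. Class code = `2·RR + BR`.

## Evaluation

Greedy nearest-first one-to-one matching within ±ε (ε = 10 s, converted
to a frame count by rounding) prevents double-counting when detections
cluster. Accounting: matched marks are TP; unmatched marks are FN, and
each absorbs the nearest unused sub-threshold/discarded candidate within
ε (the missed event itself) so that candidate is not also credited as a
TN; remaining above-threshold events are FP; remaining candidates are TN.
This is the only accounting under which `tp+fn = |marks|`,
`tp+fp = |detections|` and `tp+tn+fp+fn = |candidates|` all hold whenever
every mark coincides with some candidate — which the generator
guarantees. Undefined ratios (empty denominators) are reported as NaN
with a warning, never as 0 or 1.

The σ_bn comparators threshold the *same* left-prominence scores at
`n·σ`, where σ is the SD of (raw − smoothed) residuals over pre-injury
frames, per profile or the dataset minimum. Thresholding lp rather than
raw amplitude isolates the one difference under study — how the threshold
is constructed. Residual-from-smoothed keeps slow drift out of σ; whole
pre-injury baselines are used.

## Synthetic generator

What it states: 150 cells × 250 frames at Ts = 3 s; baseline 1.0 a.u.;
Gaussian noise σ = 0.004 (optionally log-uniform per cell for
heterogeneous-noise studies); bleach slope −0.0002 a.u./s; injury at
frame 60; 60 % responders with a biphasic response (abrupt 2-frame rise,
60 % sustained plateau ~90 s, slow return; amplitude U[0.12, 0.35]);
basal events at 0.7 per cell, 80 % fast transients (9 s rise, 30 s decay
constant) and 20 % raised-cosine oscillations (36 s period, 2 cycles),
amplitudes log-uniform over [0.03, 0.3] so near-threshold events exist;
optional coherent artifacts as 9 s-rise bumps hitting a stated fraction
of cells. Unpublished constants (template time constants, basal rate,
responder amplitudes) were fixed once at physiologically plausible values
for endothelial Ca²⁺ signalling at 0.33 Hz sampling.

Placement rules that keep the ground truth exact rather than nominal:
event onsets start at frame ≥ 15 (the smoother reaches ~5 frames left; an
event starting at the boundary loses its left minimum and is legitimately
undetectable); basal waveform footprints are disjoint (an event riding
another's decaying tail has its measured prominence eroded below its
nominal value); basal peaks stay ≥ 10 frames clear of the injury.
Artifact bumps rise over 3 frames so their per-frame differences stay
below `th_diff` — an artifact mimicking the injury step itself is a
different failure mode than the one under test. Ground-truth marks sit at
event peaks, except events starting within 90 s of the injury, marked at
their 20 %-rise point as the experts did.

What it does *not* emulate: slow baseline wander beyond linear bleach,
photon shot noise scaling with intensity, cell-tracking dropouts, wave
propagation between neighbouring cells, and overlapping same-cell events.
A green test therefore establishes correctness of the algorithmic
contracts and recovery in a well-posed regime, not performance on real
rat-aorta recordings; the published headline numbers are not reproducible
without the original (undeposited) data, and the package does not attempt
them.

## Numerical choices

- Frame `i` ↔ time `i·Ts`, 0-based everywhere; expert mark times snap to
  the nearest frame on binding.
- Earliest-index tie-breaks: argmax of `c(i)`, plateau collapse, modal
  histogram bin.
- Traces shorter than 3 samples have no extrema; recordings need ≥ 2
  frames; σ_bn needs ≥ 3 pre-injury frames.
- All randomness flows from one `numpy` `default_rng(seed)` per
  generated dataset; identical seeds give bit-identical recordings.
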