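# Methods

## Problem and pipeline

`nyhagrade` grades heart-failure severity on the four-level NYHA scale
from single-lead (lead II) ECG recordings sampled at 125 Hz.  The
workflow is:

1. **Duration sweep.** A record of `T` seconds is segmented into
   non-overlapping windows of `d` seconds only when `d` divides `T`
   evenly; for 30-minute records and the 2–20 s sweep this admits twelve
   durations (7, 11, 13, 14, 16, 17 and 19 s are excluded).  The default
   working duration is 12 s.
2. **R-peak cleaning.** Each segment passes a QRS detector (below);
   segments with fewer than two validated QRS complexes are discarded so
   every training segment contains at least two complete beats.
3. **Per-segment z-scoring.** `x' = (x − μ)/σ` with the segment's own
   mean and population standard deviation (ddof 0).  A constant segment
   raises an error rather than silently becoming zeros: a flat segment
   has no QRS and should already have been filtered.
4. **Classification.** A 1-D CNN-LSTM with squeeze-and-excitation (SE)
   channel attention, trained with Adam (lr 0.001, batch 32) on
   class-weighted softmax cross-entropy under stratified 5-fold
   cross-validation, reporting per-class one-vs-rest Acc/PPV/Sen/Spe in
   percent plus macro averages and overall accuracy.
5. **Interpretation.** 1-D grad-CAM against the last conv stage.

## R-peak detector

The detector is a Pan-Tompkins-family heuristic operating on the raw
(unnormalized) segment:

* dynamic threshold: consecutive 1.5 s windows contribute
  `μ_w + k·σ_w` (default `k = 1`); candidates are local maxima above the
  threshold of their window;
* refractory merge: candidates closer than 200 ms are merged keeping the
  larger;
* QRS validation: a surviving peak must have prominence at least
  `0.5 × (window max − window median)` and half-prominence width at most
  160 ms;
* T-wave discrimination: a peak within 360 ms after an accepted QRS
  whose height above the window median is less than half the previous
  QRS's height is rejected as a T wave.

All six constants are exposed in `RPeakParams`.  On noiseless synthetic
records the detector recovers every ground-truth R-peak within ±40 ms
with sensitivity and positive predictivity ≥ 0.99; the same holds at the
generator's default noise (σ = 0.02 signal units).  Above roughly
σ = 0.05 the positive predictivity degrades — the pipeline deliberately
performs no band-pass filtering, so heavy noise is out of scope.

## Architectures

Three variants share one configuration object:

* `cnn` — nine counted layers: three conv(+ReLU)/max-pool stages and
  three dense layers.  Conv defaults are a 32/64/128 filter pyramid with
  kernels 7/5/3 (the counted-layer structure is fixed; widths are free
  hyperparameters).
* `cnn_lstm` — the three conv stages feed a stacked LSTM reading the
  last stage as a time series.
* `cnn_lstm_se` — additionally, SE blocks after the second and third
  conv layers.  With the default 10-layer LSTM stack the counted
  components are 3 conv + 2 SE + 10 LSTM + 3 global-average-pool +
  2 dense = 20.

The exact wiring among conv stages, the pooling skips and the recurrent
stack is not uniquely determined by the layer census; this implementation
pools each conv stage globally (the three GAP components) and
concatenates those skips with the LSTM's final hidden state into the
dense head.  The census and the tensor contracts (4-way softmax output,
SE placement) are the tested surface.

The LSTM cell follows the standard gate equations with the recurrent
state concatenated before the input, `σ(K·[h_{t−1}, x_t] + Z)` per gate;
`lstm_step_reference` and `se_block_reference` are deliberately literal
transcriptions used as oracles against the vectorized training layers
(agreement ≤ 1e-5 in float32).

Training schemes: **A** uses no dropout; **B** drops 20% of LSTM input
and recurrent connections (one mask per sequence, inverted dropout,
inference-time passes are deterministic).

The whole training core (convolution, pooling, SE, LSTM with BPTT, Adam,
weighted cross-entropy) is implemented in numpy with explicit
forward/backward passes; gradient correctness is checked by directional
finite differences in the development history and by the
reference-equation oracles in the test suite.

SE reduction ratio defaults to r = 8 (standard SE-Net practice);
"10 LSTM layers" is read as ten stacked recurrent layers with default
hidden size 32 — small enough to train at desk scale, configurable.

## Evaluation

Metrics reduce the 4×4 confusion matrix one-vs-rest per class.  Macro
values are unweighted means over classes (weighted means are also
computed); a class with an empty PPV denominator is reported as missing
and excluded from the macro with a warning rather than zero-filled,
avoiding silent bias on degenerate folds.  `overall_accuracy`
(trace/total) is what a single headline accuracy number refers to.
Class weights are inverse-frequency, `w_c = N/(K·n_c)` (balanced labels
give 1 for every class).

Folds are stratified; splitting is **segment-level by default** (the
conventional protocol for fixed-duration ECG segments) with
**patient-level** group-aware splitting available.  The two differ
materially: see "Leakage" below.

## Synthetic data generator

Each cardiac cycle is a sum of five Gaussian deflections (P, Q, R, S, T)
on a baseline plus a smooth ST-segment shelf 50–160 ms after the R-peak.
Records are built by overlap-adding beats at RR intervals drawn
`Normal(60/hr, 0.04 s)` (per-record heart rate `Normal(75, 5)` bpm),
adding white Gaussian noise (σ = 0.02), and clipping to the class
amplitude envelope.  Severity is encoded as:

| class | envelope | ST offset | beat dispersion |
|-------|----------|-----------|-----------------|
| I | [0, 1] | 0.00 | 4% |
| II | [−2, 2] | −0.18 | 12% |
| III | [−2, 2.8] | −0.35 | 15% |
| IV | [−2.8, 2.2] | −0.55, inverted T | 15% |

ST-offset magnitude is monotone non-decreasing in grade (enforced at
config time), matching the clinical observation that ST-T deviation
grows with severity; the per-class envelopes match the amplitude ranges
reported for the four grades.  No quantitative per-class ST statistics
exist to calibrate against, so the effect sizes are synthetic
conventions, chosen once to be clearly separable at default spacing and
exactly zero under `SynthConfig.null_effect()` (all classes share one
morphology).  Ground-truth R-peak positions are exact by construction.

What the generator does **not** emulate: arrhythmias, baseline wander,
electrode artifacts, inter-patient morphology variability beyond the
amplitude-dispersion knob, or real MIMIC-style waveform statistics.
Passing recovery tests therefore demonstrates that the pipeline and
model behave correctly on data satisfying their assumptions — not
clinical performance.

## Desk-scale study conditions

The recovery/ablation studies run on a balanced cohort of 10 records per
class, 240 s each, cut into 12-s segments: exactly 200 segments per
class (800 total).  The null-effect study uses 40 records per class of
60 s (the same 200 segments per class): because accuracy clusters at
record level under patient-level folds, the chance-level estimate's
standard error is governed by the number of records, and 10 records per
class would leave it too coarse (~7 percentage points) to read against
the 25% chance line.  The reduced classifier uses conv filters 8/16/32,
kernels 7/5/3, max-pool 5, a 2-layer LSTM of width 24, scheme B,
10 epochs.  Pool size 5 matters: with pool 3 the 55-step recurrent stack
does not converge within the fixed 10-epoch budget, while 12 recurrent
steps do.  One 5-fold CV run takes well under a minute on one CPU.

## Leakage, and why the studies use patient-level folds

Each synthetic record carries a distinctive resting heart rate.  Under
segment-level splitting, segments of the same record appear on both
sides of the divide, and the model can identify the record (hence its
label) from rate alone: with **zero** class effect, segment-level CV
still measures ≈31% accuracy — above the 25% chance level.  This is the
classic subject-leakage failure mode of physiological-signal evaluation,
reproduced in miniature.  The recovery, null-effect and ablation studies
therefore use patient-level folds, under which the null study scores
chance (≈24%) and the default-effect study still recovers the grades at
≈100%.  Segment-level remains the pipeline default for workflow parity,
with patient-level recommended for any claim about generalization.

## Numerical choices and degenerate inputs

* All network arithmetic is float32; losses accumulate in float64.
* Weight init is Glorot uniform; LSTM forget-gate bias starts at 1.
* Adam: β₁ = 0.9, β₂ = 0.999, ε = 1e-7.
* WFDB output quantizes at gain 1000 (0.001 signal units/LSB, 16-bit);
  reading back yields the quantized amplitudes exactly.
* Grad-CAM differentiates the pre-softmax class score; maps are
  rectified, linearly upsampled, max-normalized; an input that excites
  nothing positively yields an all-zero map.  The default attended
  tensor is the SE-rescaled output of the last conv stage (what the
  downstream network consumes); a flag switches to the raw conv output.
* Ties in max-pooling resolve to the first maximum (numpy argmax).
* Empty segment sets round-trip through the bundle format; a corrupted
  manifest or a manifest/sample count mismatch fails loudly.

## Known limitations

* Headline accuracies from credential-gated clinical cohorts cannot be
  reproduced here; the synthetic studies validate machinery, not
  clinical claims.
* The stored-waveform amplitude unit (mV vs ADC counts) is preserved
  as-is by the readers; no unit conversion is attempted.
* The numpy training core is single-threaded apart from BLAS matmuls;
  it is sized for desk-scale experiments, not full-cohort training.
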