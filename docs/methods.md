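# Methods

## Signal model and pipeline

The bolus reports 3-axis acceleration at a nominal f_s = 12.5 Hz in
arbitrary sensor units; the pipeline never interprets the units because
every stage up to the learned decision boundary is scale-covariant
(scaling the trace by c scales the jerk magnitude by |c| and every
variance-derived series by c²).

Stages, with window lengths converted to samples once at ingestion as
`round(window_s * fs)`:

1. **Jerk** — per-axis first difference of consecutive samples, *not*
   divided by the sample period. Output length n−1, start advanced by one
   sample period. Constant per-axis offsets (gravity, static orientation)
   cancel exactly; the slow orientation drift of a real bolus survives
   only as a negligible low-frequency residue.
2. **Jerk magnitude** — Euclidean norm across the three axis jerks.
3. **Rolling variance**, 1.5 s (19 samples), trailing window, population
   denominator (divide by w). Short enough to resolve the
   high-variability contraction bursts against the quiescent chewing
   pauses between them.
4. **Rolling mean**, 8 s (100 samples) — approximately one
   reticuloruminal contraction, smoothing the variance envelope so each
   contraction appears as a single bump.
5. **Peak detection** — all strict local maxima (a flat-topped plateau is
   reported once, at its midpoint, left-biased on even widths: one event
   per contraction), each with standard topographic prominence, the
   series ends acting as infinitely low terrain.
6. **Prominence threshold** — the sensitivity curve (surviving peak count
   vs threshold) is evaluated exactly on the sorted distinct prominence
   values; the threshold is taken at the knee: normalise both axes to
   [0, 1], subtract the curve from the chord joining its endpoints, and
   take the first threshold maximising the difference (ties resolve to
   the smallest threshold, retaining more peaks). A fixed threshold can
   be supplied instead (`prominence_mode: fixed`). Because the counts
   curve is already monotone no smoothing is applied, and the knee
   criterion reduces to the deterministic core of the Kneedle method
   with sensitivity 1.
7. **ICI** — successive differences of retained peak times, stamped at
   the later peak.
8. **JVB** — 40 s (500-sample) trailing rolling median of the smoothed
   variance; one inter-contraction period, so a single burst (≈ 9 s)
   cannot lift the median off the quiescent floor.
9. **Blocks** — contiguous 270 s blocks anchored at the first collar
   interval. `mean_ici` averages the intervals whose later peak falls in
   the block (missing if fewer than 2 contribute); `mean_jvb` averages
   the JVB samples in the block; `log_jvb = ln(mean_jvb)` (base
   configurable). Label = majority of the three covering 90 s collar
   intervals (configurable to `all`/`any`), missing on incomplete
   coverage; rows with any missing field are dropped before training and
   the exclusion count is logged.
10. **Classifier** — the majority class is subsampled to the minority
    size (seeded), each class is split 80/20 independently, features are
    standardised with training-set statistics, and a linear SVM is fit.
    Rumination is the positive class; a decision value of exactly zero
    predicts rumination. Ten stratified folds (seeded shuffle, contiguous
    partition) quantify sensitivity to sample selection.

All rolling windows are trailing and stamped at the right edge; outputs
are shorter than inputs and carry their own start time. No edge padding
is used, because padded edges would fabricate variance spikes for the
peak detector. A consequence worth knowing: every detected peak lags its
contraction by the same deterministic filter delay (about half the
smoothing window plus half the burst duration). Intervals, and therefore
all downstream features, are unaffected.

## Metrics

precision = TP/(TP+FP), recall = TP/(TP+FN), specificity = TN/(TN+FP),
NPV = TN/(FN+TN), F1 = 2·precision·recall/(precision+recall). A metric
whose denominator is zero is reported as missing, never as 0. Per-fold
F1 inside cross-validation uses the algebraically identical form
2TP/(2TP+FP+FN), which remains defined (0) for a fold in which no
positives were predicted; stratification guarantees its denominator is
positive. Fold variance is the population variance over the k fold
scores.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `fs` | 12.5 Hz | nominal bolus sampling frequency |
| `variance_window_s` | 1.5 s | jerk-magnitude rolling variance |
| `smoothing_window_s` | 8 s | rolling mean; ≈ one contraction |
| `jvb_window_s` | 40 s | rolling median; ≈ one inter-contraction period |
| `block_s` | 270 s | feature block; three collar intervals |
| `label_rule` | majority | collar fusion: majority / all / any |
| `train_fraction` | 0.8 | balanced train share |
| `k_folds` | 10 | cross-validation folds |
| `C` | 10 | SVM regularisation strength |
| `prominence_mode` | auto | knee-selected or fixed threshold |

`C = 10` (rather than the textbook 1.0) reflects the problem geometry:
blocks that straddle a behaviour change are rare — a handful per day of
data — and sit close to the midline between the two clusters. A soft
margin at C = 1 finds it cheaper to sacrifice them wholesale, which makes
cross-validation folds that hold such blocks out unstable; a stiffer
margin respects them while remaining finite against genuine label noise.
The boundary, mapped back to the original feature axes, is a straight
line whose slope varies little across folds on separable data.

## The synthetic generator

`rumibolus.synthetic` emulates the *signal structure* the pipeline
exploits, not rumen biomechanics. Acceleration is gravity times a slowly
drifting unit orientation vector (a projected Gaussian random walk on the
sphere, step 0.002 per sample) plus per-axis white noise whose standard
deviation encodes behaviour:

* rumination: quiescent floor 0.0072 units with contraction bursts every
  50 ± 5 s (truncated at 20 s; the 4 h demonstration scenario uses
  45 ± 4 s), lasting 9 s, amplitude 0.1 under a raised-cosine envelope —
  contractions wax and wane, which keeps each burst a single peak after
  smoothing;
* feeding/other: elevated floor 0.0198 units with aperiodic spikes
  (24 s refractory gap plus exponential tail, mean spacing 30 s, 3 s
  duration, amplitude 0.05 ± 40 %).

The floor levels were calibrated so the two block-feature clusters land
near (45 s, ln JVB ≈ −9.9) for rumination and (≈ 27 s, ≈ −7.9) for
feeding, the geometry the classifier is designed around. Labels are
emitted as 90 s majority-state intervals, mirroring a collar.

What the generator does **not** model: real contraction waveforms (bursts
are amplitude-modulated noise — sufficient because the pipeline responds
to jerk variance, not shape), drinking and temperature artefacts,
collar classification errors (labels are exact by construction),
clock drift between bolus and collar, biological variability between
animals, and gradual behaviour transitions (state changes are
instantaneous). Consequently, passing tests demonstrate that the
implementation recovers the structure it is specified to recover; they do
not certify field performance on animal data, where the published
classification quality is noticeably lower than on these clean
simulations.

## Problem sizes and numerical choices

* The end-to-end checks run the full pipeline on ten 4 h scenarios
  (180,000 samples each, 53 blocks); parameter-recovery checks use ten
  2 h single-behaviour traces, a size at which the sample mean of the
  generated spacing is stable to a fraction of a second.
* The knee threshold always lies on a detected prominence value and
  retention is inclusive (≥), so the peak defining the knee survives —
  one borderline peak per dataset, immaterial at these problem sizes.
* Rolling variance can produce tiny negative values on near-constant
  windows through cancellation; outputs are clipped at zero.
* Trace CSVs are written with `%.17g` and parsed with round-trip float
  precision, making write→read the identity on IEEE doubles.
* Timestamps may be ISO-8601 or plain seconds; internally everything is
  float seconds. Gaps (spacing > 120 % of nominal) abort ingestion by
  default or split the trace into independently processed uniform
  segments in permissive mode; sub-nominal spacing (< 80 %) is always an
  error. The median spacing must be within 5 % of nominal.
* Degenerate inputs raise typed errors (`InsufficientDataError`,
  `NoElbowError`, `InsufficientClassError`, ...) rather than returning
  silent defaults; a constant or perfectly linear sensitivity curve has
  no knee by definition.

## Known limitations

* One prominence threshold is selected per dataset (per trace). Per-animal
  thresholds are possible by running traces separately.
* Blocks straddling a behaviour change carry a majority label but mixture
  features; they are the dominant error source and an irreducible ~2 % of
  blocks under the alternating demonstration schedule.
* The 270 s block and 90 s collar period are assumed aligned; collar
  tracks that do not align leave blocks unlabelled rather than
  approximated.
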