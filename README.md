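# rumibolus

Rumination detection in cattle from a motion-sensitive reticuloruminal
bolus — an accelerometer-bearing capsule that rests in the reticulum and
logs 3-axis acceleration at 12.5 Hz from inside the animal.

Time spent ruminating ("chewing the cud") is a key welfare and health
indicator in dairy cattle, conventionally estimated with neck collars that
sense jaw motion. A bolus cannot see the jaw, but the reticulorumen
contracts rhythmically (roughly every 40–60 s) to regurgitate feed during
rumination, and those contractions shake the bolus. This package turns
raw bolus acceleration into two behavioural features and classifies
270-second blocks as rumination or non-rumination with a linear SVM,
supervised by collar labels.

## Method

For each axis, acceleration is differenced sample-to-sample into a jerk,
which cancels gravity and any static orientation offset:

    j_x(t) = x(t) − x(t − 1/f_s)

The resultant jerk magnitude ‖j(t)‖ = √(j_x² + j_y² + j_z²) is reduced to
a motion-energy envelope by a 1.5 s trailing rolling variance σ²(t)
(population denominator) followed by an 8 s rolling mean — about the
duration of one contraction. Contraction peaks are all local maxima of
the smoothed signal, filtered by topographic prominence; the prominence
cut is placed at the knee of the peak-count-versus-threshold curve
(Kneedle-style maximum distance to the chord after axis normalisation),
so it adapts to whatever units the sensor reports. Two features follow:

* **ICI** — the inter-contraction interval, the time between successive
  retained peaks (≈ 40–60 s during rumination, shorter and irregular
  otherwise);
* **JVB** — the jerk variance baseline, a 40 s rolling median of the
  smoothed variance (≈ one inter-contraction period), which sits on the
  quiescent floor between contractions: low while the animal chews,
  high while it feeds or moves.

Both are averaged over contiguous 270 s blocks (three 90 s collar
intervals; block label = majority of the three, feeding and other both
counting as non-rumination). A linear SVM on (mean ICI, ln mean JVB)
separates the two behavioural clusters; performance is reported as a
confusion matrix with precision, recall, specificity, negative predictive
value and F1, plus 10-fold cross-validation of the training split.

## Worked example

No animal data ships with the package; the `synthetic` module generates
traces with the same signal structure (quasi-periodic contraction bursts
over a quiet floor during rumination; a higher floor with aperiodic
spikes during feeding; drifting gravity vector on all axes):

```sh
rumibolus simulate demo --seed 3            # 4 h labelled trace at 12.5 Hz
rumibolus pipeline demo/trace.csv demo/labels.csv demo/run --seed 3
```

prints

```
wrote 180000 samples and 160 label intervals to demo
                     true rum    true non-rum
  pred rum          TP=5         FP=0         precision=1.000
  pred non-rum      FN=0         TN=5         npv=1.000
                    recall=1.000 specificity=1.000 F1=1.000
k-fold F1 mean 1.000, variance 0.000000
```

i.e. of the ten held-out blocks (five per class after balancing), all ten
are classified correctly, and the ten cross-validation folds agree. The
run directory contains the block feature table (`features.csv` — e.g. the
first rumination block has mean ICI 41.0 s and ln JVB −9.70), the
sensitivity curve behind the automatic prominence threshold, the
human-readable linear model (`model.txt`), per-fold scores and the
effective configuration.

The same steps are available as a library:

```python
import rumibolus as rb

trace, labels = rb.default_scenario(seed=3)
result = rb.run_end_to_end(trace, labels, rb.PipelineConfig(seed=3))
print(result.metrics.pretty())
```

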