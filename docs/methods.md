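# Methods

## Signal representations

All classifiers consume the magnitude series of a tri-axial channel group:
the per-sample Euclidean norm of (x, y, z), in raw sensor units with
gravity included. No gravity subtraction, filtering or calibration is
applied — working on raw acceleration keeps every assumption about the
physiological appearance of dyskinesia out of the preprocessing.
Recordings at rates other than 100 Hz are rejected rather than resampled.

Three input representations feed the 32 expression terminals:

* **time** — overlapping 32-sample windows (0.32 s), stride 1; a series of
  length L yields L − 31 windows. The stride of one sample is forced by
  that window count.
* **spectral_long** — one 32-vector per movement sample: Welch's averaged
  periodogram (Hann taper, 256-sample segments, 50% overlap, mean
  detrend) reduced to the mean density over each of 32 equal intervals
  tiling (0, 50] Hz, DC excluded. Welch parameters are this package's
  choice; nothing in the deployed design pins the estimator, and any
  density estimate with this binning would serve.
* **spectral_short** — a per-window 32-vector: the 32-sample window is
  zero-padded to 64 samples, a single boxcar periodogram is taken and
  one-sided bins 1..32 (DC dropped) are kept. The padding is needed
  because a 32-sample window natively has only 17 one-sided bins; the
  alternative reading (short-term spectra of a longer window) was
  rejected to keep the three models dimensionally identical per window.

## The classifier and its training

A genome is a 6 × 6 feed-forward grid of (function, input, input) triples
over the set {add, sub, mul, div, mean, min, max, abs}, plus one output
gene; connection genes may address any terminal or any node in a strictly
earlier column (unlimited levels-back), so validity is positional and
every crossover of valid parents is valid. Nodes not reachable from the
output are inactive and provide neutral variation. Design choices:

* all functions are encoded with two connection genes; `abs` reads only
  the first (uniform genome layout);
* `mean` is the binary mean (a + b)/2, consistent with its place among
  the binary operators;
* division is protected: when |denominator| < 1e-6 the numerator is
  returned — total, deterministic and scale-preserving;
* node outputs are clamped to ±1e150 so no finite input can produce a
  non-finite value through chained multiplications;
* positional uniform node-wise crossover replaces the implicit-context
  representation of the original training system; it searches a space of
  identical size and dimensionality, and its mechanics are documented
  here rather than inherited from an external implementation;
* per-gene mutation rate 0.02 and crossover probability 0.9 are the
  package defaults (config-overridable); the deployed system's exact
  values are not published;
* selection is tournament of size 4 with generational replacement and
  elitism 1 — chosen over fitness-proportionate selection because AUC
  fitness spans a compressed range.

A movement sample's score is the mean expression output over its windows
(or the single output on the long-term spectrum). Fitness is the
Mann–Whitney AUC of those scores, grade-0 items versus grade ≥ 3 items;
items with 0 < grade < 3 — including rater-averaged fractional grades
such as 2.5 — are excluded from training, a restriction that empirically
yields more robust classifiers than training across the clinically
ambiguous middle grades (3.5 is included, 2.5 is not). Training is
repeated over independent seeds; each run's best genome is scored on the
test split and the highest-test-AUC instance is selected. Reference
protocol scale is population 200 for 100 generations over 50 runs; the
desk-scale protocol used throughout the tests and the acceptance script
is population 50, 40 generations, 10 runs (seeds 1–10), which trains in
about a minute on one CPU and already reaches holdout AUC ≥ 0.9 on the
default synthetic study.

## Evaluation machinery

AUC uses the Mann–Whitney pair-counting convention with ties counting
one half (computed via midranks); the swept ROC curve's trapezoidal area
equals it to numerical precision, and both formulations are cross-checked
in the tests. Bootstrap ROC bands resample within class (so neither class
can empty), interpolate TPR on a fixed 101-point FPR grid and report the
2.5/97.5 percentiles. Per-grade thresholds maximise Youden's J
(sensitivity + specificity − 1) over all candidate cut-points at each
adjacent grade boundary, with ties resolved toward the lowest threshold
and the four thresholds coerced non-decreasing; J was chosen because the
reported operating points are sensitivity/specificity pairs and no other
optimality criterion is published. Activity-stratified AUC flags (rather
than computes) strata missing a class.

The daily summary cuts a recording into consecutive epochs (default 60 s;
the reporting resolution is a free choice), scores each epoch, maps the
score through the fitted thresholds, and merges adjacent same-band epochs
at grade ≥ 3 into episodes with no gap-bridging — one lower epoch splits
an episode. Sleep intervals are a user-supplied annotation, not inferred;
sleep epochs are excluded from banding. Windows are assigned to labelled
segments only when fully contained in them; intervals are half-open
[start, end) in seconds from recording start; each sensor site is
classified independently (no channel fusion).

## The synthetic study

Clinical recordings are not available, so the generator emulates their
structure well enough to exercise every pipeline stage against ground
truth. Segments are 10 s at 100 Hz, one per recording, partitioned into
train/test/holdout with grade-0 classes most frequent (mirroring the
clinical grade distribution's shape). Defaults per split: train
12 rest / 14 walking / 8 voluntary / 4+4+9+9 dyskinesia grades 1–4;
test and holdout 8/10/5/3+3+7+7.

* **Gravity** is a 1 g vector with slow sinusoidal orientation drift;
  magnitude is rotation-invariant, so at rest the series sits at
  1 g + noise. Accelerometer noise is 0.08 g (train/test) and 0.12 g
  (holdout) — the holdout split emulates a different set of sensor
  modules, which also makes it the harder split on average.
* **Dyskinetic bursts** are caldera-shaped transients: a raised-cosine
  first lobe with a narrow subtractive dip at its crest (depth 0.4,
  sigma 1.5 samples), then a shorter, lower second lobe; unit peak before
  scaling. Each occurrence is time-warped ±10%, placed without overlap,
  and planted along the instantaneous gravity axis as a zero-mean
  transient (core plus a wide shallow rebound). Zero net area models a
  jerk with no lasting velocity change and concentrates burst energy in
  the 1.5–5 Hz band; planting along gravity keeps the magnitude response
  linear, so the shape survives the magnitude transform. Grades map to
  (occurrences/min, amplitude in g): 1 → (4, 0.3), 2 → (8, 0.6),
  3 → (14, 1.0), 4 → (22, 1.5) — invented, config-overridable values on
  a declared scale; tests rely only on their monotonicity. Each labelled
  dyskinesia segment contains at least one occurrence (a rater graded it
  because something was visible). A quarter of dyskinesia segments get a
  ±0.5 rater-averaged fractional grade to exercise the training filter.
* **Walking** combines a cadence-locked harmonic series (cadence
  1.5–2.1 Hz with 5% sinusoidal drift; weights 1, 0.5, 0.25; peak
  amplitude 0.4–0.9 g, varying per segment so power alone does not
  identify the class) with a symmetric damped 7–12 Hz ring transient at
  each step (0.6–1.2 g). The rings share the band and per-window power of
  dyskinetic bursts but carry no positive–negative asymmetry — phase
  structure is the one cue spectral representations discard, and it is
  what makes the time-versus-spectral comparison meaningful rather than
  decided by signal power. Half of all dyskinesia segments ride on a
  walking carrier.
* **Voluntary movement** is smooth bell-enveloped 1–2 Hz oscillation
  (0.5–1.0 g) — the classic hard-to-discriminate confounder.
* **Gyroscope** channels carry the same planted waveform at half
  amplitude with equal noise (half SNR), and with no gravity bias their
  magnitude rectifies the signed transient; rotational data is therefore
  the weaker source by construction, which is the property the
  accelerometer-versus-gyroscope comparison tests.

The generator is validated by construction-independent oracles: planted
occurrence times are recovered by normalised cross-correlation against a
±10% warp bank of the known template (≥ 90% detection at grade 3), and
the pooled study separates grade 0 from grades 3–4 at matched-filter
AUC 0.97 — the sanity ceiling that justifies asking an evolved classifier
for holdout AUC ≥ 0.9.

What passing these tests does **not** show: the generator is not a
biomechanical simulation. Real dyskinesia varies in waveform between
occurrences and patients, real gait is far richer than a harmonic comb
with ring transients, label boundaries in real data are imprecise, and
real segments are heterogeneous within themselves. Results on this
surrogate demonstrate that the pipeline works end-to-end and that the
time-domain representation can exploit shape where spectral ones cannot —
they do not certify clinical performance.

## Numerical and degenerate-input conventions

Equality of the grid evaluator with its recursive-interpreter oracle is
exact (same operation order, no tolerance). AUC degenerate cases (an
empty class) raise rather than return a default. Epochs shorter than one
window are dropped at the end of a recording. Threshold fitting with a
boundary whose one side is empty skips that boundary; if none is
computable it raises. Recording CSVs store time with fixed 1e-7 s
precision so the reader's 1e-6 s rate-consistency tolerance holds at any
recording length; sample values round-trip to ~1e-7 relative precision.

## Known limitations

Best-of-N selection on a 32-item test split has realisation variance
(run-seed decades other than the documented 1–10 have produced holdout
AUCs from 0.80 to 0.97); the documented protocol pins the seeds rather
than averaging it away. The spectral baselines use this package's
estimator choices, so their absolute AUCs are not comparable to other
implementations — only the qualitative ordering is claimed. Sleep
annotation, medication times and per-site fusion are deliberately out of
scope.
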