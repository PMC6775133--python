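# Methods

`artidec` implements a complete decoding pipeline for cued-movement
experiments recorded with high-density electrocorticography (ECoG) grids
over sensorimotor cortex: preprocessing, high-frequency-band (HFB, 60–130
Hz) power estimation, responsive-electrode selection, template-matching
classification with cross-validation, electrode-importance and minimal-grid
localization, and topographic mapping.  Because clinical ECoG is not freely
shareable, the package ships a synthetic-run generator with the same trial
design, so every stage is testable end to end.

## Study design emulated by the simulator

A run consists of 4 movement classes × 20 trials plus 20 rest trials in a
single pseudorandom order.  Each trial shows a 1500 ms cue followed by a
1500 ms (configurable 2000 ms) inter-trial interval.  Electrodes sit on a
rectangular grid (default 8×8 at 4 mm pitch; 8×16 and 3 mm variants are
configurable) sampled at 512 Hz by default (2000 Hz supported).

The signal model is, per channel:

* **Background** — unit-variance Gaussian noise with power spectral density
  ∝ 1/f^α (default α = 1), independent across channels.
* **Mains interference** — a shared 50 Hz sinusoid with harmonics
  (amplitude 1/h for harmonic h, default 3 harmonics) and a mild ±5 %
  per-channel gain spread.  50 Hz is the default mains frequency;
  configurable.
* **Class effect** — during each active trial, band-limited (60–130 Hz)
  noise is added from movement onset (cue onset plus a uniform 0–200 ms
  jitter) for the cue duration.  Its per-channel amplitude follows a
  spatial Gaussian (default σ = 6 mm) around a class-specific grid
  location.  The injected noise has the same 1/f spectral shape as the
  background restricted to the band, so the per-frequency-bin power ratio
  between active and rest is flat and the realized mean-of-dB HFB rise at
  the center channel equals `effect_db` by construction (the calibration
  test checks ±0.5 dB).  `effect_db` (default 6 dB) is a free parameter
  spanning chance (0 dB) to ceiling (≥ 6 dB on a 16-channel grid); real
  effect sizes in dB are not published for this paradigm.

What the simulator does *not* model: cortical geometry and volume
conduction, non-stationary artifacts, behavioural variability beyond onset
jitter, and cross-channel correlated noise.  Passing tests therefore show
the *analysis* is correct and calibrated, not that real cortex behaves like
the generator.

## Preprocessing

Bad channels are *flat* (variance < 1e-10) or *noisy* (variance, or mains-
band power, above 10× the across-channel median).  The criteria in the
source literature are not published; these thresholds are this package's
definition and are configurable.  The notch filter is a zero-phase 2nd-
order butterworth band-stop (1 Hz wide) at the mains frequency and each
harmonic below Nyquist, applied forward-backward.  Common-average
re-referencing subtracts the mean of *included* channels at every sample;
excluded channels are left untouched (whether the original analyses
included bad channels in the average is unstated; excluding them is the
safer choice).  Order: detection → notch → re-reference.  Notch and
re-reference are both linear, so they commute exactly; the order is fixed
only for reproducibility.

## HFB envelope

Each channel is convolved with complex Gabor atoms at 1 Hz spacing over
60–130 Hz.  "FWHM of 4 wavelets per frequency" is read as: the Gaussian
envelope's full width at half maximum equals 4 cycles of the bin's center
frequency (FWHM = 4/f s) — the standard Morlet-family parameterization; a
frequency-independent 4 s FWHM would be physically implausible at these
frequencies.  Atoms are L2-normalized and truncated at ±5 σ; convolution is
zero-padded with a centered crop.  Per-bin power is floored at 1e-12 of its
mean (so silent channels stay finite), converted to dB (10·log₁₀), and the
envelope is the **mean of the per-bin dB series** — deliberately not the dB
of the mean power; a regression test asserts the two differ.  Atom
normalization shifts every bin by a constant dB offset and cannot affect
any downstream statistic (all are correlations or z-scores); a test asserts
this invariance.  Convolutions run in single precision by default
(~1e-5 dB error, far below any downstream tolerance).

## Electrode selection

Per electrode and movement, r² is the squared Pearson correlation between
per-trial mean HFB power (over the cue period — "end of a trial" is read as
cue offset) and the binary active-vs-rest design; other movements' trials
are excluded from the contrast.  Significance: the design is shuffled
(default 10 000 permutations) with add-one p-values, p ≥ 1/(n_perm+1), then
Benjamini–Hochberg FDR at α = 0.05 across electrodes **within each
movement** (the family choice is ambiguous in the source description; a
joint family is available via `fdr_family="joint"`).  An electrode is
selected when significant for ≥ 1 movement.  Permutations shuffle each
movement-vs-rest contrast separately.

## Classification

The envelope is smoothed with a centered 0.5 s moving average (truncated at
the run edges), z-scored per electrode **over the full run** (a constant
electrode z-scores to zero), and epoched into 2 s windows from cue onset
(extending 0.5 s past the cue, literally).  Spatial features time-average
each epoch; spatio-temporal features keep the electrode × time matrix.
Templates are per-class means over training trials; a test trial goes to
the class with the highest Pearson correlation, ties to the lowest class
index, and a zero-variance trial vector is defined to correlate 0 with
everything.

10-fold cross-validation uses stratified folds (with 20 trials per class,
each fold holds 8 trials, 2 per class; the trial→fold map is a seeded
permutation).  Electrode selection is re-run inside every fold on training
trials only (plus all rest trials, which are never classified), so the test
fold cannot influence feature selection.  When a fold's selection is empty
— common on null data, and never encountered in practice when real effects
exist — the fold falls back to all included electrodes; without a fallback
no classification would be defined.  Reported accuracy is the mean over
folds, with the SD over folds.  Significance of accuracy is a label-
permutation test repeating the entire cross-validation (the original
report does not name its test); the add-one convention applies.

Leave-one-trial-out CV serves the localization procedures; it takes the
electrode subset as given (selection happens at the whole-grid stage) and
is vectorized so thousands of subset evaluations are cheap.

## Localization

**Random-search importance**: each iteration draws a subset size uniformly
on [1, N], then a uniform subset of that size (the size law is not
published; a fixed-fraction rule is available), scores it with spatial
leave-one-out accuracy, and credits the accuracy to every member.  Final
scores are per-electrode means over crediting iterations, z-scored across
electrodes.  The convergence curve at iteration i is the mean correlation
of the cumulative pattern after i iterations with the patterns after every
later iteration; electrodes not yet included are filled with the mean of
defined entries (neutral under correlation), undefined (zero-variance)
correlations are skipped and counted, and the curve has length n_iter − 1.
The curve is computed from mean-accuracy patterns; z-scoring the patterns
would not change it, since Pearson correlation is affine-invariant.

**Searchlight**: square k×k windows (k = 1 … min(rows, cols)) step one
electrode at a time over the grid; each window's included electrodes are
scored with spatial leave-one-out accuracy (excluded channels are simply
absent; an empty window is NaN).  A k×k window at pitch s covers (k·s)² —
e.g. 3×3 at 4 mm is 12×12 mm = 1.44 cm² — matching the convention that a
3-row window "corresponds to approximately 12 × 12 mm".  The minimal area
for a target accuracy is the area of the smallest k whose best position
exceeds the threshold, with "not reached" signalled as None.

## Topographic maps

Per electrode, the winner is the movement with the highest r², kept only
when that r² is strictly above 0.2; ties go to the lowest movement index.
Maps live on electrode-grid (row, col) coordinates; the surface-normalized
group coordinate system used for published group maps requires subject
anatomy and is out of scope.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline on a 4×4 grid
(16 channels) at 512 Hz with the standard 100-trial design.  The
chance-level and calibration properties being checked do not depend on
channel count, and 16 channels keeps a hundred full-pipeline replicates
cheap on one CPU.  The scaled "test profile" (1000 selection permutations,
500 importance iterations) is used wherever the full 10 000/5000 settings
would only shrink Monte-Carlo error, not change the quantity; the defaults
in the library and CLI remain the full-profile values.  All randomness
flows from explicit integer seeds through `numpy.random.Generator`;
identical seeds give bit-identical runs, selections, folds and importance
maps.

## Known limitations

* The simulator's class effect is spatially Gaussian and temporally flat
  within a trial; spatio-temporal templates therefore gain little over
  spatial ones on synthetic data except through onset jitter.
* Permutation significance of accuracy re-runs the whole CV per
  permutation and is expensive at the full profile.
* Bad-channel thresholds are heuristics; grossly non-stationary artifacts
  are not modelled or detected.
* r² of HFB responses is computed on dB-scale power only.
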