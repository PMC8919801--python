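# Methods

`fingertap` analyzes the finger-tapping task as it is administered in
movement-disorder clinics: a seated participant taps index fingertip
against thumb "as fast and fully as possible" for about 15 s per hand
while a camera records the hand and a markerless pose tracker emits
per-frame 2-D coordinates for the index tip, thumb tip and wrist.  The
package starts from those landmark time series.  Everything upstream —
video decoding, network-based landmark detection, manual relabeling — is
out of scope by design.

## Signal model and preprocessing

The analysis object is the tapping amplitude time series: the per-frame
Euclidean distance between index tip and thumb tip.  The conditioning
chain is

1. trim to the annotated task segment (or an activity-based fallback
   window when no annotation exists);
2. leave-one-out cubic outlier rejection on the raw distance series;
3. cubic interpolation of missing-sample gaps up to 0.5 s;
4. downsampling of 60 Hz recordings to the common 30 Hz rate
   (anti-aliased FIR decimation);
5. zero-phase FIR low-pass at 10 Hz (windowed-sinc design, ~2 s of taps,
   applied forward–backward) to suppress frame-to-frame tracker jitter
   while preserving tap dynamics;
6. z-scoring to zero mean and unit variance, cancelling the scale effect
   of camera distance;
7. velocity, acceleration and jerk by central finite differences scaled
   by the sampling rate (one-sided at the edges).

QC runs on raw pixel-scale frames and normalization comes last: z-scoring
before outlier rejection would corrupt the robust scale estimates the
threshold depends on.

**Outlier detector.**  Each sample is re-estimated by a cubic through its
four nearest valid neighbors with the sample held out; the absolute
re-estimation error is its deviance.  Local polynomial support (rather
than a global spline) keeps a spike from leaking into its own estimate.
The masking threshold is expressed in robust units:
`6 × max(median(deviance), 0.2 × p95(|Δx|))`.  The median term adapts to
the jitter level; the frame-to-frame-increment floor protects the sharp
trough corners of a clean tapping waveform, whose median deviance is
essentially zero and would otherwise flag every contact event.  Masking
is iterative — the worst sample is removed and its neighborhood
re-estimated before the next decision — because a single large spike
inflates the deviance of the samples whose estimates it participates in.
Per-frame tracker confidence below 0.1 is treated as missing before any
of this runs.  Interior gaps longer than the 0.5 s interpolation limit
are bridged linearly so the filter sees a contiguous series, and flagged
as unrecoverable in the QC counters.

## Tap events and the feature inventory

Peaks (full finger extension) are local maxima with prominence ≥ 0.5
z-units and separation ≥ 0.15 s (`scipy.signal.find_peaks`); troughs
(finger–thumb contact) are the signal minima between consecutive peaks,
so the event sequence alternates by construction and partial edge cycles
are dropped.

Eleven summary measures are used throughout: mean, absolute mean, max,
min, std, median, 10th/90th percentile, range, interquartile range and
entropy.  Entropy is the Shannon entropy (nats) of a 16-bin equal-width
histogram over the sequence's own range, defined as 0 for a constant
sequence; no canonical definition exists for this statistic, so the
choice is recorded here and frozen by tests against an independent
histogram oracle.

The five families:

* **TS** — the 11 measures on amplitude, velocity, acceleration, jerk
  (44), plus the Welch spectral peak frequency (4 s segments, 50%
  overlap, searched in 0.5–10 Hz) as a flag-controlled extension;
* **Pk / Th** — the peak or trough amplitude sequence, its
  finite-difference derivatives taken against actual event times (the
  periods are irregular and the features are kinematic), 11 measures per
  series, plus the OLS slope of amplitude vs time;
* **PkTh** — time and amplitude drop from each peak to its following
  trough; mean/std/median of each (6);
* **ThTh** — a least-squares quadratic `a·τ² + b·τ + c` per
  trough-to-trough cycle on normalized cycle time τ∈[0,1]; the τ²
  coefficient is the curvature of the tap's inverted-U trajectory.

**Inventory profiles.**  The full-depth inventory is 143 features per
hand (TS 44, Pk 45, Th 45, PkTh 6, curvature-only ThTh 3), shipped as the
`canonical` profile (144 emitted per hand with the spectral extension).
A second profile, `paper-total`, fixes the event-family derivative depth
at two and featurizes all three quadratic coefficients, giving exactly
128 features per hand — TS 44 + spectral peak 1 + Pk 34 + Th 34 + PkTh 6
+ ThTh 9 — and 256 over both hands.  Every feature table is emitted with
a machine-readable manifest whose per-family counts must sum to the
total, so the inventory arithmetic is executable rather than assumed.

## Dimensionality reduction and models

Each family (both hands pooled) is standardized and decomposed by PCA
independently; the first two components per family give 10 model inputs.
Numerically constant columns (the z-scored amplitude mean is ~1e-17 by
construction) are dropped before decomposition, and a deterministic sign
convention (largest-magnitude loading positive) fixes the component
orientation.

Cross-validation is subject-grouped throughout: all sessions of a
participant share one fold, folds are balanced on recording counts by a
seeded greedy assignment, and 10 folds are used by default.
Classification is logistic regression with an L1 penalty by default
(L2 available); severity regression is ridge.  The regularization
strength is tuned per outer fold by an inner grouped 10-fold search over
a log-spaced grid (1e-3…1e3, 13 points); a fixed-strength fast path
exists for permutation nulls, where tuning cannot change the chance-level
expectation.  Standardization and PCA are fit inside each training fold
by default (leakage-safe); a `pca_scope="global"` switch fits them once
on all data for users who want the simpler single-decomposition
procedure.

Reported metrics come from pooled out-of-fold predictions: AUC plus
sensitivity/specificity at probability 0.5 for classification, Pearson r
(with r² reported as its square, matching how such pairs are printed in
the clinical literature) for regression.  95% intervals are percentile
bootstrap over subjects, 1,000 resamples by default.

**Feature contributions.**  A linear model on PC scores is expanded back
onto the original standardized features:
`contribution(feature) = Σ_c coef(PC_c) × loading(PC_c, feature)`,
summed over that feature's family components.  Contributions are signed,
ranked by magnitude, and the top 2% flagged for plotting; PCs zeroed by
the L1 penalty contribute nothing.  Diagnostics include Pearson
correlations of the disease-class probability with age and severity, and
per-feature Welch t tables between groups with Benjamini–Hochberg q
values appended.

**Clinical score harmonization.**  The unit-range common arm score is the
BARS arm score divided by 4 (the single-arm maximum) for ataxia, and the
arm bradykinesia composite divided by 12 for parkinsonism; controls are
fixed at exactly zero.  The parkinsonism divisor is configurable (a
divisor of 24 is also defensible given published cohort summaries; the
package defaults to 12 and asserts neither).

## The synthetic cohort generator

No public dataset of clinical tapping landmark series exists, so the
generator is first-class, tested code that defines the study conditions
for every downstream stage.  A recording is a train of tap cycles: cycle
k has period `T_k = (1/rate)·max(0.2, 1 + period_cv·ε_k)` and peak
amplitude `A_k = base_amp·(1 + amp_slope·t_k)·max(0.1, 1 + amp_cv·η_k)`
with standard-normal ε, η (the truncation floors keep the event structure
well-defined at high CV).  Within a cycle the index–thumb distance is the
parabola `d(τ) = A_k·4τ(1−τ)` — zero at the troughs, maximal mid-cycle —
so the trough-to-trough quadratic model is exact on clean data and the
cycle-fit stage has an analytic test surface.  Landmarks are rendered
with a fixed thumb anchor and tap direction, then corrupted with
i.i.d. Gaussian jitter (1.5 px), geometric-length dropout gaps
(per-frame start probability 0.004, mean length 0.2 s, all landmarks
missing, confidence 0) and isolated spike outliers on the index tip
(probability 0.003, 60 px).

Group presets encode the reported *directions* of impairment — ataxia:
1.8 Hz, period CV 0.25, amplitude CV 0.25; parkinsonism: 2.8 Hz, period
CV 0.10, amplitude CV 0.12, amplitude slope −0.03/s; control: 3.0 Hz,
period CV 0.05, amplitude CV 0.08.  The magnitudes are package defaults:
no quantitative phenotype magnitudes are published for this task, so
they were chosen once as clinically plausible and are fully
configurable.  Cohort generation draws per-subject parameters around the
presets, adds a mild per-hand asymmetry (5%), assigns ages from
group-specific normal distributions (49±22, 67±8, 30±20 years, clipped
to plausible ranges), and defaults to the published cohort sizes: 169
ataxia, 74 parkinsonism and 58 control sessions, with repeat-visit
counts of 41/13/8 (repeat subjects contribute two sessions sharing their
subject-level phenotype).

Severity is a deterministic monotone map of the pathological axes,
`severity = 1.0·period_cv + 0.6·amp_cv + 0.8·max(0, 1 − rate/3.0)`
clipped to [0,1], with controls fixed at 0.  Clinical scale values
derive from it: BARS arm = severity×4 rounded to 0.5 steps, BARS total ≈
severity×30; UPDRS arm composite = severity×12, rounded.  The weights
make the preset groups span a usable severity range without saturating
the clip.

**What the generator does and does not emulate.**  It reproduces the
statistical structure the features measure — rate, rhythm and amplitude
variability, amplitude decrement, tracker noise, dropouts, spikes,
repeated visits, group-dependent ages — under an idealized parabolic
cycle shape with a stationary hand.  It does not simulate hand drift
toward or away from the camera (a real-world confound of 2-D distance
amplitudes), contact dwell at the trough, tremor superimposed on the
tap, or correlated tracker failure modes.  Passing tests therefore
demonstrate that the pipeline recovers phenotype structure of this kind
when present; they do not certify clinical accuracy on real video, and
the published cohort's AUC/r values are not reproduction targets (that
data is unavailable).

## Numerical choices and problem sizes

* Cubic interpolation/estimation uses local 4-point polynomial fits in
  shifted coordinates (exact for cubics, numerically stable, no global
  leakage).
* Cycle fits require ≥ 4 samples; shorter cycles are skipped with a
  warning.
* Event families require enough events for the deepest derivative series
  to retain ≥ 2 points (depth + 2).
* Peak-plateau ties (two equal samples around a symmetric peak) resolve
  deterministically via the detector's plateau midpoint.
* Monte-Carlo checks run at deliberately modest sizes chosen as adequate
  for their margins: directional recovery uses 100 cohort pairs of 6 + 6
  sessions, discrimination uses 20 seeds of 100 + 100 sessions,
  permutation nulls use 100 subject-level permutations, fold integrity
  uses 1,000 random rosters.

## Known limitations

* The outlier threshold's increment floor trades spike sensitivity for
  trough safety; spikes whose distance displacement is below roughly the
  per-frame signal excursion can survive QC (they are then attenuated by
  the low-pass).
* The auto-trim fallback is a heuristic for unannotated recordings and is
  off by default; clinical use should prefer explicit task segments.
* With near-perfect preset separation the logistic probabilities
  saturate, so probability–severity correlations within a single group
  are weaker than across the pooled cohort.
* r² is the square of the out-of-fold Pearson correlation, not the
  out-of-sample coefficient of determination; the two diverge when
  predictions are biased.
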