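# Methods

This note documents the models, parameter choices and numerical conventions
behind `turngait`, and what the synthetic-data experiments do and do not
demonstrate.

## The classification problem

Participants walk a six-minute walk test (6MWT): continuous passes along a
~30 m walkway with a 180° turn at each end. Three tri-axial accelerometers
(posterior pelvis/lower back, left and right lateral shanks; axes vertical,
medial-lateral, anterior-posterior; units g) record at a nominal 50 Hz.
Labels are prospective: a participant who falls at least once during a
six-month follow-up is a prospective faller (PF), otherwise a non-faller
(NF). The scientific question is whether features computed from the *turn*
sections classify future fallers better than the same features computed from
*straight* walking.

## Synthetic session model

Clinical accelerometer recordings of this kind are generally not
shareable, so the package ships a generator that reproduces the statistical
structure the analysis depends on, with planted ground truth.

**Schedule.** Walking starts 1 s after a synchronization spike. One walkway
cycle lasts `walkway_time_s` (default 25 s) and ends with a five-step turn;
the walker keeps walking until the session clock runs out, so the final
straight pass may be partial. Each planted turn interval spans its five
steps plus half an impulse width on each side.

**Vertical channel.** Each foot strike at time `t_j` contributes a
raised-cosine impulse

    a_j · ½(1 + cos(2π(t − t_j)/w)),   |t − t_j| < w/2,

with width `w` equal to half the step period, plus a small harmonic series
of the step frequency (trunk gain 0.15, shank gain 0.05 of the step
amplitude — a shank is comparatively quiet between its own strikes). Step
amplitudes `a_j` combine:

* a left/right split `1 ± asymmetry` — a symmetric gait is periodic at the
  *step* period, so its spectrum lives on even harmonics of the stride
  frequency; alternate-step scaling provably injects odd stride harmonics
  and therefore lowers REOH;
* a per-section scale with coefficient of variation `section_variability`,
  clipped to [0.8, 1.3] of nominal (a walker does not halve or double their
  vertical impulse between passes), which drives the across-section SD
  aggregates;
* site weights: the lower back sees both feet at full weight, each shank
  sees its own foot at 1.0 and the contralateral strike at 0.1 (a small
  transmitted transient). Keeping the contralateral weight and shank
  harmonic gain below the step-detection prominence is what makes shank
  "strides" genuinely same-foot strike pairs.

The whole vertical channel is multiplied by `turn_attenuation` (default
0.5) inside each planted turn interval — the magnitude drop that the turn
detector exploits.

**Other channels.** The AP channel carries phase-lagged biphasic (sine
lobe) impulses with the same amplitude structure, so it responds to
asymmetry like the vertical channel; the ML channel is a stride-frequency
sway plus an extra 0.4 Hz component during turns. Band-limited Gaussian
noise above 12.5 Hz with power `hf_noise_power` (g²) is added to all axes —
this is the knob that lowers FQFFT — plus a 0.01 g broadband sensor floor.

**Clocks.** Each sensor runs at 50·(1 + jitter) Hz with per-sensor jitter
drawn within `sample_rate_jitter` (default ±0.4%), and starts 0.1–0.4 s
before the common synchronization spike (amplitude 3× step amplitude), so
first-peak synchronization is well defined and non-trivial.

**Class profiles.** Defaults: NF asymmetry 0.05, HF noise power 0.0005 g²,
section variability 0.05; PF 0.20 / 0.003 g² / 0.12. These effect sizes are
the generator's own choices of a clearly-detectable impairment, not
measured population values; no generative faller model exists to copy.
Consequently the synthetic cohorts are *easier* to classify than a clinical
cohort — passing tests demonstrate that the pipeline recovers planted
structure, not that clinical accuracy would reach these levels.

**Determinism.** All randomness flows from one `numpy` generator seeded per
session; cohorts derive participant seeds as `base_seed + index`.

## Preprocessing choices

* **Resampling** to a uniform 0.02 s grid uses cubic-spline interpolation
  (linear for under 4 samples): at 50 Hz a linear interpolant distorts
  5 Hz content by several percent of the amplitude, which would leak into
  the spectral features.
* **Synchronization**: each sensor's first vertical peak with prominence
  ≥ 1.0 g defines time zero; signals are truncated to the common overlap
  and the first 0.5 s after the spike is discarded so the spike cannot be
  mistaken for a step.
* **Step detection**: vertical peaks with prominence ≥ 0.3 g and minimum
  separation 0.3 s (a cadence ceiling of 200 steps/min).
* **Turn detection**: the 1.0 s sliding RMS of the lower-back vertical
  channel is compared with its session median; maximal runs below
  0.7×median lasting ≥ 0.5 s are candidates. The detected step nearest the
  RMS minimum becomes the centre step; the segment is centre ± 2 steps with
  0.2 s buffers; candidates without five available steps are dropped and
  overlaps resolve in favour of the deeper RMS minimum. Window, statistic,
  threshold and driver site are config keys — the underlying phenomenon is
  only "reduced vertical magnitude", so these constants are this package's
  operationalization. Sessions with fewer than two detected turns are
  flagged for exclusion.
* **Straight sections** are the complement of the turns, trimmed 0.2 s at
  each junction, and must contain at least 3 reference-foot (left shank)
  strides.
* **Stride definitions**: shank strides are consecutive same-site strike
  pairs; lower-back strides are anchored on left-shank strikes (the choice
  of anchoring foot is arbitrary; it is fixed for determinism).

## Feature conventions

* **Directional statistics** are computed over the positive samples
  (max/mean/SD) and the magnitudes of negative samples of each axis within
  a stride, then averaged across the section's strides. An empty direction
  contributes zeros. SD is the sample SD (ddof = 1) everywhere, defined as
  0 for fewer than two observations.
* **FQFFT** = Σ|A(f)| for 0 < f < 12.5 Hz over Σ|A(f)| for 0 < f ≤ 25 Hz on
  the mean-removed amplitude spectrum of the whole section (a power-spectrum
  variant is available behind a switch). An all-zero signal is defined as
  1.0. The 12.5 Hz edge is the first quartile of the 0–50 Hz FFT range.
* **REOH** samples the magnitude spectrum at the bin nearest k·(stride
  frequency), k = 1…20, and returns Σeven/(Σeven+Σodd) ∈ [0, 1] (the
  bounded form; the literal even/odd quotient is available behind a
  switch). The section's stride frequency is 1/(mean left-shank
  strike-to-strike interval). Computed per section, not per stride: a ~1 s
  stride at 50 Hz cannot resolve stride-frequency harmonics. Note that
  lower-back REOH approaches 1 for symmetric gait and falls with
  asymmetry, while shank REOH sits near 0.5 regardless: a single-foot
  impulse train is periodic at the stride period and carries even and odd
  harmonics alike.
* **Aggregation**: max/min/mean/SD of each of the 74 features across a
  participant's sections of one condition (296 values; SD = 0 for a single
  section). NaN per-section values (e.g. REOH in a section with fewer than
  two strides) are excluded from aggregates; a feature missing in every
  section excludes the participant.

## Modeling conventions

* Min–max normalization learns `y_min`/`y_max` from training rows only;
  constant features map to 0; test values are not clamped to [0, 1].
* SEL combines an F-test p < α filter with Benjamini–Hochberg FDR at α
  (α = 0.05), deduplicated, ordered by p; if nothing passes, the single
  best-p feature is used (logged).
* RFE uses impurity importances of a 100-tree random forest, removing 10%
  of the surviving features per round down to k = 5 (`rfe_step` config;
  set to 1 for literal one-at-a-time elimination). One-by-one elimination
  from ~300 features costs ~60× more forest fits and produced no ranking
  difference at these cohort sizes.
* SVMs use C = 1, scale gamma, coef0 = 0; kNN uses Euclidean distance and
  uniform weights. These are library defaults, recorded here because no
  tuning is performed anywhere.
* Metrics treat PF as the positive class; any 0/0 is defined as 0
  (logged). MCC uses its defining confusion-count formula.

## Protocol conventions

* Competition ranking: higher metric = better; ties share the minimal
  position (scores 9,8,7,7,7,6,5 → ranks 1,2,3,3,3,6,7); the rank sum over
  the seven metrics orders combinations.
* CI half-width = 1.96·SD/√n over the n CV repetitions.
* Per-iteration seeds derive from the base seed via
  `numpy.random.SeedSequence(base, spawn_key=(…))`, so any iteration can be
  reproduced in isolation.
* Pruning after Test I counts classifier/selector appearances in the pooled
  straight+turn top nine; ties are broken against the candidate with the
  worse best rank sum.
* MFO threshold = 10% of the iteration count (250 of 2500); frequency ties
  break alphabetically for determinism. An optional cap
  (`mfo_max_features`) truncates the MFO list to its most frequent
  entries: an unbounded selector (SEL) on a strongly separated cohort can
  pass hundreds of features in every iteration, which would make the
  nested sweep quadratic in a long tail of ties without changing its
  conclusion. The cap is off by default.
* Test IV takes its top four classifiers from the Test II *turn* ranking,
  since Test IV's purpose is to probe whether straight features add
  anything to the turn result.
* Welch comparisons use the Welch–Satterthwaite df and are computed for all
  seven metrics; a metric constant in both compared samples is skipped with
  a warning.

## Null-cohort calibration and the selection winner's curse

With a pinned feature set, repeated shuffle-split CV on a label-independent
cohort yields mean MCC statistically indistinguishable from zero (tested).
With *per-iteration feature selection* on a fixed null cohort this is no
longer true: iterations are correlated through the shared sample, and the
selected (maximal train-correlation) feature systematically overstates even
its own cohort-level correlation, so the held-out complement absorbs the
difference and the mean MCC is systematically *negative* (measured −0.1 to
−0.3 on 40-participant null cohorts, every classifier×selector
combination). This is a property of the resampling scheme, not a leak: it
disappears when selection is pinned. Naive `SD/√n_iterations` bands treat
iterations as independent and will reject such null runs; conclusions about
class signal should rest on comparisons between conditions (as the Welch
tests do), not on the distance of a single condition's mean from zero.

## Problem sizes

The test suite exercises the full pipeline on 2-minute sessions and
40-participant cohorts with 200 shuffle-split iterations; the acceptance
script simulates a 43-participant cohort (26 NF / 17 PF — the 43:28 class
ratio at desk scale) of 6-minute sessions and runs the four-test protocol
at 100 iterations with the MFO list capped at 10. The iteration count and
cap are config keys (`ProtocolConfig.n_iter`, default 2500;
`mfo_max_features`, default off); all reported CIs scale with the count
actually run.

## Known limitations

* The generator is a phenomenological signal model: no musculoskeletal
  dynamics, no gyroscope/magnetometer channels, no real logger artifacts.
* Faller effect sizes are synthetic design choices; absolute classification
  numbers on synthetic cohorts say nothing about clinical performance.
* Turn detection assumes the vertical-magnitude drop; gaits whose turns do
  not attenuate vertical impact (or data without a synchronization spike)
  need different segmentation.
* The five-step turn standardization may clip or pad real turns; the effect
  of this standardization on REOH is untested here.
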