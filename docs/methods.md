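# Methods

This note records the model, the choices made where the design was open, the
numerical conventions, and what the synthetic data can and cannot show.

## Paradigm and signal model

A session is a 20-minute auditory oddball run: stimuli every 575 ms
(stimulus-onset asynchrony = 75 ms standard tone + 500 ms gap), each
independently a deviant with probability 0.14.  The SOA is a parameter
because the interstimulus convention (onset-to-onset vs offset-to-onset) is
ambiguous in practice; epoching always keys off the recorded event onsets,
never an assumed period, so the analysis is valid for any SOA.  An optional
flag suppresses back-to-back deviants (common oddball practice); the default
is i.i.d. placement.

Recordings carry four channels (Fz, Cz, C3, C4) in microvolts.  Default
sampling rate 500 Hz — any fs ≥ 200 Hz keeps the 20/320 ms window edges
within one sample of the grid.

## Preprocessing

- Standard pathway: Cz, Butterworth band-pass 0.5–50 Hz, order 4.
- Deviant pathway: sample-wise channel sum (or Cz alone in single-electrode
  mode), Butterworth low-pass 10 Hz, order 2, applied to the continuous
  summed trace before epoching.  Epoch-then-filter is exposed as a flag for
  sensitivity checks; the two orders agree up to edge effects because the
  filter is linear and time-invariant.
- All filtering is zero-phase (forward–backward, `sosfiltfilt`).  Rationale:
  the deviant features depend on extrema *positions*, which a causal filter
  would delay.  Consequence: the effective magnitude response is the square
  of the single-pass response (0.5 at the nominal cutoff, not 1/√2).
- Epochs are [0, 500] ms post-onset; all statistics use the closed
  [20, 320] ms window (151 samples at 500 Hz).  Both windows are
  configurable.
- No baseline correction: σ and |ΔV| subtract means or difference extrema,
  r is correlation-based, and N_E depends only on ordering, so every feature
  is invariant to constant offsets and the band-pass removes drift anyway.
- No automatic artifact rejection by default (the analysis assumes
  pre-screened recordings); an optional peak-to-peak epoch-rejection
  threshold exists for real data.
- Half-split: epochs belong to the half containing their onset, split at the
  session midpoint.

## Features

- σ_X uses the population (1/N) variance convention, matching the integral
  mean; so does the cohort z-score.  Cohort normalization divides by the
  standard deviation, not the variance — dividing by Var would make the map
  coordinates unit-inconsistent.
- The split-half similarity r is the Pearson correlation between the two
  half-session averages (n = 2 halves fixed by default, parameterizable).
- Extrema on sampled data: a point is an extremum where the first difference
  changes sign; plateaus (runs of equal samples) collapse to one extremum at
  the run midpoint; endpoints never count.  This definition is robust and
  brute-force checkable, and makes |ΔV| ≤ total variation hold by
  construction.
- Standard-map features always come from Cz (the most reproducible ERP
  site); the electrode mode only switches the deviant channel sum.

## Classifiers

- Gaussian: per-class ML mean and covariance (1/N), prior = good-class
  fraction.  A covariance is regularized by ε·I with
  ε = 1e-6 × mean(diagonal) when its smallest eigenvalue falls below ε —
  relevant for tight clusters of few patients.  Posteriors are computed in
  log space.
- kNN: Euclidean distance on the normalized map, k = 4 by default (the
  sweep k ∈ {3, 4, 6, 8} is available through the configuration).  Distance
  ties at the k-th rank include all co-ranked points and renormalize, so
  results are independent of training-point order.  Weighted mode uses
  inverse-distance weights over the K nearest only; a zero-distance query
  short-circuits to the label fraction among exact matches.
- SVM: soft-margin RBF (γ = 1, C = 10) through a standard dual solver.  The
  posterior is a one-parameter sigmoid of the signed decision value, slope
  fitted by maximum likelihood on the training scores and clipped to
  [1e-3, 50] (separable training sets push the ML slope to infinity).  With
  no intercept, p = 0.5 sits exactly on the decision boundary.  The exact
  probability construction for SVM maps is a documented package choice; the
  confusion matrices are stable across (γ, C) ∈ [0.5, 2.5] × [3, 30] on
  separable cohorts, which the suite asserts.
- Hard labels use p > 0.5 ⇒ good; exactly 0.5 ⇒ bad, conservative toward
  specificity.
- The three families extrapolate differently outside the data support (kNN
  tends to the perpendicular bisector, the RBF decision to its intercept
  sign, the Gaussian boundary is quadratic), so probability maps should be
  read near the cohort, not at the grid margins.

## Validation and decision

Leave-one-out refits the z-score *and* the classifier on every fold's n−1
training patients and projects the held-out point with training statistics —
no cohort-level leakage.  The fold score s_i ∈ {0, 1} aggregates to
s = mean(s_i), which equals the accuracy of the pooled confusion matrix by
construction.  Confusion counts use the standard convention with
positive = good outcome.

The combined decision p_dec = min(p_standard map, p_deviant map) uses, by
default, unweighted kNN on the standard map and distance-weighted kNN on the
deviant map.  Taking the minimum is conservative: a good call requires both
maps to agree, so the combined rule cannot produce more false positives than
either input.

The two-sided Fisher exact test follows the point-probability convention
(sum of hypergeometric probabilities ≤ the observed one); the doubling
convention would give different values on asymmetric tables.

## Synthetic cohorts

The generator emulates the study conditions: 20-minute sessions, 86/14 %
tone mix, 575 ms SOA, four channels, 6 good / 23 bad patients.  Signal =
stationary background (pink:white RMS ratio 2:1, total 2 µV RMS) + per-event
ERP template.  Templates are sums of Gaussian-windowed components shaped
like the P50/N100/P200(/N300) sequence; the minor early/late components are
expressed per patient with probabilities 0.7/0.5, and every component's
amplitude (log-normal, sd 0.2), latency (±15 ms sd) and width (0.85–1.25×)
vary per patient.  This inter-patient morphology variability is what gives
the discrete extrema count a realistic spread across a cohort.

Class differences: good patients have SNR 3 (peak ≈ 6 µV against the 2 µV
reference background) and a stable template; bad patients have SNR 0.4,
20 ms-sd per-trial latency jitter, and their second-half template morphs
80 % of the way toward an alternative low-correlation morphology
(`similarity_drift_bad = 0.8`), which degrades the split-half similarity.
SNR is defined against the fixed 2 µV reference so the ERP survives when
noise is switched off for exactness tests.

Seeding: one master seed; each patient's schedule and signal streams derive
from `SeedSequence(master, spawn_key=(patient, stream))`, so cohorts are
bit-reproducible and patients independent.

What passing tests show — and do not show: under these defaults the two
classes form well-separated clusters in both maps, so classifiers recovering
the labels (median LOO ≥ 0.9 over 20 seeds) demonstrates the *pipeline's*
correctness end to end, not clinical performance.  Real recordings add
non-stationary artifacts (ECMO, ventilation, electrode drift), sedation
effects, overlapping class distributions and label noise, none of which the
generator models beyond stationary colored noise.

## Problem sizes used by the suite

The cohort-level tests run 20 seeded 6/23 cohorts at full session length
(20 min, 500 Hz) — about two minutes of compute, shared through one session
fixture.  Fast unit tests use 1–4 minute sessions at 250 Hz.  The
acceptance script draws 20 full-length schedules.

## Known limitations

- The EDF writer is minimal (EDF+C, 1 s records, 16-bit, one annotation
  signal); it round-trips through MNE but does not implement the full EDF+
  specification (no sub-second record offsets, no discontinuous files).
- `N_E` is discrete; cohorts whose patients all share one extrema count have
  a degenerate deviant map and raise `DegenerateFeatureError` rather than
  silently dividing by zero.
- The Gaussian model assumes elliptical classes; with 6 positive patients
  its covariance is barely estimable and leans on the ε regularization.
- Probability grids default to [−3, 3]² at step 0.05; posteriors outside the
  data support are extrapolations (see above).
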