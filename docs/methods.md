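# Methods

This note documents the models, estimators and design choices behind
`qeegml`, what the synthetic-data generator does and does not emulate, and
the problem sizes the default configurations are tuned for.

## Spectral features

**Estimator.** Power spectral density is estimated by averaged modified
periodograms (Welch): Hann window, 50 % overlap, per-window mean removal.
The window length is `fs / resolution` samples, 4 s at the default 0.25 Hz
resolution, so PSD bins land exactly on multiples of 0.25 Hz. Band powers
integrate the PSD over half-open intervals `[low, high)`; the topmost band
(gamma) is closed at 45 Hz so the eight bands tile [1, 45] Hz exactly and
the per-channel band-power sum equals the total PSD integral over that
range. A bin at a shared edge (e.g. exactly 10 Hz) belongs to the upper
band.

**Relative power.** Each channel's eight band powers are divided by their
sum, i.e. the denominator is total 1–45 Hz power. Relative powers are
therefore per-channel probability vectors, invariant to per-subject
amplitude scale (skull conductivity, gain), and invariant to any
common-mode signal because extraction always re-references to the common
average first (instantaneous 19-channel mean subtracted; idempotent).

**Assumptions.** Inputs are assumed artifact-free: no filtering, ICA or
artifact rejection is performed. Recordings must carry the 19 canonical
10–20 labels; EDF channel names are matched case-insensitively with
reference-suffix stripping and the modern T7/T8/P7/P8 synonyms.

## Synthetic cohorts

The generator is specified by a *band-power template contract*: each
subject has a 19×8 matrix of expected relative band powers, and a generated
recording's extracted features equal that template up to PSD-estimation
error (≲ 0.013 absolute at 180 s, tested at 0.02).

* **Baseline template** — an alpha-dominant, gamma-poor eyes-closed
  spectrum (δ .22, θ .16, α1 .19, α2 .13, β1 .10, β2 .08, β3 .08, γ .04)
  with a posterior alpha boost on T5/P3/Pz/P4/T6/O1/O2.
* **Group effects** — additive shifts of band relative power on listed
  channels, renormalised per channel. The default positive-group profile
  raises delta and beta1 and lowers alpha and gamma over the channel sets
  where those group differences are reported; one scalar (default 0.02,
  against a between-subject SD of 0.02) scales all shifts. No effect
  magnitudes are published, so these are free parameters chosen to make a
  single shifted feature detectable by a two-sample test at n = 100/100
  with power > 0.9 at α = 0.01 — a moderate, recoverable effect.
* **Signals** — random-phase multisines on the record's Fourier grid:
  pink (1/f^1.2) magnitude profile inside each band, plus a Gaussian
  9 Hz peak in alpha1 (the posterior dominant rhythm), rescaled band-by-band
  so each band's variance matches the template (total 400 µV², ~20 µV rms).
  The peak is centred mid-band because energy at the 10 Hz band edge leaks
  across the alpha1/alpha2 boundary under Hann windowing and would break
  the template contract. Fixing the seed fixes every sample; per-subject
  seeds derive from `(design seed, subject index)` so cohorts extend
  without reshuffling existing subjects.
* **What is not modelled** — eye-blink/muscle/electrode artifacts, drift,
  non-stationarity, volume-conduction correlation between channels, age and
  sex structure, and site effects. Passing tests therefore demonstrate that
  the machinery recovers planted spectral group structure from clean,
  stationary data; they do not demonstrate clinical performance.

Cohort compositions default to the target population's: SCD 34 positive /
146 negative, MCI 29/34 (prevalence ≈ 1:2.5), ~180 s at 200 or 250 Hz.

## Cohort preparation

* **Holdout** — stratified by (diagnosis, amyloid label); the total test
  count is `round(fraction · n)`, apportioned across strata by largest
  remainder; deterministic per seed. Default fraction 0.2.
* **Augmentation** — every amyloid-positive *training* subject is replaced
  by the feature vectors of the first and second temporal halves of its
  recording (lineage recorded), exactly doubling the positive training
  count. Test rows are never augmented, and a subject's halves never
  straddle the train/test boundary or a CV fold. Without recordings the
  rows are duplicated verbatim — a degraded mode that rebalances classes
  but adds no spectral information, flagged by a warning.
* **Reliability screen** — per-channel Pearson correlation between the
  Welch PSDs of the two halves over [1, 45] Hz, with a > 0.90 pass
  threshold. The screen uses 0.5 Hz windows (2 s): a stability check wants
  a low-variance estimate, and halving the window doubles the averaged
  periodograms per half. Advisory by default; strict mode raises.

## Univariate screening

Welch's two-sample t-test per feature (the groups are independent
subjects, so an unequal-variance two-sample test is the appropriate form),
augmented halves collapsed to one row per subject first. No multiplicity
correction by default — the topography is a feature-wise report —
with Benjamini–Hochberg adjusted p-values available. Under the null
generator the screen is calibrated: ~5 % of features flagged at α = 0.05
(tested against a 99 % binomial band over 500 replicate tables). Screening
does not gate the combinatorial search.

## Generational combinatorial search

Each generation enumerates **all** C(|pool|, k) k-feature combinations and
scores each by stratified, lineage-grouped 5-fold CV. "Good models" are the
top 1 % per generation with a floor of 50; each feature's occurrence count
among them is the gene tally. The next generation's pool is the
highest-tally features within a budget (ties broken by the best CV accuracy
of a top model containing the feature, then canonical feature order). The
first reduced generation merges tallies from all fully exhaustive
generations; later ones use their predecessor. Models above the retention
accuracy (default 0.75) become ensemble candidates. With no pool budget the
procedure degenerates to exhaustive search — the property used to validate
it against a brute-force oracle on 12-feature pools.

**Classifier.** Linear SVM with per-fold unit-variance standardisation:
the L2-regularised squared-hinge primal (the `LinearSVC(dual=False)`
objective, bias regularised) solved directly by damped Newton iteration.
The problem has at most `k_max + 1 ≤ 6` unknowns and is strictly convex, so
a few Newton steps reach machine precision; a direct solver is used because
one search evaluates 10⁴–10⁶ combinations and per-call estimator overhead
would dominate. Coefficient-level agreement with scikit-learn's LinearSVC
is asserted in the tests. Degenerate folds (a class missing) trigger a
bounded reshuffle with an incremented seed.

**Problem sizes.** Exhaustive k = 3 over 152 features is 573,800
evaluations; the desk-scale default schedule keeps generation 1 exhaustive
over all 152 features and caps later pools at {2: 40, 3: 25, 4: 20, 5: 16},
i.e. ~12.5k evaluations (≈15 s single-core) for a full five-generation
search. A budget guard (default 700,000 evaluations) refuses larger
generations and suggests pool reduction. Searches can checkpoint each
generation to JSON-lines.

## Ensemble, cutoff, evaluation

* **Selection** — candidates are ranked by the mean of CV accuracy and
  accuracy on selection data. Default selection data is an inner validation
  quarter carved out of the training rows (grouped, stratified), so the
  holdout is never touched; `selection="holdout"` reproduces the protocol
  of ranking by holdout accuracy and is tagged on the resulting ensemble.
  The top 20 (fewer, with a warning) are refit on the full training split.
* **Scoring** — a subject's score is the fraction of sub-models voting
  positive; scores live on the grid k/n, k = 0…n.
* **Cutoff** — Youden's J maximised over the observed score grid
  (prediction rule: score ≥ cutoff; ties take the lower cutoff, favouring
  sensitivity; J ≤ 0 everywhere falls back to 0.5). The scores used are
  **out-of-fold**: the ensemble's combinations are refit without each
  training fold and score the held-out original subjects, because refit
  sub-models score their own training rows near-perfectly and an in-sample
  fit drives the cutoff toward degenerate extremes. A fixed user cutoff is
  also supported.
* **Evaluation** — strict mode audits the test table (no augmented rows, no
  subjects seen in training) before scoring; the confusion matrix yields
  sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy, and
  balanced accuracy = (sensitivity+specificity)/2. SCD and MCI are trained
  and evaluated as separate strata throughout.

## Numerical and degenerate-input conventions

Relative-power rows are validated to sum to 1 within 1e-9; zero-total-power
channels, zero-variance features (both groups), single-class tables,
too-short recordings and Nyquist-violating sampling rates raise immediately
with specific messages. All tie-breaks (top-model ordering, pool ranking,
cutoff ties) are deterministic and documented in the docstrings.

## Known limitations

* Synthetic channels are statistically independent; real EEG is strongly
  spatially correlated, which changes the effective multiplicity of the
  152 features and likely makes the search easier here than on real data.
* The holdout strata are small at realistic prevalence (6–7 positive test
  subjects per stratum), so per-run holdout metrics are noisy by
  construction; seed-to-seed variation of ±15 percentage points in
  sensitivity is expected and observed.
* The degraded (duplication) augmentation mode rebalances classes without
  new information; signal-level augmentation is preferred whenever
  recordings are available.
* EDF files can be read but not written (no EDF-export backend is a
  dependency); synthetic cohorts are stored as plain-text matrices plus a
  manifest.
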