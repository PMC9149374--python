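# Methods

This note documents the models, conventions and design choices behind
`mwlindex`, stage by stage, including what the synthetic-data generator does
and does not emulate.

## Synthetic cohort generator

Each recording is `fs × duration` samples × 14 channels (defaults 128 Hz,
150 s → 19,200 rows) in the fixed montage AF3 F7 F3 FC5 T7 P7 O1 O2 P8 T8
FC6 F4 F8 AF4. A channel is the sum of

* an independent pink-noise floor (`1/f^β`, default β = 1, 10 µV RMS),
* a theta-band (4–8 Hz) oscillation weighted 1.0 on frontal channels
  {AF3, AF4, F3, F4, F7, F8, FC5, FC6} and 0.3 elsewhere,
* an alpha-band (8–12 Hz) oscillation weighted 1.0 on parietal/occipital
  channels {P7, P8, O1, O2} and 0.3 elsewhere.

Oscillations are band-passed Gaussian noise, not sinusoids, so periodogram
estimates carry realistic variance. Each band mixes a cohort-shared source
with a channel-local one (half weight each) so channels correlate without
being copies. Under the *Simkap* condition theta power is multiplied by
`theta_task_gain` (default 2) and alpha power by `alpha_task_gain` (default
0.5); these defaults are the study conditions used throughout the tests and
the acceptance computation.

**Between-subject amplitude spread.** Every subject's recording is scaled by
a log-normal gain (`subject_scale_sigma` = 0.4, identical for the subject's
two conditions). Real EEG band power varies by roughly an order of magnitude
across individuals (skull thickness, electrode impedance, gain), and this
spread is the physiological reason band *ratios* are preferred over absolute
band powers: ratios are invariant to a per-subject scale, absolute powers
are not. Without it, absolute cluster power separates the conditions almost
perfectly and the single-band/ratio comparison is degenerate.

**Ratings** are drawn from a discretized Gaussian (σ = 1.2) centered at 3
for *Rest* and 3 + `rating_effect` (default 4) for *Simkap*, clipped to
1–9. The defaults produce a strongly bimodal cohort in which most *Rest*
rows binarize to "suboptimal" and most *Simkap* rows to "superoptimal",
with occasional neutral 5s that are discarded. For chance-level (null)
simulations the sensible configuration is `rating_effect=0` with
`rest_rating_mean=5`: ratings are then symmetric around the discarded
neutral point, both labels are equally likely, and labels are independent
of the signal. (`rating_effect=0` with the default center of 3 yields an
almost single-class cohort, which is a class-imbalance regime, not a
chance-level one.)

**Blinks** arrive as a Poisson process (default 0.1 events/s) of ~400 ms
Hann pulses (~150 µV) on AF3/AF4 with reduced weight on F7/F8, with a
ground-truth sample mask. Their energy is below 4 Hz, giving the denoiser a
measurable target.

**Determinism.** One master seed; independent per-(subject, condition,
purpose) substreams are derived through `numpy.random.SeedSequence` keyed
on integer tuples, so any recording can be regenerated in isolation.

What the generator does **not** emulate: volume conduction and realistic
channel covariance, ERP morphology, non-stationarity within a recording,
muscle/line-noise artifacts, and any coupling between rating and EEG beyond
the shared condition. Passing tests therefore demonstrate that the pipeline
recovers the structure the generator encodes — band-limited power effects
observable through ratings — not that it would reach the same numbers on
real recordings.

## Denoising

Average re-reference, then a zero-phase 4th-order Butterworth high-pass at
1 Hz (`sosfiltfilt`), then fixed-point negentropy-maximizing ICA (FastICA,
tanh contrast, max 500 iterations, tol 1e-5). The ICA dimension defaults to
the numerical rank of the data — 13 after average reference — so that
reconstruction with nothing removed is exact to numerical precision.

Components are screened by four statistics:

* **spectral kurtosis** — excess kurtosis of Welch PSD ordinates (2-s Hann
  segments, 50% overlap);
* **spectral slope** — least-squares slope of log10 power vs log10
  frequency over 1–40 Hz (the regression reading of a "mean spectral
  slope"; a two-point difference is ill-defined for noisy spectra);
* **Hurst exponent** — rescaled-range estimate over dyadic block sizes
  (≥16), log–log regression of mean R/S on block length. White noise lands
  near 0.5 (slightly above, the estimator's known small-sample bias);
* **gradient median** — median absolute first difference of the component
  time course (absolute value so large transients always increase it).

Constant components use the conventions kurtosis 0, slope 0, Hurst 0.5,
gradient median 0 — never NaN. Each statistic is z-scored across the
components of one recording (population SD) and a component is flagged when
any |z| > 3. Flagged components are zeroed and the channels reconstructed
by the inverse transform. ICA runs once per subject × condition recording.
The ±3 rule is an outlier test, so it occasionally flags a clean component
(roughly the rate expected of a 14-sample outlier screen); the benchmark
with injected blinks shows flagged components capture the artifact and
reduce sub-4 Hz frontal energy in ≥ 90% of runs.

## Band powers and indexes

Windows are 1 s, non-overlapping, trailing remainder dropped. Per window
and channel the PSD is a Hann-tapered periodogram (128 samples → 1 Hz
bins; averaging multiple segments inside 1 s is impossible at this
resolution). Band power is the **sum** of ordinates with frequency in the
half-open band [lo, hi) — 8 Hz belongs to alpha only, no double counting —
with the DC bin always excluded. Cluster power is the arithmetic mean over
the cluster's electrodes; cluster powers are floored at 1e-12 µV² before
any division so degenerate windows cannot divide by zero. Ratio indexes are
scale-invariant; single-band indexes scale with amplitude squared.

## Feature catalog

Exactly 210 features, 70 per domain, frozen in `FEATURE_NAMES` order:

* *statistical*: moments through the 6th, robust location/scale, 21
  quantiles, ECDF evaluated at 10 evenly spaced points of the value range,
  10-bin histogram frequencies, histogram entropy;
* *temporal*: difference statistics, linear trend, Hjorth mobility and
  complexity, run lengths and peak structure, permutation entropy (order
  3), time-reversal asymmetry, autocorrelation at lags 1–30;
* *spectral*: distribution shape of the Hann periodogram (centroid, spread,
  skewness, kurtosis, slope, decrease, flatness, entropy, roll-offs),
  cumulative-energy frequencies, 10 relative band energies, the first 24
  FFT magnitudes, 4 multiscale (moving-average residual) detail energies,
  and the human-range energy ratio (0.6–2.5 Hz band over total; zero when
  the band lies above Nyquist, as it does for 1-s windows).

Degenerate-input conventions: a constant series has entropy 0,
autocorrelation 1 at all lags, and all spectral-distribution features 0.
Extraction is bit-reproducible and raises on any non-finite value rather
than silently imputing.

The catalog is defined by this package: the count is pinned at 210 and the
named exemplar features (kurtosis, mean, median, ECDF, human-range energy,
variability, peak-to-peak) are included, but the exact membership is a
design choice, since no canonical 210-feature list exists.

## Feature selection

One-way ANOVA F (two classes; +inf sentinel when within-group variance is
zero with distinct means) ranks features, ties broken by catalog order.
The halving search evaluates mean Monte-Carlo accuracy at 210, 105, 52, 26,
13 and 7 features (integer halving with a floor of 7) and stops at the
first count whose accuracy drops; the previous count is `k_opt`. Ranking is
computed once on the full table (the selection protocol of the study
design); per-split normalization still happens inside each training fold.
The scoring learner is fixed to logistic regression for determinism. The
greedy Pearson prune scans the selected set in descending-F order and drops
any feature with |r| > 0.5 against an already-retained one.

## Copula augmentation and quality scores

The synthesizer is a Gaussian copula with empirical marginals, fitted per
task-load condition on at least 10 rows: normal scores via mid-ranks →
correlation matrix (eigenvalue-clipped to PSD, unit diagonal), sampling via
Cholesky → Φ → inverse empirical CDF, so synthetic values never leave the
observed range. Synthetic subjects receive fresh negative ids (no collision
with originals in subject-grouped splits) and a label drawn from the
condition's empirical label distribution.

Quality scores map raw quantities to percentages linearly, pinned by their
endpoint cases (identical tables → 100, maximal divergence → 0):

* field correlation stability = 100·(1 − mean |Δr| / 2) over feature pairs
  (2 is the largest possible correlation difference); pairs involving a
  constant column contribute 0;
* deep structure stability: PCA on the standardized original (components
  covering ≥ 95% variance, capped at 5), both tables projected, per-
  component 20-bin base-2 JSD, score 100·(1 − mean);
* field distribution stability: per-column base-2 JSD on 20 shared
  equal-width bins spanning the pooled range, zero-count bins smoothed
  with 1e-12, score 100·(1 − mean).

The Jensen–Shannon divergence uses the standard equal-weight mixture form
H(M) − ½H(O) − ½H(S), which is bounded in [0, 1] bits. The overall score is
the exact arithmetic mean of the three, graded Very Poor / Poor / Moderate
/ Good / Excellent on 20-point bins. When one score per index is needed the
two conditions' tables are pooled (96 original vs 180 synthetic rows) and
scored as one pair.

With 48–96 original rows in 20 bins, the sampled JSD of two *identical*
distributions is noticeably positive (multinomial noise of order
(bins−1)/n), so distribution-stability scores saturate in the low-to-mid
90s rather than at 100; this is a property of the estimator at cohort
size, not of the synthesizer.

## Classification protocol

Ratings 1–4 → "suboptimal", 6–9 → "superoptimal", 5 discarded; the
positive class is "superoptimal". Instances are one row per (subject,
condition). Splits are random 70/30 at the *subject* level (a subject's
rows never straddle the boundary), stratified on each subject's label
profile, 100 iterations. Features are z-scored with training-fold mean and
population SD only; zero-variance features map to 0. Learners: logistic
regression (liblinear, C = 1), linear-kernel SVM (C = 1), Gini decision
tree (unlimited depth); hyperparameters are the library defaults of that
family since none are prescribed by the protocol. Metrics use the standard
confusion-matrix formulas with zero-denominator cases mapped to 0 and
logged; recall is tp/(tp+fn). Pairwise index comparisons use the pooled
two-sample two-tailed t-test (Welch available as an option), samples
treated as independent, Bonferroni correction by multiplication within
each contrast family, significance reported at α = 0.05 raw and 0.005
corrected.

## Problem sizes used by the test suite

Unit tests run on 4–20 subject cohorts of 15–60 s recordings. The
discrimination simulation uses ten 48-subject, 150-s cohorts with the
default task effects, artifact-free (`blink_rate_hz=0`) and without ICA —
artifact removal is exercised by its own injected-blink benchmark, and
omitting it keeps the band-power property isolated from ICA variability.
The synthetic-quality computation (also run by `scripts/acceptance.py`)
uses the full default cohort: 48 subjects, blinks at 0.1 Hz, complete
denoising, all ten indexes, 180 synthetic subjects.

## Known limitations

* The generator's independence assumptions (channels, windows) make the
  copula's job easier than real feature tables would; quality scores here
  upper-bound what heavier-tailed, more dependent real data would achieve.
* The ±3 z-score screen has a nonzero false-positive rate by construction;
  no manual component review exists.
* The halving search ranks features on the full table before Monte-Carlo
  scoring; selection is therefore mildly optimistic, as in the original
  protocol.
* t-test samples across the 100 iterations are correlated between learners
  and indexes (shared splits), so raw p-values are anti-conservative; the
  Bonferroni correction is applied to them unchanged.
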