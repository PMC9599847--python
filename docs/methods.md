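# Methods

## Problem setting

A contact-free vibration sensor pointed at the chest wall records a
single-channel signal containing heart sounds, respiration-driven
motion, and — in a congested lung — additional low-frequency energy and
crackle-like transients tied to the inhale phase. The package turns such
recordings into a 0–1 congestion score and evaluates the score as a
diagnostic test. Because no public recordings of this kind exist, the
package ships a generative signal model so every stage can be exercised
and validated end to end on synthetic cohorts.

## Signal model (`lungvib.cohort`)

A measurement of duration `T` (default 120 s, a two-minute spot check)
sampled at `fs` (default 500 Hz) is

```
x(t) = h(t)·(1 + m·r(t)) + g·r(t) + c(t) + u(t) + v(t) + ε(t)
```

* **Heart-sound train `h(t)`** — beats advance by RR = 60/HR with
  Gaussian beat-to-beat jitter (HR 70 ± 3 bpm by default, RR clipped to
  [0.3 s, 2 s]). Each beat places two Gabor wavelets
  `a·exp(−τ²/2σ²)·sin(2πf τ)` with σ = 8 ms (≈40 ms support): S1 at the
  beat onset (25 Hz, amplitude 1 — the reference scale) and S2 a
  fraction `systole_fraction` = 0.35 of that beat's RR later (45 Hz,
  amplitude 0.6). `fs > 4·max(f_S1, f_S2)` is enforced.
* **Respiration `r(t)`** — a piecewise-sinusoidal cycle of period
  60/resp_rate (15 breaths/min default) rising from −1 to +1 over the
  inhale segment (`inhale_fraction` = 0.4 of the cycle) and falling
  back over the exhale segment. It modulates heart-sound amplitude
  (depth m = 0.25) and leaks into the channel directly (gain g = 0.5).
* **Congestion `c(t)`** (cases only) — band-limited Gaussian noise
  (default band 2–4 Hz), unit-RMS normalized, gated by a smoothed
  inhale-interval mask and scaled to RMS
  `congestion_effect × 0.05`, plus Poisson-placed 10–20 ms damped
  50 Hz crackle transients (≈2 per inhale) at 1.5× that amplitude.
  How congestion manifests in a chest vibration signal is not publicly
  documented; this inhale-phase band-energy/crackle signature is an
  explicit modeling assumption and every part of it is configurable.
* **Murmur `u(t)`** — systolic 100–200 Hz band noise (RMS 0.1) for
  subjects with a valvular disorder; **wheeze `v(t)`** — a narrowband
  150 Hz tone (amplitude 0.1) gated to exhale intervals for subjects
  with a respiratory condition. Both are deliberately placed above the
  0.5–64 Hz feature grid: they make detection harder without making
  comorbidity a shortcut label proxy.
* **Noise ε(t)** — white Gaussian, SD 0.05.

The effect-size scale is worth stating: `congestion_effect` multiplies a
base RMS equal to the white-noise SD, but the signature is concentrated
in a 2 Hz band where the white-noise floor is ~10⁻⁵ units²/Hz, so even
effects well below 1 are detectable in principle; the default planted
effect 3 models gross congestion and is recovered essentially perfectly.

**Covariates.** By default every covariate (age 68 ± 14, BMI 28 ± 6,
65% male, 68% HF history, 15% respiratory condition, 40% valvular
disorder) has the same distribution in cases and controls, so that with
`congestion_effect = 0` the case and control signal distributions are
exactly identical and null checks are exact.
`CovariateConfig.clinic_shifted()` provides a heart-failure-cohort-like
imbalance (cases older, more comorbid). With shifted covariates,
comorbidity acoustics (murmur/wheeze) genuinely carry label information
even without congestion — a realistic confounding structure that the
null-behaviour tests deliberately avoid.

**Reproducibility.** Each measurement draws from its own RNG stream
derived by SHA-256 from (seed, subject id, measurement id), so cohorts
are bit-reproducible and any single measurement can be regenerated in
isolation.

## Landmarks (`lungvib.landmarks`)

Measurements are split into overlapping buffers (60 s windows, 30 s
step; the last window is the final full-length one). Heart sounds are
found on the 15 Hz high-passed signal: the envelope (magnitude of the
analytic signal, 20 ms moving average) is thresholded at 3× its median —
an adaptive floor invariant to recording gain — with a 200 ms refractory
separation (max plausible HR 180 bpm); peaks are paired into (S1, S2) by
the alternating-interval rule (the parity whose outgoing gaps are
shorter opens systole). Respiratory phases come from the 1 Hz low-passed
wave: trough→peak spans are inhales, peak→trough exhales, extrema
requiring 10% of the wave's range in prominence and ≥1 s separation.
All filters are 4th-order Butterworth applied forward–backward
(zero-phase), so landmark times are not lag-shifted. A buffer with
fewer than 4 envelope peaks or no respiratory extrema is flagged low
quality and dropped from feature extraction (logged, not an error) —
the software analogue of an unusable measurement. The spectrogram is a
one-sided Hann-window short-time PSD (2 s window, 75% overlap).

The filter families, cutoffs, buffer overlap, envelope construction,
thresholds and the pairing rule are all package decisions, exposed in
`PipelineConfig`.

## Features (`lungvib.features`)

Per buffer: 15 time features (mean/SD of RR, S1→S2 and S2→next-S1
intervals, RR coefficient of variation, bpm, envelope amplitudes at S1
and S2, S2/S1 amplitude ratio, breaths/min, inhale/exhale duration
ratio — the SD of a single observation is defined as 0 so vectors stay
complete) and 28 frequency features: mean spectral power in each of 7
octave bands (0.5–64 Hz) × 3 phases (inhale, exhale, full) plus a
per-band inhale/exhale energy ratio. The proprietary system reportedly
computes thousands of features and selects a few tens; this package
reproduces the construction rule with ~43 well-defined features rather
than the (unpublished) exact list. Per-measurement vectors are the mean
over quality-passing buffers (median available by config). Missing
cells (a phase with no spectrogram frames) are NaN and are imputed with
training-fold column medians inside cross-validation — imputation never
alters observed values and never sees held-out data.

## Classifier (`lungvib.boost`)

Classic discrete AdaBoost with decision stumps, used both as feature
selector and classifier (the source pipeline is vague about whether a
second-stage model consumes the boosted selection; a single model avoids
an unspecified stage). Stump search is exhaustive over features ×
midpoint thresholds × polarities; ties break toward the lower feature
index, then the lower threshold. Rounds stop early at ε_t ≥ 0.5, or
after a perfectly separating stump (ε capped at 10⁻¹⁰ so α stays
finite). T = 50 rounds by default, which selects "a few tens" of unique
features. The score is (margin+1)/2 with margin = Σα_t h_t / Σα_t ∈
[−1, 1].

The operating threshold θ maximizes balanced accuracy over midpoints of
adjacent sorted unique scores plus {0, 1}; ties go to the θ closest to
0.5. The inconclusive zone (θ−w, θ+w) takes the largest half-width
w ∈ {0, 0.005, …, 0.25} such that (a) at most `max_na_frac` (default
5%) of calibration scores fall strictly inside and (b) balanced
accuracy on the conclusive calibration scores is no worse than with no
zone; w = 0 always qualifies, and centering on θ keeps the zone
meaningful under class imbalance. Boundary convention: score ≥ θ is a
case call; the zone is an open interval.

## Evaluation (`lungvib.evaluate`)

Cross-validation is grouped by subject: subjects are shuffled by seed
and dealt round-robin into k = 10 folds (sizes differ by ≤1; 227
subjects yield seven folds of 23 and three of 22), and every
measurement inherits its subject's fold. Within each training split the
pipeline re-runs imputation, boosting, θ selection and NA calibration;
the held-out fold is scored exactly once. ROC points are taken at every
distinct score threshold and the trapezoid AUC equals the Mann–Whitney
U probability to machine precision (ties counted ½).

The metric panel: Se, Sp, balanced accuracy, PPV/NPV from raw counts at
the sample prevalence (algebraically identical to the Bayes identity
evaluated at p̂), PPV/NPV at an external prevalence (default 32%, a
routine HF-follow-up population) via Bayes' identity, PLR = Se/(1−Sp)
(reported as +∞ when Sp = 1) and NLR = (1−Se)/Sp. Inconclusive outputs
are either excluded from the counts (default, tracked separately) or
charged against their true class (`count_as_error`: an inconclusive
case is a false negative, an inconclusive control a false positive —
the reading consistent with specificity dropping when NAs are
included). Confidence intervals are 95% percentile bootstrap over 1000
resamples of *subjects* (all measurements of a subject travel
together, respecting the repeated-measurement clustering; resampling
individual measurements would understate the variance).

The duration sweep crops every measurement to its first d seconds for
d = 30, 35, …, 120 (19 runs), adapts the buffer length to min(60 s, d),
and repeats the whole cross-validated evaluation per duration with the
operating point re-selected each time.

The covariate screen marks conclusive predictions correct or
misclassified and tests each covariate for association with
misclassification: Fisher's exact test (p summing hypergeometric
probabilities of all tables no more probable than the observed one) for
binary covariates, the two-sample Kolmogorov–Smirnov test for
continuous ones, with D exact over the pooled order statistics and the
p-value from the asymptotic Kolmogorov distribution at effective
n = n₁n₂/(n₁+n₂) (exact small-sample KS p-values are out of scope). No
multiple-testing correction is applied, matching the original analysis
protocol. Constant covariates and error-free runs yield explicit
not-computable rows.

## What the synthetic cohorts do and do not show

The generator reproduces the *structure* the pipeline relies on —
quasi-periodic S1/S2, respiratory amplitude modulation and phase
asymmetry, an inhale-locked congestion signature, comorbidity
nuisances, repeated measurements, white noise. It does not reproduce
optical speckle physics, sensor dropouts, motion artifacts, arrhythmia,
or the true (unknown) acoustic signature of congestion. Passing the
planted-effect and null tests therefore demonstrates that the
implementation is correct and leak-free (signal in ⇒ signal out; no
signal in ⇒ chance-level out), not that the method achieves any
particular accuracy on real patients.

## Numerical and testing choices

* Problem sizes used by the test suite and acceptance run: 100 subjects
  (planted effect 3) for recovery and NA-budget checks, 60 subjects for
  the null band [0.35, 0.65] (≈2 binomial SDs at that n), a 16-subject
  cohort for the duration-sweep structure; bootstrap resamples are
  reduced (50–200) in tests where only determinism or bracketing is
  asserted.
* Oracle tests compare Fisher p-values against full hypergeometric
  enumeration and KS D against a brute-force ECDF scan for all n ≤ 12,
  stump fits against exhaustive candidate enumeration, and AUC against
  the Mann–Whitney statistic to 1e-12; boosting is cross-checked
  round-by-round against scikit-learn's SAMME AdaBoost (α_t equal up to
  the SAMME factor 2) — scikit-learn is a test-time reference only,
  never the implementation.
* The exact symmetric 4-point XOR square is indecisive for midpoint
  stumps (every stump has weighted error exactly 0.5), so the boosting
  test uses a fixed jittered square that both this implementation and
  the reference drive to zero training error within 8 rounds.
* Two-sample band-energy equality for stationary noise is asserted at
  300 s of signal, where the 20% tolerance corresponds to ≈2 SDs of the
  frame-sampling variance; at 60 s the per-band variance alone exceeds
  the tolerance.
* Per-feature null behaviour is asserted via marginal calibration
  (Bonferroni min-p, bounded rejection fraction) rather than a
  uniformity test of the p-value distribution, because features are
  mutually correlated and their p-values are not independent draws.

## Known limitations

* The congestion signature is an assumption; real congestion may
  manifest elsewhere in time–frequency space, and the default band
  (2–4 Hz) should be treated as a tunable hypothesis.
* The KS p-value is asymptotic; for very small groups the covariate
  screen is conservative/approximate where an exact test would not be.
* S1/S2 pairing assumes systole is shorter than diastole (true below
  ~180 bpm) and a broadly regular rhythm; atrial fibrillation-like
  rhythms would degrade the parity rule.
* The NA zone is calibrated on training folds; its held-out NA fraction
  is only stochastically bounded by the budget (it holds with margin in
  all seeded runs here).
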