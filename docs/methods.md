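# Methods

## Signal model and the SSNR decomposition

A continuous run is a channels × samples matrix `X` with labelled stimulus
onsets.  The package models it as the superposition of a response evoked
only by targets, a response common to every stimulus, and noise:

    Xᵀ ≈ D₁ A₁ + D₂ A₂

`D₁` (samples × L) carries a 1 at row `onset + j` in column `j` for every
*target* onset; `D₂` does the same for *all* onsets.  `L` is the assumed
response length, by default equal to the 1000 ms classification window.
Overlapping responses superpose linearly, which is exactly what the
least-squares fit assumes.  `A₁, A₂` (L × channels) are obtained from the
normal equations on the sparse joint design; because the fit is
column-separable in channels, a fitted model restricts to any channel
subset *exactly* by sub-selecting the cached Gram matrices
`G₁ = (D₁A₁)ᵀ(D₁A₁)` and `G_X = XXᵀ`.  Backward elimination exploits this:
one least-squares fit per run serves every candidate subset.

Identifiability: if a run contains only one stimulus class, the two
response blocks are collinear; the model then fits only the identifiable
block (targets-only → `D₁` alone, which for non-overlapping events equals
epoch averaging).  A rank-deficient joint design falls back to a
minimum-norm (SVD) solution with a logged warning; generalized
eigenproblems with a singular denominator get a ridge of
`1e-6 · trace/n` on the diagonal.

Per-sensor SSNR is `G₁[i,i] / G_X[i,i]`, clamped to [0, 1]; a filter `w`'s
SSNR is the same Rayleigh quotient `wᵀG₁w / wᵀG_Xw`.  xDAWN filters are the
generalized eigenvectors of `(G₁, G_X)` in descending eigenvalue order, so
the reported per-filter values *are* SSNRs and the first filter is globally
SSNR-optimal by construction.  On epoched data (inside the classification
chain) the target-average waveform replaces the least-squares ERP estimate.

CSP solves `(Σ_target, Σ_target + Σ_standard)`; filters are retained
alternately from the two eigenvalue extremes with relevance
`max(λ, 1−λ)`.  PCA uses the pooled channel covariance.

## Ranking criteria

All eight criteria sit behind one `Ranker` interface (`score(S)`, optional
`contributions(S)`) keyed by
`{xdawn, csp, pca, ssnr_s, ssnr_v, svm1, svm2, performance}`.
Following the processing conventions of ERP work, SSNR- and filter-based
criteria operate on low-pass-filtered signals of a single selection run;
SVM criteria train on slope features *without* a spatial filter, so each
weight maps to exactly one sensor; the performance criterion runs a 5-fold
cross-validation of the entire chain per candidate set.

The ranking SVMs use a fixed complexity (`ranking_svm_c = 0.1`, standardized
features, class weights `n_standard/n_target` on the target class): a full
grid search per candidate subset would multiply the cost of an already
expensive criterion without changing the weight *pattern* the ranking reads.

## Search

Generic recursive backward elimination scores every single-sensor removal
with a criterion refit on the candidate subset (ties: the lowest-index
sensor is removed; a failing candidate scores −∞ so the search stays
total).  The fast variant fits the criterion once per step and removes the
sensor with the smallest per-sensor contribution.

These two are provably identical for additive, refit-invariant criteria
(sensor-space SSNR) and for weight criteria under a *fixed* filter model.
For refitted filter/SVM weight criteria they are not: eigenvector banks
refitted on different candidate subsets carry non-comparable scales, so
per-candidate-refit scores are not meaningfully comparable across
candidates in the first place.  Removing the minimum-|weight| sensor under
the parent-set model is the well-defined (and efficient) reading of
weight-based elimination, and the evaluation harness therefore uses the
fast variant for weight criteria (`evaluation.FAST_METHODS`) and the
generic one for `ssnr_v` and `performance`.

`exhaustive_best` enumerates all subsets of a size (capped at 1e5
combinations) and serves as the small-instance oracle in tests.

## Classification chain

Per trial and channel: standardize over the 1000 ms post-stimulus window
(variance floor 1e-12, so flat channels map to zeros instead of NaN), then
zero-phase order-5 Butterworth low-pass at 4 Hz (applied forward-backward;
DC gain 1).  If the constellation has more than `k = 5` sensors, an xDAWN
bank fitted on the training split retains the 5 most relevant virtual
channels.  Features are least-squares slopes of 400 ms segments cut every
120 ms (6 per channel on a 1 s window), in amplitude per second so they are
sample-rate invariant.  Features are standardized with training-split
statistics only (leakage guard — test data never touches any fitted
statistic).  The classifier is a class-weighted linear SVM
(squared-hinge); its complexity is chosen from
`{1e-6 … 1e0}` by stratified 5-fold inner cross-validation on balanced
accuracy (ties to the smaller C).  All tunables live in `ChainConfig`.

Balanced accuracy `(TPR + TNR)/2` is the only performance measure: with
~6:1 standard:target ratios, raw accuracy would reward the trivial
all-standard predictor with ~0.86.

## Random-constellation model

Balanced accuracies of uniformly drawn size-m constellations are fitted by
maximum likelihood to Beta(α, β) (method-of-moments start values; ≥10
values required; exact 0/1 scores must be clamped to ±1e-6 explicitly by
the caller, since the likelihood diverges at the boundary).  The
exceedance `P(bACC ≥ q)` is the beta survival function; its reciprocal is
the expected number of random draws needed to match a score `q`, and
`1/C(n, m)` approximates the probability of drawing the unknown best
constellation.

## Synthetic data

The generator emulates the statistical structure selection methods rely
on, not the physiology.  Each run is white (optionally 1/f) Gaussian noise
per channel, plus two Gaussian-bump components added at stimulus onsets:
a class-shared negative "visual" deflection (peak −1 unit at 200 ms,
σ = 30 ms) loading on occipito-parietal labels, and a target-only positive
component (600 ms, σ = 80 ms) loading only on the configured informative
sensors.  Stimuli arrive every 1000 ± 100 ms (uniform jitter); targets are
rare (defaults 120 of 840 per run).  Session 2 loadings are session 1
loadings plus `N(0, 0.25²)` perturbations on every channel, standing in
for day-to-day changes in electrode position and impedance.  Subjects,
sessions and runs use independent seeded streams, so generation is
reproducible and order-independent.

What it deliberately does **not** emulate — and what passing tests
therefore do not show about real EEG: background noise is spatially
independent, so *sensor-space* criteria (per-sensor SSNR) and PCA perform
far better here than on real recordings, where volume conduction
correlates channels and high-variance artifact sources mislead PCA; there
are no eye/muscle artifacts, no drifts, no head-model mixing; component
waveforms are deterministic across trials.  Conclusions about the
*relative* failure modes of criteria on real data come from real data;
this generator validates the machinery (optimality, exactness, monotone
behaviour, transfer loss) under known ground truth.

## Benchmark conditions and problem sizes

`benchmarks.benchmark_config` fixes the default benchmark: actiCAP-32
montage, 10 centro-parietal informative sensors, 240 standards + 40
targets per run, 2 runs per session, `erp_amplitude = 0.5`,
`noise_sd = 1.0`.  The amplitude is calibrated to a *medium*-SNR regime:
the all-sensor chain scores ≈ 0.98 balanced accuracy while random
10-sensor constellations spread over ≈ 0.4–0.95 — the regime where
selection quality is visible at all (at ceiling every method ties; at
chance none can win).  `chance_config` is the negative control: 12
channels, `erp_amplitude = 0`, three runs.  Test and acceptance runs use a
few seeds (5 or 10) and these few-hundred-trial runs; they complete on one
CPU in minutes while leaving every algorithmic path identical to a
full-size study.

## Known limitations

* The 62-channel layout is a reconstruction of a standard 64-channel 10-10
  cap with TP7/TP8 removed; it is a plausible stand-in, not a copy of any
  specific recording setup.
* `rank_performance` inherits the chain's inner grid search, making
  performance-driven elimination by far the most expensive criterion
  (O(m²) chain cross-validations for a full elimination) — consistent with
  its role as the straightforward-but-costly baseline.
* The beta model is an assumption; it fits unimodal accuracy samples well
  but nothing enforces it for, e.g., strongly bimodal constellations.
* Exact-duplicate channels make the signal Gram singular; the automatic
  ridge keeps results finite and perturbs virtual-space scores by ~1e-6.
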