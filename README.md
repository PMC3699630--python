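# erpselect

EEG sensor (electrode) selection for event-related-potential (ERP) based
binary classification, in one unified framework: eight set-ranking criteria,
recursive backward elimination, random-constellation baselines modelled with
a beta distribution, and intra-/inter-session evaluation of the full
single-trial classification chain.

The practical problem: P300-style brain-computer interfaces detect rare
*target* stimuli among frequent *standards* from multichannel EEG, but a
full 62-channel cap makes preparation slow and intrusive.  Which small
subset of electrodes — a *sensor constellation* — keeps single-trial
detection performance, and how do you know a selection method is actually
better than guessing?  `erpselect` is for BCI/neurotech researchers who want
to compare selection criteria under controlled conditions; everything runs
on a bundled synthetic oddball-ERP generator with known informative sensors,
and the same API accepts any recording in the package's dataset-bundle
format.

## The methods

A ranking criterion assigns a real score `R(S)` to a sensor set `S`
(higher is better):

* **Spatial-filter weights** (`xdawn`, `csp`, `pca`):
  `R(S) = Σ_{i∈S} Σ_{j=1..k} |w_ij|`, the absolute filter coefficients of
  sensor `i` in the `k` most relevant filters fitted on `S`.
* **Sensor-space SSNR** (`ssnr_s`): the recording `X` is decomposed by least
  squares as `Xᵀ = D₁A₁ + D₂A₂ + N` — a target-only evoked response, a
  response common to every stimulus, and residual noise (`D₁`, `D₂` are
  shifted-onset indicator designs).  Each sensor's signal to
  signal-plus-noise ratio is `SSNR(i) = ‖D₁A₁e_i‖² / ‖Xᵀe_i‖²` and
  `R(S) = Σ_{i∈S} SSNR(i)`.
* **Virtual-space SSNR** (`ssnr_v`): `R(S) = Σ_{j=1..k} SSNR(x̂_j)` where
  `x̂_j = Xᵀw_j` are the first `k` virtual channels of an xDAWN filter bank
  fitted on the data projected onto `S`.  xDAWN filters are the stationary
  points of the SSNR ratio, solved here as the generalized symmetric
  eigenproblem on (ERP-component Gram, signal Gram); redundant sensors are
  pooled into shared virtual channels instead of being double-counted.
* **SVM coefficients** (`svm1`, `svm2`): a linear SVM with 1-norm or 2-norm
  weight regularization is trained on per-sensor slope features (no spatial
  filter), and `R(S) = Σ_{i∈S} Σ_{j=1..F} |w_ij|`.
* **Performance** (`performance`): mean balanced accuracy
  `bACC = (TPR + TNR)/2` of the full chain over a 5-fold cross-validation on
  the selection run.

The **search** is recursive backward elimination: starting from the full
set, score all single-sensor removals and keep the best subset, down to the
target size.  Criteria that are additive in per-sensor contributions support
a fast variant (one criterion fit per step).  An exhaustive search is
included as a small-instance oracle.

Selected constellations are judged by the **classification chain**
(standardize → 4 Hz low-pass → xDAWN retaining 5 virtual channels → segment
slopes as features → feature standardization → class-weighted linear SVM
with cross-validated complexity grid) and compared against **random
constellations**, whose balanced accuracies are modelled as
`bACC ~ Beta(α, β)`; `P(bACC ≥ q) = 1 − F_Beta(q; α, β)` gives the expected
number of random draws needed to match a selected constellation.
Evaluation is **intra-session** (select, train and test within one session)
or **inter-session** (constellations — not classifiers — transfer to a
different session of the same subject, with perturbed sensor loadings).

## Worked example

`examples/03_backward_elimination.py` selects sensors on one benchmark run
(32 channels, 10 informative, medium SNR) with the virtual-space SSNR
criterion and scores the result on a held-out run:

```
size  criterion  recovered  test bACC   selected sensors
  32     0.507     10/10   0.988     ...
  16     0.463     10/10   0.992     ...
  10     0.413      9/10   0.990     Cz,CP5,CP1,CP2,CP6,P7,P3,P4,P8,O2
   8     0.381      8/10   0.990     Cz,CP5,CP1,CP2,CP6,P3,P4,P8
```

The criterion column is `R(S)` (monotone in the set, so it shrinks as
sensors are removed); *recovered* counts how many of the 10 truly
informative sensors survive; test bACC is held-out balanced accuracy —
here selection reaches a quarter of the original cap without losing
performance.  `examples/04_random_baseline_beta.py` quantifies the benefit
against chance:

```
100 random 10-of-32 constellations: mean bACC 0.849, range [0.412, 0.944]
beta fit: alpha=23.8, beta=4.3 (mean 0.848)

selected constellation bACC: 0.973
P(random constellation >= that): 3.43e-03
expected random draws to match it: 292
```

The other examples cover simulation + bundle I/O (`01`), the SSNR
decomposition and xDAWN optimality (`02`), and intra- vs inter-session
transfer (`05`).

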