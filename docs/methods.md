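# Methods

This note records the models implemented in `bcibench`, the assumptions they
make, the defaults and why they were chosen, and what the synthetic-data
results do and do not demonstrate.

## Signal model and preprocessing

EEG is represented as a channels × samples matrix in microvolts with
0-based sample indexing. Epochs are half-open windows `[start, end)` in
samples around cue markers; seconds convert to samples by rounding half away
from zero. These conventions make epoch lengths unambiguous across sampling
rates and are applied uniformly (epoching, sliding windows, interval
accounting).

"Standardization" before CSP means per-trial, per-channel **mean removal
only** — no variance scaling — so that the variance of a band-pass-filtered
channel equals its band power, which is the quantity CSP is meant to
concentrate. Centering is idempotent and leaves channel covariances
unchanged (tested properties).

### Filter bank

Band-pass blocks are Butterworth filters of order 5 (maximally flat pass
band), applied forward–backward (`filtfilt`) because the framework is
offline: zero phase avoids group-delay misalignment between bands, at the
cost that the effective magnitude response is the squared single-pass
response. Edge transients are suppressed by odd-symmetric extension with pad
length 3·(2·order+1), truncated for short epochs — stated so results are
bit-reproducible. Defaults: the direct band-power path uses {8–12, 16–24} Hz
(the α and β rhythms that motor imagery desynchronizes); the Morlet path
uses a single broad 4–30 Hz pre-filter, a design choice (the wavelets
themselves are already narrow-band, the pre-filter only removes drift and
high-frequency noise).

### CSP

Class covariances are means of trace-normalized single-trial covariances
XXᵀ/tr(XXᵀ); trace normalization removes trial-to-trial amplitude scale.
The variance-ratio objective is solved by symmetric whitening of the
composite covariance Σ⁺+Σ⁻ followed by eigendecomposition of the whitened
Σ⁺, giving filters with w(Σ⁺+Σ⁻)wᵀ = 1 and wΣ⁺wᵀ = λ ∈ [0, 1]. Numerical
choices:

* ridge 1e-10·trace on the composite before whitening (zero-phase filtering
  of short epochs can leave it rank-deficient);
* filters sorted by descending λ, ties kept in stable eigen-index order;
* each filter's largest-magnitude coefficient is made positive
  (deterministic across LAPACK builds);
* filter selection keeps the n most extreme filters from *each* end
  (symmetric pairs); asymmetric or heuristic rankings are deliberately out
  of scope.

Multiclass uses one-against-others: one filter set per class (positive =
that class, negative = all other trials pooled trialwise), features
concatenated across sets.

### Features

Band power is the **time-averaged** sum of squared samples rather than the
raw sum, so candidate time segments of different lengths remain comparable
during model selection; the difference is a per-segment constant and does
not change any classifier's decision ordering. The BP family emits power and
log(power) per band per channel, with log(max(p, 1e-12)) guarding filtered
all-zero segments. The Morlet family uses unit-energy complex Morlet
wavelets, 7 cycles at every centre frequency, at 26 centre frequencies
4.5, 5.5, …, 29.5 Hz — the unique uniform 1-Hz tiling of 4–30 Hz producing
26 bands; power is the time-averaged squared magnitude of the convolution.
The 7-cycle width and time-averaging are defaults chosen here (a common
wavelet-analysis convention), and Morlet features are raw power by default
with a switch for logs.

## Classifiers

Seven probabilistic classifiers sit behind one train/predict-probability
contract guaranteeing sorted class order, rows-sum-to-one probabilities, and
determinism given (spec, seed, data). Established scikit-learn estimators
implement LDA, QDA (with 1e-6 diagonal shrinkage for singular per-class
covariances in high-dimensional Morlet spaces), elastic-net logistic
regression (the only consistent reading of "L1 and L2 jointly"; mixing ratio
on the grid), RBF-kernel SVM (one-against-one multiclass, Platt-calibrated
probabilities) and the tree ensembles. The MLP is implemented here as a
seeded single-hidden-layer softmax network trained by full-batch Adam on the
negative log-likelihood with both L1 and L2 penalties and early stopping on
a 10 % validation split (patience 25, ≤300 epochs), because that loss — with
an explicit L1 term — is part of the model's definition and is not offered
by the standard estimators.

Feature standardization (train-set mean/variance) is applied inside the
contract for the scale-sensitive learners (SVM, LR, MLP) and not for trees;
freezing train statistics prevents test-set leakage.

Hyperparameter **grids** are first-class data with a fixed axis schema per
classifier (the discriminant-analysis models have none). The numeric
candidate values shipped as defaults (e.g. C ∈ {0.1, 1, 10, 100}, γ ∈
{0.1, 1, 10}·(1/d)) are configuration conventions — log-spaced ranges a
practitioner would start from — and are fully overridable.

## Model selection and evaluation

The search enumerates the full Cartesian product of BCI parameters (time
segments and CSP pair counts for cued data; window length/overlap for
self-paced data) with each classifier grid, scoring by 5×5-fold stratified
cross-validation (accuracy or AUC). Band filtering and centering are
per-trial operations and are computed once per configuration; CSP, scaling
and the classifier are refit per training fold. Repeat r derives its fold
seed from (seed, r), so runs are bit-reproducible. Ties on mean CV score
break toward the earlier time segment, fewer CSP pairs, then
lexicographically smaller classifier parameters — a simplicity-first rule
adopted because nothing in the protocol dictates one.

Self-paced streams are cut into overlapping sliding windows; a window is
labelled *control* when ≥ 50 % of its samples lie inside a control interval
(a symmetric, threshold-free rule for boundary-straddling windows; how such
windows "should" be labelled is genuinely open). Training windows are drawn
with the same geometry so train and test distributions match. AUC gives tied
scores half credit (Mann–Whitney convention, matching AUC's probabilistic
definition); multiclass accuracy takes the argmax with ties to the earliest
sorted class.

Final testing refits the winning configuration on all training data and
scores an independent session once; identical train/test recordings (by
identity, shared id, or equal signal arrays) raise a leakage error.

## Statistics layer

Ranks are computed per subject (1 = best, ties averaged), so the analysis
depends only on within-subject orderings and is invariant to any
subject-wise monotone transform of the scores. The Friedman statistic is the
**classic** χ² form without tie correction; the bundled benchmark tables
reproduce their published Friedman p-values under this form, and
`scipy.stats.friedmanchisquare` (which applies tie correction) serves as an
independent cross-check on tie-free tables in the tests. Holm comparisons
use raw two-sided normal p-values of z = (Rⱼ − R_ctrl)/√(k(k+1)/(6N)),
sorted ascending against thresholds α/(k−1), …, α, with rejection stopping
at the first retention. The default α = 0.1 matches the published
comparison's choice.

Reporting truncates (not rounds) average ranks to 2 decimals and p-values to
4 decimals — the convention under which the bundled tables' published
summaries are recovered exactly — while the API returns full precision.

One known inconsistency in the reference material: recomputing the
self-paced BP ranks gives SVM 5.8125 and BST 5.5, the mirror of the
published summary's SVM(5.5)/BST(5.81), while the published pairwise
p-values agree with the recomputation. The discrepancy is in the source's
summary table, not resolvable here; those two cells are therefore not part
of the validated surface.

## Synthetic data

The generator emulates the one property of motor-imagery EEG the pipeline
exists to exploit: class-dependent band-power modulation (ERD/ERS). Sources
are **band-limited Gaussian noise** (unit RMS per segment), not pure tones —
pure tones would make CSP trivially rank-1 — mixed linearly into channels by
a full-column-rank matrix, with white Gaussian sensor noise added.
Modulation multiplies source *power* (amplitude × √factor), since ERD is
defined on power. Defaults model a plausible small montage: 8 channels,
250 Hz, α (8–12 Hz) and β (16–24 Hz) sources of unit amplitude, 100 trials
per class of 4 s with 1 s inter-trial baseline, α-power factor 0.3 for one
class (strong ERD), sensor noise 0.5 µV. Self-paced streams alternate
No-Control and control stretches with lengths uniform on 1.5–8 s (the range
motor-imagery evaluation intervals span in self-paced recordings); the final
stretch is truncated for exact sample accounting and relabelled No-Control
if a truncated control stretch would fall below the minimum.

Randomness splits one integer seed into per-segment streams keyed by
(purpose, session, segment, source), so raising the trial count extends a
recording without reshuffling earlier trials, and the class order is
shuffled block-wise (one trial per class per block) to keep classes exactly
balanced under that scheme. The `session` field exists because a subject's
spatial mixing is a property of the head, not of the recording day: train
and test sessions share the seed-derived mixing matrix while drawing
independent noise, which is what makes cross-session transfer a meaningful
test.

**What passing tests show — and don't.** Recovery of the planted ERD through
filterbank → CSP → band power → classifier demonstrates that the chain is
wired correctly, leak-free, and sensitive at realistic SNR. It does not
demonstrate performance on real EEG: the generator has no 1/f background,
no artifacts (EOG/EMG), no non-stationarity or session drift, no volume-
conduction head model, and its sources are exactly band-limited. Absolute
accuracies on synthetic data are therefore not comparable to accuracies on
recorded datasets.

## Problem sizes used in validation

The acceptance checks run the statistics layer on the full bundled tables
(21 × 7 and 8 × 7), the CSP oracle on 2–5-channel covariance pairs against
1e5 random directions with a Nelder-Mead polish, the AUC oracle on 100
random sets of up to 2000 scores, pipeline recovery at the generator's
default scale (100 trials/class, 8 channels, 250 Hz; 480 s self-paced
streams), and Friedman calibration on 2000 simulated null tables of 10
subjects × 5 classifiers — sizes chosen so the whole suite completes in
well under a minute of compute per check while keeping sampling error
far from the asserted bounds.

## Known limitations

* Readers for native BCI-competition formats (GDF/MAT dialects) are out of
  scope; recordings enter via the HDF5 container or the generator.
* No online/causal operation: all filtering is zero-phase offline.
* No regularized/shrinkage CSP variants or mutual-information filter
  selection; no nested CV (the protocol uses a single train/test split).
* The Iman–Davenport F transform, Nemenyi test and critical-difference
  diagrams are not implemented.
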