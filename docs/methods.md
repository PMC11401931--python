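# Methods

This note documents the models and procedures implemented in `laminardyn`,
the choices made where the design was genuinely open, and what the synthetic
validation does — and does not — establish about real data.

## Task and design model

The package analyzes a delayed match-to-sample working-memory session with
two run types: *load* runs (high = 4 items vs. low = 1 item) and *motor*
runs (respond vs. abstain at the probe). A trial is a fixed 30.7 s clock —
sample 3.5 s + 0.2 s mask, delay 13 s, probe/response 4.2 s, inter-trial
interval 10 s — with 16 trials per run at TR = 2 s. A run lasts 504 s; the
12.8 s remainder is modelled as a lead-in before the first trial
(`DesignSpec.lead_in_s`, configurable, since the placement of the slack is
not determined by the trial arithmetic). Because 30.7 s is not a TR
multiple, onsets are deliberately not TR-locked. Condition sequences are
counterbalanced (8 + 8) and pseudorandomized with at most 3 consecutive
same-type trials, generated by a constrained sequential sampler (uniform
over feasible continuations, not uniform over all valid sequences — a run
is never rejected, so pathological constraint settings fail fast with a
clear error).

One consequence of the lead-in choice: the last trial of each run ends
exactly at the run boundary, so its 17-TR decoding epoch overruns the run
and is dropped during epoching. Decoding therefore uses 15 + 16 = 31 trials
per run-type pair.

## Synthetic laminar BOLD generator

Signal for voxel v in layer L at scan time t:

    s_v(t) = Σ_trials Σ_periods A(L, c, p) · m_v(L, c, p) · (box_p * h)(t)

where `box_p` is the period boxcar on the task clock (encoding [0, 3.7) s,
delay [3.7, 16.7) s, retrieval [16.7, 20.9) s post onset), `h` the canonical
double-gamma HRF (peak 6 s, undershoot 16 s, peak:undershoot 6, unit peak),
and each period regressor is scaled so a single trial's response peaks at 1
— injected amplitudes are per-trial peak percent signal change (PSC),
directly comparable to FIR estimates. `m_v` is 1 for the univariate
amplitude component and a unit-norm random pattern scaled by √n for the
multivariate component, so pattern amplitudes are per-voxel RMS PSC. In
*stable* mode a condition keeps one pattern across periods; in *dynamic*
mode each period draws its own pattern, resampled until all within-layer
pairwise |cos| < 0.3.

The draining-vein confound is a single linear leakage term: superficial
signal += λ · deep signal (before noise), λ ∈ [0, 1).

Noise is AR(1) per voxel (marginal SD σ = 1 PSC, ρ = 0.3 by default) plus
random polynomial drift (orders 1–3, coefficient SD 1 PSC) on a baseline of
100, so raw units equal PSC. Cohorts add multiplicative per-subject effect
gain (SD 0.25) to model between-participant variability. Defaults were
chosen once to match the scale of the study being emulated: univariate load
effects of 0.1–0.2 PSC and group decoding accuracies peaking around
0.6–0.75. Layers are disjoint voxel blocks (200/layer by default, 9
subjects); the middle layer exists but carries no analyzed signal.

What the generator does **not** emulate: spatial autocorrelation and
partial-volume mixing beyond λ, vascular physiology, motion, distortion,
behavioural-performance coupling to BOLD, and realistic ROI geometry.
Passing recovery tests therefore shows the *analysis chain* is correct and
calibrated under its own assumptions — not that those assumptions hold in
real laminar data.

## Layer binning

Depths (0 = white-matter surface, 1 = pial) are binned equidistantly:
bin k covers [k/3, (k+1)/3), top bin closed at 1 (a deterministic
tie-break the convention leaves open). Only deep and superficial bins are
analyzed; middle is a partial-volume buffer. The upsampling factor used to
produce depth maps is recorded as metadata only — depths are inputs here.
Layer comparability across subjects is checked with a two-tailed paired t
on deep vs. superficial voxel counts per ROI.

## FIR trial timecourses

Condition timecourses are estimated by ordinary least squares on
concatenated runs with (a) one tent basis per condition — 17 knots over
32 s at 2 s spacing, first and last knots fixed to zero (15 free
regressors), events pooled across runs, fractional loading for off-grid
onsets — and (b) per-run polynomial nuisance blocks up to order 5.
The nuisance polynomials are discretely orthogonalized on the scan grid
(QR of the Legendre Vandermonde, constant column kept as exact ones):
sampled Legendre polynomials are not orthogonal on a finite grid, and exact
orthogonality makes the constant predictor cleanly interpretable as the run
baseline. PSC conversion is 100·β/baseline per voxel; non-positive
baselines exclude the voxel with a log entry. No prewhitening is applied —
noise autocorrelation enters inference only through the permutation
machinery. A rank-deficient design (e.g. two conditions with identical
event trains) raises an error naming the aliased regressors.

## Univariate period statistics

Effects are condition contrasts of layer-mean timecourses (high − low;
response − abstain), averaged over hemodynamically shifted windows: delay
11.3–15.1 s and retrieval 20.7–24.5 s post onset, both *closed* intervals on
the knot grid (capturing knots {12, 14} and {22, 24} s — closed-interval
membership is our convention; the alternative half-open reading would drop
no knots here but is not what "time points associated with the period"
suggests). Layer comparisons use classical two-tailed paired t-tests with
95% CI on the PSC-difference scale and paired Cohen's d = t/√n. No
correction across the two periods is applied, matching the reporting
convention of the results being reproduced.

## Decoding

Per run: third-order Butterworth high-pass (cutoff 1/128 s⁻¹, zero-phase
`sosfiltfilt`; the filter family and cutoff are free choices here — this is
the common fMRI default and both are configurable), then per-voxel temporal
z-scoring.
Trials are 17-TR epochs starting at floor(onset/TR); adjacent TRs are then
averaged in a moving-average manner (timepoint labelled by the later TR,
leaving 16 decoding timepoints at 2–32 s). Trial normalization is a spatial
z-score per trial-timepoint — the operationalization of "removing overall
activation differences"; it makes the features invariant to any per-trial
affine gain/offset of a spatially uniform component.

Cross-validation folds balance the four trial-transition subtypes
(current × previous condition): n_folds = 4 × min subtype count; each fold
trains on an equal random draw per subtype (one fewer than the scarcest
count, so the scarcest subtype always contributes a test trial) and tests
on all held-out trials. The first trial of a run takes its previous-trial
label from the last trial of the preceding run of the same type; if there
is none it can be tested on but never trained on. Fold compositions are
pairwise distinct (bounded retries).

The classifier is a linear SVM with cost 1 (libsvm via scikit-learn).
Feature z-scoring is fit on the training set and — independently — within
the test set. A decision value of exactly 0 predicts the lexicographically
lower class (deterministic tie-break). Cross-decoding fits one classifier
per training timepoint per fold and evaluates it at every test timepoint;
the matrix diagonal equals the plain decoding timecourse under the same
folds by construction, and train/test trials never overlap at any element.

## Permutation inference

*Subject level*: 250 label permutations by default, shuffling training
labels within each fold's training set (test labels intact), rerunning the
identical procedure.

*Population level*: 10,000 draws; each draw samples one value per subject
and computes a one-sample t vs. chance (or a paired t between layers). The
phrase "average resulting in a mean t-value" is ambiguous; we implement it
as a t statistic across the per-subject draws, which is the reading that
yields a well-defined null of the group statistic.

*1-D cluster test*: pointwise t thresholded at the pointwise permutation
p < 0.05 (same tail), maximal contiguous same-sign runs, summed t compared
to the null's maximum cluster summed t; p = (1 + #{null ≥ obs})/(1 + n).
Cluster-level effect size is the mean of t/√n over cluster elements.

*2-D cluster test*: element-wise t vs. chance; sign-flip null (each
subject's centered matrix × ±1); 4-connected clusters (edges, not corners —
the conservative adjacency). The cluster-forming threshold is the pointwise
quantile computed over the observed *and* permuted maps jointly: computing
it from permuted maps alone breaks the exchangeability of observed and
permuted max-cluster statistics and measurably inflates the type-I error
when accuracies are discrete fold averages (0.07–0.08 at nominal 0.05 in
our calibration runs; 0.05–0.06 with the symmetric threshold).

*Dynamic elements*: one-tailed "lower" cluster tests on a_ij − a_ii and on
a_ij − a_jj; an off-diagonal element is dynamic only if it sits in
significant clusters of *both* tests and both diagonal partners lie inside
above-chance clusters.

*Interaction test*: two-way fully-within-subject ANOVA (3 task periods ×
2 layers) on period-averaged decoding accuracies; F for the interaction
from the standard decomposition with the subject × period × layer residual
as error; η² = SS_int/(SS_int + SS_err) (partial). The permutation scheme —
unstated in the convention being followed — exchanges the six cell labels
within each subject, which is exact under the null of full cell
exchangeability; 10,000 permutations.

All permutation p-values use the add-one rule; all RNG flows from a single
seed through `numpy.random.SeedSequence` spawning, making every result
bit-reproducible.

## Calibration and recovery suites

`laminardyn.evaluation` runs the acceptance-grade suites:

- **Type-I calibration** (200 null cohorts, reduced to 100 subject-level
  samples and 1,000 draws/permutations for confidence-interval speed): null
  cohorts are generated at the *statistic level* — per-subject accuracies
  and their subject-level null distributions are draws from the same
  binomial chance process, which is exactly the exchangeability the
  inference machinery assumes. Re-running 200 × 9 full decoding pipelines
  with 100 label permutations each would measure the same property at ~200×
  the cost; the decoding stage's own chance behaviour is verified separately
  by label-shuffle tests at the decoding level.
- **Univariate recovery**: superficial-only delay amplitude of 0.2 PSC;
  fraction of 50 cohorts with a significant layer difference via the full
  FIR → PSC → period-average → paired-t path.
- **Dynamic/stable recovery**: pattern amplitude 0.45 PSC RMS (group peak
  accuracy ≈ 0.9 — clearly high SNR without the accuracy ceiling that makes
  lower-than-diagonal comparisons degenerate), 40 voxels/layer, 1,000
  permutations; fraction of 50 cohorts with a dynamic element at
  between-period intersections (dynamic patterns) or with any dynamic
  element (stable patterns).

Problem sizes (40 voxels/layer for decoding suites, 9 subjects, reduced
permutation counts) are the package's Monte-Carlo defaults; the statistical
code paths are identical at full size.

## Known limitations

- The generator's layers are statistically independent voxel blocks; real
  laminar GE-BOLD has depth-dependent SNR, spatial smoothing and vascular
  structure that only the λ-leakage term gestures at.
- Trial normalization removes uniform gain/offset differences exactly, but
  a *patterned* signal whose amplitude differs between classes remains
  partially decodable after normalization — an inherent property of the
  method, not an implementation artifact.
- The temporal cluster test inherits the usual caveat that cluster
  membership is not pointwise inference: significance statements apply to
  clusters, not to individual timepoints.
- **The dynamic-coding conjunction is susceptible to trial carry-over.**
  With 30.7 s trials and 32 s epochs, epoch-edge timepoints contain a
  mixture of the neighbouring trial's pattern and weak current-trial
  signal. At high SNR those edges reach above-chance clusters, and
  cross-elements between edges and mid-trial timepoints are then reliably
  below both diagonals — so the conjunction flags "dynamic" elements even
  when the injected code is period-stable (the stable-pattern recovery
  suite measures this false-positive cohort rate; it falls to near the
  nominal level once trials are separated enough to remove the epoch
  overlap, e.g. ``DesignSpec(trial_duration_s=44.7, iti_s=24)``). Dynamic
  clusters that touch the first or last couple of decoding timepoints
  should therefore be interpreted with caution in designs with contiguous
  trials.
- With 9 subjects a sign-flip null has 512 distinct values; permutation
  p-values below ~0.002 are not attainable and ties are resolved
  conservatively by the add-one rule.
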