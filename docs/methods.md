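# Methods

`fusemri` implements a multi-modal MRI classification pipeline for major
depressive disorder (MDD): distinguishing patients from healthy controls
(*diagnosis*) and predicting whether a patient reaches a positive
6-month outcome (*outcome prediction*), from tabular per-subject feature
sets.  Because clinical MRI cohorts of this kind cannot be redistributed,
the package ships a synthetic-cohort generator that reproduces the
statistical structure the analysis assumes, and every claim the test
suite makes is a property of the pipeline established on such cohorts.

## Outcome definition

Depression severity is measured with the 17-item Hamilton Depression
Rating Scale (HDRS, integer range 0–52).  For a patient with baseline
score `b > 0` and follow-up score `f`, the relative improvement is
`(b − f) / b`; a reduction of at least 50 % (boundary inclusive) labels
the subject PO (positive outcome), otherwise NO.  Subjects without a
follow-up assessment are dropped from outcome analyses (complete-case).

## Feature sets

Eleven feature sets per subject, consumed as numeric tables:

| set | elements | content |
|---|---|---|
| T1 | 113 | subcortical volumes + cortical thickness |
| T2 | 66 | hippocampal subfield + amygdalar nuclei volumes |
| MD, FA, AD, RD, sSW | 5 × 3486 | white-matter edge metrics over C(84,2) region pairs |
| Act | 22 | task-activation contrasts, 11 ROIs × 2 contrasts |
| sFC | 105 | static network correlations over C(15,2) pairs |
| nCC | 105 | coherence-cluster counts per network pair |
| leadCoh | 210 | directed lead-coherence, 15 × 14 ordered pairs |

The three resting-state sets are computed by this package from 15
network time series; the others arrive as tables (image processing is
out of scope).  Edge-metric matrices are vectorized as the row-major
upper triangle of the symmetric 84 × 84 matrix.

### Wavelet-coherence features

Wavelet coherence between two network series uses a complex Morlet
mother wavelet (`cmor1.5-1.0`), 24 logarithmically spaced scales
covering 0.01–0.2 Hz (the band-pass window of the fMRI preprocessing
anchors the scale range), Gaussian time-smoothing with width
proportional to scale, and a 3-point boxcar across scales, before
forming magnitude-squared coherence.  Cells inside the cone of
influence (edge distance < √2 · scale) are excluded.

*Significance* defaults to a per-scale Monte-Carlo threshold: the 95th
percentile of coherence between independent white-noise pairs on the
same grid, estimated once from 20 simulated pairs with a fixed internal
seed and cached per grid configuration.  On null data ≈5 % of usable
cells are therefore flagged by construction.  A fixed numeric cutoff
can be configured instead.  The exact parameterization of the original
wavelet analysis is not restated in the source literature, so all of
these are explicit configuration with the defaults above.

*Phase convention*: `phase = arg(W_x · conj(W_y)) > 0` means the first
series leads (its band content occurs earlier); verified against
analytically lagged sinusoids.

* **nCC** counts connected components (4-neighbour) of the significant
  mask, with components split by interaction kind — in-phase
  (|φ| < π/4), out-of-phase (|φ| > 3π/4), leading / lagging otherwise
  by sign — so one contiguous region containing two kinds counts twice.
* **leadCoh(i→j)** is by default the *binary* fraction of significant
  cells in which i leads j; a phase-weighted variant (mean positive part
  of sin φ) is available behind a switch.  Whether the original measure
  aggregated a binary indicator or a weighted extent is not documented;
  the binary form is the default because it is scale-free in φ.
* **sFC** is the Fisher z-transformed Pearson correlation per unordered
  pair, with |r| capped at 1 − 10⁻⁶ so identical series stay finite.

## Classification

A linear soft-margin SVM (C = 1, never tuned) inside nested
leave-one-out cross-validation (LOOCV).  For each outer fold (one
held-out subject):

1. an inner LOO loop over the n−1 training subjects repeats, per inner
   fold, the **double feature ranking** below and evaluates candidate
   models using the top 1..k_final ranked elements;
2. the number of features is the only tuned parameter: k_optimal is the
   candidate k with the highest inner AUC (ties → smallest k);
3. the outer training set is re-ranked, the SVM refit on the top
   k_optimal elements, and the held-out subject predicted.

Features are z-scored with training-fold statistics at every step, so
no information from a held-out subject reaches standardization, ranking
or fitting (asserted by a corruption test).

**Double ranking.**  Stage 1 selects the k_initial elements with the
smallest two-sample p-values; per element, a pooled-variance t-test is
used when both class samples pass a Shapiro–Wilk normality check at
α = 0.05, a Wilcoxon rank-sum test otherwise (classes with < 3
observations skip the gate and use rank-sum, flagged).  Stage 2 orders
the survivors by one of:

* **MRMR** — greedy forward selection maximizing
  relevance − mean redundancy, with relevance the absolute
  point-biserial correlation of the element with the labels and
  redundancy the mean absolute Pearson correlation with the already
  chosen set.  Both terms live on [0, 1]; with the classical mutual
  information formulation replaced by this correlation form because the
  features are continuous and the cohorts small.  A perfect duplicate
  of a chosen element (redundancy 1) therefore never outranks a weakly
  relevant independent one.
* **CV-SVM** — feature selection via concave minimization: a separating
  plane that trades the two classes' average bounding-plane violations
  against an exponential approximation (steepness α = 5) of the number
  of nonzero weights, solved by successive linear programming (HiGHS
  LP via scipy), up to 50 iterations, converged when the weight support
  is stable and the objective improves < 10⁻⁶.  The first iteration
  uses a plain 1-norm cost: the exponential cost linearized at w = 0 is
  α-times steeper and would lock in the all-zero plane immediately.
  Elements are ordered by descending |weight|; zero-weight elements
  follow, ordered by univariate p.  Trade-off weight λ = 0.5.

Everything is deterministic: ties break by p-value, then |statistic|,
then element index; argmax ties by smallest k / lowest index.

**Inner-loop AUC.**  Each inner fold contributes a single held-out
decision value, so a per-fold AUC does not exist; the n−1 values per
candidate k are pooled into one AUC (the standard resolution).  An
accuracy-averaging variant is available (`inner="averaged"`).

**Metrics.**  AUC uses the Mann–Whitney pair-counting convention (ties
count ½) on decision values; accuracy, sensitivity, specificity,
precision and F1 come from thresholding at 0.  The positive class is
MDD for diagnosis, PO for outcome.  When a model emits only labels
(majority-vote ensembles), its "AUC" is the single-operating-point
value (sensitivity + specificity)/2 — the only ROC area consistent with
a binary output.

## Multi-modal fusion

1. **Concatenation** — all sets joined column-wise; the uni-modal
   procedure runs unchanged.
2. **Forced fusion** — inside every training fold the top 5 elements of
   each set by univariate group difference are pooled (every set is
   represented), then MRMR/CV-SVM ranking and the k search run with
   k_final = 5.  The nested search re-optimizes k up to 5 rather than
   always using exactly 5 (the more conservative reading of the
   procedure).
3. **Majority-vote ensembles** — the stored uni-modal LOO label
   predictions of n_set ∈ {3, 5, 7, 9, 11} member sets vote per
   subject; no refitting.  Odd membership precludes ties; ablation can
   create even memberships, whose ties break by summed decision values.

## Inference

* **Permutation test** — class labels are shuffled and the *entire*
  nested pipeline rerun per permutation; p = #(null AUC ≥ true
  AUC)/n_perm, ties counting against the hypothesis.  p = 0 is printed
  as "< 1/n_perm".  Simple label shuffles (class ratio preserved).
* **Bootstrap CI** — the fixed (decision value, label) pairs are
  resampled with replacement to the original n; percentile 2.5/97.5
  bounds over the resampled AUCs; resamples missing a class are redrawn
  and counted.
* **Group-difference screen** — the same normality-gated two-sample
  tests per element, with Benjamini–Hochberg FDR control at α = 0.05
  applied separately within each feature set.

## Feature analysis

Per uni-modal model: the outer-fold occurrence percentage of each
element (selection stability) and its mean |β| over the folds where it
was selected (β in standardized space, so magnitudes are comparable);
the two rankings may disagree and are both reported.  Min–max
normalization of contributions pools all models so scores are
comparable between them.  Per ensemble: leave-one-member-out ablation
(ΔAUC per removed set, negative values permitted).

## Synthetic cohorts

`generate_feature_tables` draws Gaussian feature tables with one shared
standard-normal factor per set and subject (equicorrelation ρ, default
0.1 — a mild set-level batch/subject factor) and plants standardized
mean shifts of ±d on chosen elements in group B.  This matches the
two-group mean-shift structure the univariate screen assumes while
staying analytically tractable.  `generate_hdrs` draws baseline scores
from N(24.4, 4.62²) — the severity distribution of a moderately
depressed cohort — relative reductions from outcome-specific normals,
rounds to the integer instrument, clips to [0, 52], and clamps across
the 50 % boundary so that the reduction rule recovers the intended
assignment exactly, up to an explicit label-noise rate.
`generate_rsn_timeseries` builds each network as unit-variance white
noise plus, per coupled pair, a shared band-limited component (Gaussian
spectral window, relative bandwidth 0.25) delayed in the lagging
network by `phase_lag/(2π f)`.  One master seed expands into per-stage
child streams via CRC-hashed paths, so every stage is bit-reproducible
and replicates are order-invariant.

What the generator does *not* emulate: non-Gaussian marginals, site or
motion artifacts, realistic anatomical covariance between feature sets,
1/f temporal spectra, or any image-level process.  Tests passing on
these cohorts therefore establish that the pipeline is correct and
calibrated — not that real MRI data carries the signal.

## Problem sizes and numerical choices

LOO AUC at cohort sizes of tens of subjects is highly dispersed (and,
with feature selection chasing noise, slightly pessimistic under the
null); calibration statements are therefore made about means over
seeds.  The test suite uses: 20 seeds of n = 20+20 with 105 elements
for null calibration and signal recovery; 40 repetitions of a
200-permutation test on n = 6+6 cohorts with 10 elements for type-I
calibration; 500 replicates for bootstrap coverage; 50 realizations for
the lead-coherence direction.  `scripts/acceptance.py` runs the full
workflow on clinically sized cohorts (31+32 diagnosis, 19+12 outcome) with
the five edge-metric sets down-sampled to 300 elements each — sizes
chosen so the whole script completes in a few minutes on one CPU.

Inner-loop statistics (Shapiro–Wilk via Royston's AS R94
approximation, pooled t, rank-sum normal approximation, rank-based
AUC) are vectorized across feature columns, and the SVM dual is solved
by a small SMO routine compiled with numba; each reproduces its scipy /
scikit-learn counterpart and is pinned to it by unit tests.  Degenerate
inputs are defined away explicitly: constant columns are maximally
non-normal (p = 0) with zero relevance; zero-variance training columns
standardize to zero; precision is 0 (flagged) when no positive
predictions exist; single-class training sets raise.

## Known limitations

* AUC for label-only ensembles is the one-point trapezoid; it is not
  comparable to a continuous-score AUC at equal discrimination.
* The permutation test reruns the full nested pipeline and is O(n_perm
  · n² · k_final) SVM fits; budget accordingly (or lower n_perm).
* CV-SVM ranking solves ~10–50 LPs per fold and is markedly slower
  than MRMR inside nested LOOCV; it is intended for modest k_initial.
* The Monte-Carlo coherence threshold is estimated per grid from 20
  null pairs; its sampling error (~1 % of cells) is visible in strict
  null-rate assertions.
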