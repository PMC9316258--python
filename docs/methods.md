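# Methods

## Overview

`sagpred` is a binary sequence-classification pipeline: protein FASTA in,
per-protein senescence-association scores out. The model assumes that the
signal distinguishing senescence-associated proteins from background
proteins is visible in global sequence composition and short-range
sequence order — the information captured by dipeptide frequencies,
pseudo-amino-acid correlation factors and lagged physicochemical
covariances. It makes no use of homology search, domain annotation or
expression data.

## Cleaning

Three rules are applied in a fixed order (ambiguity → length →
redundancy); a record failing several rules is attributed to the first,
so the audit counts partition the input exactly.

* **Ambiguity.** A record is removed iff it contains any of
  B, J, O, U, X, Z or any character outside the 20 standard amino-acid
  letters (internal `*` included). One *trailing* `*` is a translation
  stop, stripped at parse time and logged.
* **Length.** Strictly fewer than 50 residues (default) removes a record;
  exactly 50 is kept.
* **Redundancy.** Greedy longest-first clustering: records are visited by
  decreasing length (ties by identifier), each joining the first existing
  cluster whose representative it matches at identity ≥ 0.7, else
  founding its own. Identity is the number of identical aligned residues
  in a best-scoring global alignment divided by the length of the
  *shorter* sequence — the convention of classic greedy clustering tools.
  The alignment uses match = 1, mismatch = 0, gap = 0, under which the
  optimal score equals the longest-common-subsequence length; this makes
  identity deterministic and independent of which co-optimal alignment a
  library happens to report. No word-size prefilter is used: at the
  scales this package targets, exact scoring is affordable and exactly
  testable.

## Descriptors

All descriptors are pure per-sequence functions: the same sequence always
produces bit-identical vectors, and no corpus-level statistics enter the
encoding.

* **Kmer** (default k = 2, 400 dims): overlapping k-mer counts divided by
  `L − k + 1`, components in lexicographic order over
  `ACDEFGHIKLMNPQRSTVWY`. Sums to 1.
* **PC-PseAAC** (default λ = 2, w = 0.05, 22 dims): the 20 composition
  fractions `f_u` plus λ sequence-order factors
  `θ_j = (1/(L−j)) Σ_{i=1}^{L−j} Θ(R_i, R_{i+j})`, with
  `Θ(R_i,R_j) = (1/P) Σ_p (H_p(R_j) − H_p(R_i))²` over the property
  scales; the full vector is divided by `1 + w Σ_j θ_j`, so it sums to 1
  and is componentwise non-negative. Requires `L > λ`.
* **ACC** (default LAG = 3, 27 dims): the sequence becomes P = 3 numeric
  tracks; auto-covariances `AC(p,g) = (1/(L−g)) Σ_i (x_p(i)−x̄_p)(x_p(i+g)−x̄_p)`
  and cross-covariances for all ordered property pairs, lags 1..LAG.
  Output order is all AC blocks (property-major, lag-minor), then all CC
  blocks (ordered-pair-major, lag-minor). Track means are per-sequence —
  the plain covariance definition — which also keeps encoders pure.
  Requires `L > LAG`.

**Property table.** The shipped default is the classic trio used
throughout the pseudo-amino-acid-composition literature: hydrophobicity,
hydrophilicity (both dimensionless scale values) and side-chain mass
(daltons), stored raw in `src/sagpred/data/properties.json` and
standardized at load time to mean 0 / SD 1 over the 20 residues with the
*population* convention (denominator 20). The population/sample choice
changes every PC-PseAAC and ACC value, so it is fixed here explicitly and
checked to 1e−12 by a test. Users may supply any alternative table;
constant scales are rejected.

**Fusion** concatenates descriptor blocks in the declared encoder order;
widths are additive (400/22/27 singles; 422/427/49 pairs; 449 for all
three).

## PCA and the dimension scan

PCA is a centering plus the full eigen-decomposition of the training
covariance (full-SVD solver — deterministic, no randomized sketching).
Component signs are fixed so each loading's largest-magnitude coordinate
is positive, making serialized transforms reproducible. The dimension
scan evaluates each candidate count by stratified cross-validated F1,
re-fitting PCA *inside every training fold*: fitting it once on all data
before splitting leaks held-out information and can select a different
dimension, so the scan deliberately pays the extra fits. Ties go to the
smallest dimension. The default candidate grid is
{1, 2, 5, 10, 25, 50, 75, 90, 100} % of the full width, rounded and
deduplicated — the discriminative count is data-dependent, so the package
guarantees the mechanism rather than any particular number.

## Classifiers

* **SVM**: RBF/linear kernels with grid axes cost
  {0.1, 1, 10, 100}, gamma {1e−4, 1e−3, 1e−2, 1e−1, "scale"} and kernel
  {linear, rbf}. Features are standardized per column (training means and
  SDs) before the SVM — RBF kernels are scale-sensitive. Probabilities
  come from Platt-style sigmoid calibration fit on cross-validated
  decision values, with the final SVM refit on all training rows. The SVM
  stopping tolerance is tightened to 1e−7 so decision values are stable
  under orthonormal feature rotations (a full-rank PCA changes scores
  only at the 1e−6 level).
* **Gradient-boosted trees**: 100 trees with grid axes max_depth
  {3, 6, 9}, subsample {0.7, 1.0}, min_child_weight {1, 5},
  colsample_bytree {0.7, 1.0}, gamma {0, 1}, learning_rate
  {0.05, 0.1, 0.3}. Trees receive *unscaled* features (splits are
  scale-invariant); the bundle records the choice.

Grid search is a native exhaustive loop: identical stratified folds are
reused for every grid point, scoring is fold-mean F1, and ties break to
the earlier position in the declared grid order — a reproducibility
guarantee library grid searchers do not document. Class imbalance gets no
reweighting by default; a `balanced` switch enables standard
inverse-frequency class weights.

**Canonical row ordering.** Training rows are sorted (labels, then
feature values) before any fit, so the trained pipeline — including the
calibration folds — is invariant to the order rows arrive in. Duplicate
rows are interchangeable under this order, so the sort is well-defined.

**Degenerate inputs.** Zero-variance feature columns get scale 1 with a
logged warning (not an error — constant columns are common in sparse
k-mer matrices). Single-class labels and non-finite features are errors.

## Evaluation

ACC, Precision and Sensitivity follow the standard confusion-matrix
definitions; F1 is the harmonic mean `2PS/(P+S)`. An `f1_variant=
"printed"` switch computes the un-doubled ratio `PS/(P+S)` for auditing
legacy reports that used that form. Any 0/0 is reported as 0 with a
logged warning; all-zero confusion counts are an error.

AUC uses the rank (Mann–Whitney) formulation with ties counted one half;
a test asserts it equals the trapezoidal ROC area to 1e−10. Stratified
fivefold cross-validation fits scaler, optional PCA and classifier on
training folds only; reports carry per-fold metrics, their unweighted
mean, a pooled-count variant (the two differ when folds are uneven), and
pooled out-of-fold ROC points. The holdout protocol is a stratified
80/20 split, reproducible by seed (default seed 17 throughout).

## Prediction

Prediction-mode cleaning applies only the ambiguity filter and the length
preconditions (max of the configured minimum, default 50, and what the
bundle's encoders require); redundancy clustering is a training-set
de-biasing step and is never applied to query proteomes. Unscorable
records are returned with a reason (`ambiguous_residues` / `too_short`)
so the output ids always match the input ids exactly. Encoding streams
in chunks (default 2000 records) for bounded memory; chunk size provably
(and testably) never changes results. The decision threshold is 0.5
unless reconfigured, and is recorded in every summary.

## Synthetic benchmark generator

The generator emulates the *compositional* contrast between a positive
and a background protein class. Negatives are drawn i.i.d. from a
background residue distribution typical of curated protein databases
(shipped as a data file, so k-mer features have realistic sparsity
rather than uniform noise). Positives shift the background logits by
`divergence` times a fixed unit perturbation direction; an optional
first-order Markov term (`dipeptide_coupling`) adds signal visible to
dipeptide features but invisible to plain composition. Both directions
are pinned by a constant internal seed, so "the positive regime" means
the same thing in every run; the config seed controls sampling only.
Lengths are uniform on 60–400 residues. Dirty records are injected in
exact counts (`round(rate · n)`), making preprocessing tests
deterministic.

With `divergence = 0` and no coupling the two classes are statistically
identical — the null benchmark; cross-validated AUC then sits in the
chance band (0.35–0.65 at n = 400, the width set by AUC sampling
variability at that size). `divergence = 3` is the strong-signal
condition where the fused-feature SVM reaches fivefold F1 ≥ 0.95.

What the generator does **not** emulate: homologous family structure
(so redundancy clustering sees only injected near-duplicates), domain
architecture, length–class correlations, and any biological meaning of
the perturbation direction. Passing tests therefore demonstrate that the
pipeline recovers compositional class structure correctly and
deterministically — not that any particular biological corpus would
reach the same numbers.

## Problem sizes

Tests and the acceptance script run at n = 200–400 sequences with the
default 422-dimensional fused descriptor, fivefold cross-validation, and
a compact SVM grid (cost {1, 10} × gamma {0.01, "scale"} × kernel
{linear, rbf}) where a full search is exercised. These sizes give stable
statistics for every check while keeping the whole suite near ten
seconds; all stages scale to full proteomes through the chunked
prediction path.

## Known limitations

* The redundancy clustering is exact but O(n²) in alignment calls; very
  large training corpora would want a word-size prefilter (results on
  any test-scale input would be unchanged).
* SVM probability calibration is approximate: label-flip symmetry
  `s ↔ 1 − s` holds only to ~0.05, the documented tolerance of sigmoid
  calibration on finite data.
* The `gamma = "scale"` heuristic depends on the flattened variance of
  the training block and is therefore not exactly invariant under
  orthonormal rotations; fixed numeric gammas are.
* Percentage summaries exclude skipped records from the denominator;
  proteomes with many ambiguous translations will show that in
  `n_skipped`, not in the percentage.
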