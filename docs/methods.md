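# Methods

## Setting and model

A fruit is photographed from N viewpoints (the shipped defaults model the
two-view stem-end/flower-end arrangement). Each view's classifier emits a
multi-label score vector **P**ₙ over M ordinal ripeness stages — independent
per-class logistic outputs, so entries are non-negative and need not sum
to 1. The package fuses these vectors at the decision level; it never sees
pixels.

**Equal-weight fusion** averages: P = Σₙ (1/N)·**P**ₙ.

**Stochastic decision fusion (SDF)** weights each view by the precision
structure of its calibration confusion matrix **A**ₙ (M×M, rows = true
class, columns = predicted class, columns normalized to sum 1; the diagonal
entry of column m is class-m precision). View n's winning class
mₙ = argmax **P**ₙ selects column mₙ from *every* view's matrix, and

    αₙ = a_{n,mₙ} ⊘ Σₖ a_{k,mₙ}   (element-wise; 0/0 ≔ 0),
    P  = Σₙ αₙ ⊗ Pₙ.

At N=2 this reduces to α₁ = a₁,ₘ₁/(a₁,ₘ₁+a₂,ₘ₁), α₂ = a₂,ₘ₂/(a₁,ₘ₂+a₂,ₘ₂);
the generalization to N>2 divides each view's selected column by the sum of
all views' copies of that column.

Both rules L2-normalize the fused vector and decide by argmax. The
normalization is a monotone rescaling, so it never changes the decision; it
standardizes the reported score magnitude.

### Conventions the math does not fix

* **Column orientation.** Confusion columns are normalized by
  predicted-class totals, making the diagonal entry a precision. The
  alternative — normalizing by true-class (row) totals, which makes
  diagonals recalls — is rejected because the weighting is meant to favor
  the view that is *precise* about the class it is claiming, and because
  the column-sum-to-1 invariant is what the reference matrices satisfy.
* **0/0 coordinates.** Where no view's selected column carries mass at a
  row, the weight is 0 by default: no precision mass, no vote. A `half`
  option splits the coordinate equally (1/N each) instead.
* **Argmax ties.** Broken toward the lowest class index, i.e. the earliest,
  least-ripe stage — deterministic, and conservative for sorting (an
  under-called fruit keeps ripening in the box; an over-called one cannot
  come back). The equal-weight rule needs this on real inputs: the
  canonical two-view disagreement example averages to an exact 0.45/0.45
  tie.
* **Degenerate decisions.** An all-zero fused vector (e.g. both views
  silent) yields `stage=None` with a `degenerate` flag rather than an
  arbitrary class.

### What is provable, exactly

* When all views share the winning class m, they all select column m, so
  for every coordinate j the weights Σₙ αₙ[j] sum to 1 (or to 0 where no
  view has mass). Each fused coordinate is then a *convex combination*
  across views. When views disagree, different columns are selected and the
  per-coordinate sums are unconstrained — the canonical worked example
  gives α₁+α₂ = [1.243, 0.865, 0.714, 0, 0].
* **Agreement preservation** follows from the convexity under a cross-view
  margin: if every view's score for the shared winner m exceeds every
  view's score for any other class, then fused[m] ≥ minₙ Pₙ[m] >
  maxₙ,ⱼ≠ₘ Pₙ[j] ≥ fused[j]. Within-view agreement alone (each view merely
  ranking m first) does *not* suffice, even with diagonally dominant
  matrices: if one view holds nearly all the weight on a runner-up
  coordinate and scores it close to its own winner, the fused argmax can
  move. The test suite pins one such boundary case.
* With all views sharing one strictly positive confusion matrix, every
  weight is exactly 1/N and SDF coincides with equal weighting. Zeros in
  the selected columns break the coincidence (the 0/0 rule silences those
  coordinates), so the equivalence property is tested with positive random
  matrices.

## Calibration

`calibrate_confusion` counts (true, predicted) pairs and normalizes each
column by its total. Classes never predicted keep an all-zero column,
flagged degenerate rather than erroring: a weight lookup that lands on such
a column contributes nothing, which is the faithful reading of "no
evidence".

## Detector post-processing

The detector abstraction is a grid head: S×S cells, B boxes per cell, each
box carrying 4 coordinates + 1 objectness confidence + M class scores
(S·S·B·(5+M) numbers total). The package implements the parts that are pure
arithmetic — no network is trained or run:

* **IoU / NMS.** Boxes are fractional center-format (cx, cy, w, h), the
  annotation dialect of Darknet-style label files; corner format exists
  only as a conversion, never as interchange. NMS is greedy by descending
  confidence (ties keep input order, for determinism), class-aware by
  default (suppression within each argmax class), with conventional
  defaults IoU ≤ 0.45 kept, score ≥ 0.25 kept — both configurable since no
  single pair of thresholds suits every deployment.
* **Losses.** Three terms: box loss λ_bbox·Σ_obj d(b, b̂) with d the plain
  Euclidean distance on the 4-vector (a `squared` flag restores the
  squared-error variant of the original grid-detector formulation);
  confidence loss Σ_obj d(C, Ĉ) + λ_nobj·Σ_nobj d(C, Ĉ) with d = |·| on
  scalars; and the multi-label binary cross-entropy averaged over the M
  class outputs. Defaults λ_bbox = 5, λ_nobj = 0.1. Probabilities are
  clipped to [1e−12, 1−1e−12] before logarithms, so a perfect prediction
  costs ≤ 1e−10 rather than producing log 0. Assignment of ground truths
  to boxes is the caller's concern, expressed as a binary S²×B mask; the
  loss code takes no position on one-box-per-object policies.

## Evaluation

Per-class precision/recall/F1 are one-vs-rest; 0/0 is reported as 0 with a
degenerate flag, and macro averages always divide by the full M so an
absent class honestly drags the average down instead of silently vanishing.

The PR curve for class c sweeps thresholds over the distinct observed
scores from high to low. Its area is the stepwise sum Σᵢ (Rᵢ−Rᵢ₋₁)·Pᵢ
(recall starting at 0) — the average-precision rule — chosen over trapezoid
interpolation because it never credits precision between operating points
that no threshold achieves, and because it makes the area provably
non-decreasing when a true positive's score is raised. It equals
scikit-learn's `average_precision_score`, which the tests use as an
independent cross-check.

`kfold_split` is a seeded permutation cut into k nearly equal folds
(sizes differ by ≤ 1); an optional stratified mode deals each class
round-robin across folds. Cross-validation (`sdfuse crossval`) calibrates
per-view confusion matrices on each training fold and scores fused
decisions on the held-out fold.

## Synthetic multi-view streams

The simulator replaces an image pipeline with a score-space model:

* A **view kernel** K is an M×M row-stochastic matrix; row c is the view's
  expected score profile when the true stage is c. `make_view_kernel(M,
  accuracy, spill)` puts `accuracy` on the diagonal, `spill` on each
  existing ordinal neighbor (ripeness confusions are overwhelmingly
  adjacent-stage), and spreads any remainder uniformly over the other
  classes; infeasible rows (negative remainder, or leftover mass with no
  class to take it) are rejected.
* Scores are drawn per sample and view as Dirichlet(κ·(K[c]+ε)) with
  ε = 1e−3 smoothing (so exact zeros still give valid concentrations). The
  Dirichlet mean is the smoothed, renormalized kernel row — an exact,
  testable calibration property — and κ (unitless, default 50) sets the
  sharpness: larger κ concentrates draws around the row.
* Views are conditionally independent given the true stage; an optional
  `view_correlation` ∈ [0,1] mixes a shared per-sample random tilt into
  both rows for robustness experiments (default 0).
* Stage priors default to uniform over the M stages.

What this does *not* emulate: real logistic scores are not simplex-bound
(fusion accepts both; simplex draws were chosen to make the kernel-mean
property exact); localization error, spatial mismatch between the two
views' boxes, and lighting/pose nuisances are absent; and per-view errors
in real systems are correlated through the shared fruit surface in ways a
single correlation knob only sketches. Passing tests therefore demonstrate
the correctness and the qualitative behavior of the fusion rules, not any
particular accuracy on camera data.

A consequence worth stating: at the default κ = 50 with kernels
(accuracy 0.90, spill 0.04) and (0.78, 0.10), the per-view argmax is
essentially always correct — draws concentrate too tightly for the argmax
to flip — so the shipped fusion-gain comparison sits at the accuracy
ceiling and its inequalities hold with equality. At κ = 1 the same kernels
give realistically imperfect views (macro-F1 ≈ 0.93 and ≈ 0.81), and both
fusion rules clearly beat the best single view while staying within 0.01
macro-F1 of one another. The acceptance script reports both regimes.

## Problem sizes and numerics

The shipped experiments use 5000-sample test streams with 2000-sample
calibration streams, 5000 draws per class for the kernel-mean check (sup
-norm tolerance 0.02, comfortably above the Monte-Carlo error at that n),
and 10000-sample streams for the κ-monotonicity check at κ ∈ {1, 10, 100}.
Randomized property tests run 100–1200 trials each. All randomness flows
through explicit integer seeds (numpy `default_rng`); reruns are
byte-identical, and the CLI writes a manifest (input/output SHA-256
digests, seeds, version) next to every artifact.

Float handling: fused norms are exact to 1e−12; confusion column sums are
validated to 1e−9; CSV writers use 17 significant digits and readers parse
with round-trip precision, so write→read is the identity on floats; IoU of
two identical boxes short-circuits to exactly 1.0 to avoid corner-conversion
rounding.

## Known limitations

* Fusion assumes the per-view detections are already matched to the same
  physical fruit; spatial reconciliation of disagreeing boxes is out of
  scope.
* The confusion-matrix weighting ignores score *magnitudes* in the weight
  step (only the argmax selects the column); two views claiming the same
  class with very different confidence get the same α.
* Only the two shipped fusion strategies are provided — no learned
  (stacked/gated) fusion.
* The simulator's Dirichlet family is a modeling choice; the true
  class-conditional score distribution of a trained detector is unknown
  and need not be simplex-supported.
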