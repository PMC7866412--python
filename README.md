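# sdfuse

Decision-level fusion for multi-view fruit ripeness grading.

Automated sorting lines grade after-ripening crops such as tomatoes into
ordinal color stages (Turning, Pink, Light Red, Red, Deep Red). A single
camera view is often ambiguous — the stem end and the flower end of the same
fruit can look one stage apart — so practical systems photograph each fruit
from two opposing views, run a detector/classifier per view, and must then
reconcile two multi-label score vectors into one stage call. `sdfuse`
implements that reconciliation step and everything needed to evaluate it,
for engineers and researchers building multi-view grading pipelines.

## The method

Each view *n* produces a score vector **P**ₙ ∈ ℝ¹ˣᴹ over the M stages
(independent logistic outputs; non-negative, not necessarily summing to 1).
Two fusion rules are provided:

* **Equal-weight fusion** — P = Σₙ (1/N) · **P**ₙ.

* **Stochastic decision fusion (SDF)** — each view first commits to its own
  winning stage mₙ = argmax **P**ₙ. Let **A**ₙ be view *n*'s
  column-normalized confusion matrix from a calibration run (rows = true
  stage, columns = predicted stage; each column sums to 1, so the diagonal
  entry of column m is class-m precision). Column mₙ of every view's matrix
  is selected, and view *n*'s weight vector is the element-wise ratio

  &nbsp;&nbsp;&nbsp;&nbsp;**α**ₙ = **a**ₙ,ₘₙ ⊘ Σₖ **a**ₖ,ₘₙ ,

  with 0/0 ≔ 0. The fused score is P = Σₙ **α**ₙ ⊗ **P**ₙ (⊗ element-wise).
  A view that was historically more *precise* about the class it is claiming
  therefore dominates exactly on the coordinates where it earned that trust.

Either way the fused vector is L2-normalized and the final stage is its
argmax (ties break to the earliest, least-ripe stage). Around this core the
package provides detector post-processing (IoU, greedy non-maximum
suppression, the grid-detector loss terms), one-vs-rest
precision/recall/F1 with PR curves and k-fold splitting, a Dirichlet-based
synthetic two-view score simulator, and readers/writers for Darknet
annotation text, detections JSON, confusion-matrix CSV and label CSV.

## Worked example

The canonical two-view disagreement: the stem-end classifier calls Turning,
the flower-end calls Pink.

```python
import numpy as np
from sdfuse import ConfusionMatrix, ScoreVector, equal_weight_fuse, sdf_fuse, sdf_weights

stem = ConfusionMatrix(np.array([
    [0.90, 0.04, 0.00, 0.00, 0.00],
    [0.10, 0.92, 0.05, 0.00, 0.00],
    [0.00, 0.04, 0.90, 0.02, 0.02],
    [0.00, 0.00, 0.05, 0.90, 0.08],
    [0.00, 0.00, 0.00, 0.08, 0.90]]))
flower = ConfusionMatrix(np.array([
    [0.80, 0.10, 0.03, 0.00, 0.00],
    [0.15, 0.80, 0.06, 0.00, 0.00],
    [0.05, 0.10, 0.82, 0.10, 0.05],
    [0.00, 0.00, 0.06, 0.80, 0.10],
    [0.00, 0.00, 0.03, 0.10, 0.85]]))
p1 = ScoreVector(np.array([0.8, 0.1, 0.05, 0.025, 0.025]))  # stem end: Turning
p2 = ScoreVector(np.array([0.1, 0.8, 0.1, 0.0, 0.0]))       # flower end: Pink

a1, a2 = sdf_weights([p1, p2], [stem, flower])
print(np.round(a1.weights, 6))   # [0.529412 0.4      0.       0.       0.      ]
print(np.round(a2.weights, 6))   # [0.714286 0.465116 0.714286 0.       0.      ]
dec = sdf_fuse([p1, p2], [stem, flower])
print(dec.stage.name)            # Turning
print(np.round(dec.fused_scores, 6))  # [0.763822 0.635944 0.110229 0.       0.      ]
print(equal_weight_fuse([p1, p2]).stage.name)  # Turning (from an exact 0.45/0.45 tie)
```

The weighted rule sides with the stem-end view: its Turning column carries
0.9 precision against the flower-end's 0.8, so the fused vector peaks at
Turning (0.494958 vs 0.412093 before normalization). Plain averaging of the
same inputs lands on an exact 0.45/0.45 Turning/Pink tie that only the
deterministic tie rule resolves — the confusion-weighted rule never faced
the coin flip.

The same workflow is available from the shell:

```
sdfuse --seed 42 simulate --n 5000 --kappa 50 -o sim.json --labels labels.csv
sdfuse calibrate --pred pred_stem.csv --truth labels.csv -o stem.csv
sdfuse fuse --method sdf --scores sim.json \
    --confusion stem-end=stem.csv --confusion flower-end=flower.csv -o decisions.csv
sdfuse evaluate --pred decisions.csv --truth labels.csv --report report.json
```

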