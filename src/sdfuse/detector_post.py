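"""Detector-side post-processing and loss arithmetic.

A one-stage grid detector divides the image into S x S cells, each proposing
B boxes; every box carries 4 coordinates, an objectness confidence and M
class scores, so the output tensor holds ``S*S*B*(5+M)`` numbers. This module
implements the pieces of that pipeline that are pure array arithmetic:

* the output-tensor size contract,
* IoU between center-format boxes and greedy non-maximum suppression,
* the three-part training loss (box distance, confidence, multi-label
  cross-entropy) evaluated on prediction/ground-truth tensors.

No network is trained or run here; the loss operations exist so that every
stated formula is executable and testable on toy tensors. The distance
``d(u, v)`` is the plain Euclidean distance; ``squared=True`` switches to the
squared-error variant of the original grid-detector formulation for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types_io import Detection, BoundingBox, ValidationError

__all__ = [
    "GridSpec",
    "AssignmentMask",
    "LossWeights",
    "output_tensor_size",
    "iou",
    "nms",
    "bbox_loss",
    "conf_loss",
    "cls_loss",
    "total_loss",
]

#: Clipping bound applied to probabilities before logarithms in cls_loss.
EPS_LOG = 1e-12


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry of the detector head: S x S cells, B boxes per cell, M classes."""

    S: int
    B: int
    M: int

    def __post_init__(self) -> None:
        if self.S < 1 or self.B < 1 or self.M < 0:
            raise ValidationError(f"invalid grid spec S={self.S}, B={self.B}, M={self.M}")


@dataclass(frozen=True)
class AssignmentMask:
    """S^2 x B binary assignment: obj[i, j] = 1 where a ground truth is assigned.

    ``nobj`` is the element-wise complement, maintained as an invariant.
    """

    obj: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.obj, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("assignment mask must be 2-D (S^2 x B)")
        if not np.all((arr == 0) | (arr == 1)):
            raise ValidationError("assignment mask entries must be 0 or 1")
        object.__setattr__(self, "obj", arr)

    @property
    def nobj(self) -> np.ndarray:
        return 1.0 - self.obj


@dataclass(frozen=True)
class LossWeights:
    """Loss balance: lambda_bbox scales the box term, lambda_nobj the empty-box term."""

    lambda_bbox: float = 5.0
    lambda_nobj: float = 0.1


def output_tensor_size(grid: GridSpec) -> int:
    """Number of scalars the detector head emits: S*S*B*(5+M)."""
    return grid.S * grid.S * grid.B * (5 + grid.M)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two center-format boxes; 0 when disjoint."""
    if a == b:
        return 1.0  # exact for identical boxes despite corner-conversion rounding
    ax1, ay1, ax2, ay2 = a.to_corners()
    bx1, by1, bx2, by2 = b.to_corners()
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return float(inter / union)


def nms(
    detections: list[Detection],
    iou_threshold: float = 0.45,
    score_threshold: float = 0.25,
    class_aware: bool = True,
) -> list[Detection]:
    """Greedy non-maximum suppression.

    Detections below ``score_threshold`` are dropped, the rest are visited in
    descending confidence (ties keep input order), and each is kept only if
    its IoU with every already-kept detection (of the same argmax class when
    ``class_aware``) is at most ``iou_threshold``. Output is sorted by
    descending confidence. Idempotent by construction.
    """
    if not (0 <= iou_threshold <= 1) or not (0 <= score_threshold <= 1):
        raise ValidationError("thresholds must lie in [0, 1]")
    lengths = {d.scores.m for d in detections}
    if len(lengths) > 1:
        raise ValidationError(f"detections carry mixed score lengths {sorted(lengths)}")
    candidates = [d for d in detections if d.confidence >= score_threshold]
    # stable sort: equal confidences keep insertion order, making output deterministic
    order = sorted(range(len(candidates)), key=lambda i: -candidates[i].confidence)
    kept: list[Detection] = []
    kept_cls: list[int] = []
    for i in order:
        d = candidates[i]
        c = d.scores.argmax()
        suppressed = any(
            (not class_aware or c == kc) and iou(d.box, k.box) > iou_threshold
            for k, kc in zip(kept, kept_cls)
        )
        if not suppressed:
            kept.append(d)
            kept_cls.append(c)
    return kept


def _distance(pred: np.ndarray, truth: np.ndarray, squared: bool) -> np.ndarray:
    """Per-box distance along the last axis: Euclidean norm, or its square."""
    diff = pred - truth
    sq = np.sum(diff * diff, axis=-1)
    return sq if squared else np.sqrt(sq)


def _check_grid_shape(name: str, arr: np.ndarray, mask: AssignmentMask, inner: int | None) -> None:
    expected = mask.obj.shape + ((inner,) if inner else ())
    if arr.shape != expected:
        raise ValidationError(f"{name} shape {arr.shape} does not conform to mask {expected}")


def bbox_loss(
    pred_boxes: np.ndarray,
    truth_boxes: np.ndarray,
    mask: AssignmentMask,
    weights: LossWeights = LossWeights(),
    squared: bool = False,
) -> float:
    """Localization loss: lambda_bbox * sum over assigned boxes of d(b, b_hat).

    ``pred_boxes`` and ``truth_boxes`` are (S^2, B, 4) tensors of
    center-format coordinates; only cells/boxes flagged in ``mask.obj``
    contribute.
    """
    pred_boxes = np.asarray(pred_boxes, dtype=float)
    truth_boxes = np.asarray(truth_boxes, dtype=float)
    _check_grid_shape("pred_boxes", pred_boxes, mask, 4)
    _check_grid_shape("truth_boxes", truth_boxes, mask, 4)
    d = _distance(pred_boxes, truth_boxes, squared)
    return float(weights.lambda_bbox * np.sum(mask.obj * d))


def conf_loss(
    pred_conf: np.ndarray,
    truth_conf: np.ndarray,
    mask: AssignmentMask,
    weights: LossWeights = LossWeights(),
    squared: bool = False,
) -> float:
    """Objectness loss: assigned boxes at weight 1, unassigned at lambda_nobj.

    ``pred_conf`` and ``truth_conf`` are (S^2, B) scalars; the scalar
    distance is the absolute difference (or its square).
    """
    pred_conf = np.asarray(pred_conf, dtype=float)
    truth_conf = np.asarray(truth_conf, dtype=float)
    _check_grid_shape("pred_conf", pred_conf, mask, None)
    _check_grid_shape("truth_conf", truth_conf, mask, None)
    if not np.all((truth_conf == 0) | (truth_conf == 1)):
        raise ValidationError("ground-truth confidences must be 0 or 1")
    d = _distance(pred_conf[..., None], truth_conf[..., None], squared)
    return float(np.sum(mask.obj * d) + weights.lambda_nobj * np.sum(mask.nobj * d))


def cls_loss(
    pred_scores: np.ndarray,
    truth_onehot: np.ndarray,
    mask: AssignmentMask,
) -> float:
    """Multi-label classification loss on assigned boxes.

    Binary cross-entropy summed over the M independent per-class outputs and
    scaled by 1/M:

        -(1/M) * sum_assigned sum_m [ y_m log p_m + (1 - y_m) log(1 - p_m) ]

    Probabilities are clipped to [1e-12, 1 - 1e-12] before the logarithms.
    """
    pred_scores = np.asarray(pred_scores, dtype=float)
    truth_onehot = np.asarray(truth_onehot, dtype=float)
    if pred_scores.shape != truth_onehot.shape:
        raise ValidationError(
            f"score shape {pred_scores.shape} != truth shape {truth_onehot.shape}"
        )
    if pred_scores.ndim != 3 or pred_scores.shape[:2] != mask.obj.shape:
        raise ValidationError(
            f"scores shape {pred_scores.shape} does not conform to mask {mask.obj.shape}"
        )
    if not np.all((truth_onehot == 0) | (truth_onehot == 1)):
        raise ValidationError("ground-truth class labels must be 0 or 1")
    M = pred_scores.shape[-1]
    p = np.clip(pred_scores, EPS_LOG, 1.0 - EPS_LOG)
    ce = truth_onehot * np.log(p) + (1.0 - truth_onehot) * np.log(1.0 - p)
    return float(-np.sum(mask.obj * ce.sum(axis=-1)) / M)


def total_loss(l_bbox: float, l_conf: float, l_cls: float) -> float:
    """Total loss: the plain sum of the three non-negative components."""
    for name, v in (("bbox", l_bbox), ("conf", l_conf), ("cls", l_cls)):
        if v < 0:
            raise ValidationError(f"{name} loss must be non-negative, got {v}")
    return float(l_bbox + l_conf + l_cls)
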