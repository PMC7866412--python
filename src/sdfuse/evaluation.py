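"""One-vs-rest classification metrics, PR curves, and cross-validation splits.

Per-class precision, recall and F1 are computed one-versus-rest: class c is
the positive class, everything else negative, giving TP/FP/FN counts and

    precision = TP / (TP + FP),  recall = TP / (TP + FN),
    F1 = 2 PR / (P + R).

Any 0/0 is reported as 0 and flagged degenerate rather than dropped, so the
macro average always divides by the full class count M.

The PR curve for class c sweeps a threshold over the distinct observed
values of score[c] from high to low; a sample is called positive when its
score reaches the threshold. The area is the stepwise sum
``sum_i (R_i - R_{i-1}) * P_i`` over that sweep (recall starts at 0), the
same quantity scikit-learn reports as average precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types_io import ScoreVector, StageLabel, ValidationError

__all__ = [
    "ClassMetrics",
    "MetricsReport",
    "PRCurve",
    "classification_metrics",
    "pr_curve",
    "kfold_split",
]


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest counts and rates for a single class."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # true when any 0/0 was reported as 0


@dataclass(frozen=True)
class MetricsReport:
    """Per-class metrics plus unweighted (macro) averages over all M classes."""

    per_class: dict[int, ClassMetrics]
    macro_precision: float
    macro_recall: float
    macro_f1: float

    @property
    def m(self) -> int:
        return len(self.per_class)


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall pairs swept from high to low threshold, with area.

    ``points`` is a list of (recall, precision) pairs; recalls are
    non-decreasing along the sweep. ``empty`` flags the degenerate case of no
    positive ground truth, where recall is undefined.
    """

    points: tuple[tuple[float, float], ...]
    area: float
    empty: bool = False


def _as_index(label: int | StageLabel) -> int:
    return label.index if isinstance(label, StageLabel) else int(label)


def classification_metrics(
    true_stages: Sequence[int | StageLabel],
    predicted_stages: Sequence[int | StageLabel],
    M: int,
) -> MetricsReport:
    """One-vs-rest TP/FP/FN per class, with macro averages over all M classes."""
    if len(true_stages) != len(predicted_stages):
        raise ValidationError(
            f"{len(true_stages)} truths vs {len(predicted_stages)} predictions"
        )
    true = np.array([_as_index(t) for t in true_stages], dtype=int)
    pred = np.array([_as_index(p) for p in predicted_stages], dtype=int)
    if len(true) and (true.min() < 0 or true.max() >= M or pred.min() < 0 or pred.max() >= M):
        raise ValidationError(f"stage index out of range for M={M}")
    per_class: dict[int, ClassMetrics] = {}
    for c in range(M):
        tp = int(np.sum((pred == c) & (true == c)))
        fp = int(np.sum((pred == c) & (true != c)))
        fn = int(np.sum((pred != c) & (true == c)))
        degenerate = False
        if tp + fp == 0:
            precision, degenerate = 0.0, True
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            recall, degenerate = 0.0, True
        else:
            recall = tp / (tp + fn)
        if precision + recall == 0:
            f1, degenerate = 0.0, True
        else:
            f1 = 2 * precision * recall / (precision + recall)
        per_class[c] = ClassMetrics(tp, fp, fn, precision, recall, f1, degenerate)
    return MetricsReport(
        per_class=per_class,
        macro_precision=float(np.mean([m.precision for m in per_class.values()])),
        macro_recall=float(np.mean([m.recall for m in per_class.values()])),
        macro_f1=float(np.mean([m.f1 for m in per_class.values()])),
    )


def pr_curve(
    scores: Sequence[ScoreVector],
    true_stages: Sequence[int | StageLabel],
    c: int,
) -> PRCurve:
    """One-vs-rest precision-recall curve for class c with stepwise area."""
    if len(scores) != len(true_stages):
        raise ValidationError(f"{len(scores)} score vectors vs {len(true_stages)} truths")
    if not scores:
        raise ValidationError("pr_curve requires at least one sample")
    s = np.array([v.scores[c] for v in scores], dtype=float)
    y = np.array([_as_index(t) == c for t in true_stages], dtype=bool)
    n_pos = int(y.sum())
    if n_pos == 0:
        return PRCurve(points=(), area=0.0, empty=True)
    points: list[tuple[float, float]] = []
    area = 0.0
    prev_recall = 0.0
    for threshold in sorted(set(s), reverse=True):
        called = s >= threshold
        tp = int((called & y).sum())
        fp = int((called & ~y).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        points.append((recall, precision))
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return PRCurve(points=tuple(points), area=float(area))


def kfold_split(
    sample_ids: Sequence[str],
    k: int = 5,
    seed: int = 0,
    stratify_by: Sequence[int | StageLabel] | None = None,
) -> list[tuple[list[str], list[str]]]:
    """Seeded k-fold partition: returns k (train_ids, test_ids) pairs.

    Test sets are disjoint, cover all ids, and differ in size by at most 1.
    With ``stratify_by``, ids are dealt round-robin within each class so per
    -class proportions are approximately preserved in every fold.
    """
    ids = list(sample_ids)
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if len(ids) < k:
        raise ValidationError(f"need at least k={k} samples, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValidationError("sample ids must be unique")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        perm = rng.permutation(len(ids))
        test_folds = [[ids[i] for i in chunk] for chunk in np.array_split(perm, k)]
    else:
        if len(stratify_by) != len(ids):
            raise ValidationError("stratify_by must match sample_ids in length")
        test_folds = [[] for _ in range(k)]
        labels = np.array([_as_index(s) for s in stratify_by])
        offset = 0
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            members = members[rng.permutation(len(members))]
            for j, i in enumerate(members):
                test_folds[(offset + j) % k].append(ids[i])
            offset += len(members)
    out = []
    for fold in test_folds:
        test = set(fold)
        out.append(([i for i in ids if i not in test], list(fold)))
    return out
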