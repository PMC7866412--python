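"""Decision-level fusion of per-view classifier scores.

A sample is photographed from N viewpoints (for tomatoes: stem-end and
flower-end) and each view's classifier emits a multi-label score vector P_n.
Two fusion rules combine them into a single ripeness call:

* **Equal-weight fusion** — P = sum_n (1/N) P_n: the simple average.

* **Stochastic decision fusion (SDF)** — each view n first commits to its
  own winning class m_n = argmax(P_n). Column m_n of view n's
  column-normalized confusion matrix A_n records how score mass distributes
  over true classes when view n predicts m_n, and its diagonal entry is that
  view's precision for m_n. The weight vector for view n divides its own
  column element-wise by the sum of the corresponding columns over all
  views,

      alpha_n = a_{n, m_n} / sum_k a_{k, m_n}   (element-wise, 0/0 -> 0),

  and the fused score is P = sum_n alpha_n * P_n (element-wise product).
  Views that were more precise on their claimed class thus dominate exactly
  on the coordinates where they earned it.

Either way the fused vector is L2-normalized and the final stage is its
argmax, with ties broken to the lowest class index (the earliest, least-ripe
stage — the conservative call for sorting). An all-zero fused vector yields
a degenerate decision with ``stage=None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .types_io import (
    ConfusionMatrix,
    ScoreVector,
    StageLabel,
    ValidationError,
    default_stages,
)

__all__ = [
    "WeightVector",
    "FusedDecision",
    "calibrate_confusion",
    "equal_weight_fuse",
    "sdf_weights",
    "sdf_fuse",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class WeightVector:
    """Per-view element-wise fusion weights in [0, 1].

    Across views, each coordinate's weights sum to 1 — or to 0 on degenerate
    coordinates where no view's selected confusion column carries mass.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.weights, dtype=float)
        if arr.ndim != 1:
            raise ValidationError("weights must be a 1-D vector")
        if np.any(arr < 0) or np.any(arr > 1 + _NORM_TOL):
            raise ValidationError("weights must lie in [0, 1]")
        object.__setattr__(self, "weights", arr)


@dataclass(frozen=True)
class FusedDecision:
    """Outcome of a fusion rule for one sample.

    ``fused_scores`` has unit L2 norm unless the decision is degenerate (then
    all-zero). ``per_view_stages`` records each input view's own argmax call,
    in input order.
    """

    fused_scores: np.ndarray
    stage: StageLabel | None
    per_view_stages: tuple[StageLabel, ...]
    degenerate: bool = False

    @property
    def stage_score(self) -> float:
        if self.stage is None:
            return 0.0
        return float(self.fused_scores[self.stage.index])


def _common_m(score_vectors: Sequence[ScoreVector]) -> int:
    lengths = {v.m for v in score_vectors}
    if len(lengths) != 1:
        raise ValidationError(f"score vectors have mixed lengths {sorted(lengths)}")
    return lengths.pop()


def _decide(
    fused: np.ndarray,
    score_vectors: Sequence[ScoreVector],
    stages: Sequence[StageLabel],
) -> FusedDecision:
    """L2-normalize and take the argmax; ties go to the lowest class index."""
    per_view = tuple(stages[v.argmax()] for v in score_vectors)
    norm = float(np.linalg.norm(fused))
    if norm == 0.0:
        return FusedDecision(fused, None, per_view, degenerate=True)
    unit = fused / norm
    return FusedDecision(unit, stages[int(np.argmax(unit))], per_view)


def calibrate_confusion(
    predicted_stages: Sequence[int | StageLabel],
    true_stages: Sequence[int | StageLabel],
    M: int,
    class_names: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Build a column-normalized confusion matrix from a validation run.

    Counts land at (true, predicted); each column is then divided by its
    total, so column m describes how samples *predicted* as class m
    distribute over true classes and the diagonal entry is class-m
    precision. Classes never predicted keep an all-zero (degenerate) column.
    """
    if len(predicted_stages) != len(true_stages):
        raise ValidationError(
            f"{len(predicted_stages)} predictions vs {len(true_stages)} truths"
        )
    if not predicted_stages:
        raise ValidationError("calibration requires at least one sample")
    counts = np.zeros((M, M))
    for pred, true in zip(predicted_stages, true_stages):
        p = pred.index if isinstance(pred, StageLabel) else int(pred)
        t = true.index if isinstance(true, StageLabel) else int(true)
        if not (0 <= p < M and 0 <= t < M):
            raise ValidationError(f"stage index out of range: pred={p}, true={t}, M={M}")
        counts[t, p] += 1
    if class_names is None:
        class_names = [s.name for s in default_stages(M)]
    return ConfusionMatrix.from_counts(counts, class_names)


def equal_weight_fuse(
    score_vectors: Sequence[ScoreVector],
    stages: Sequence[StageLabel] | None = None,
) -> FusedDecision:
    """Average the per-view scores with equal weight 1/N, then normalize and decide."""
    if len(score_vectors) < 2:
        raise ValidationError("fusion requires at least two views")
    M = _common_m(score_vectors)
    if stages is None:
        stages = default_stages(M)
    fused = np.mean([v.scores for v in score_vectors], axis=0)
    return _decide(fused, score_vectors, stages)


def sdf_weights(
    score_vectors: Sequence[ScoreVector],
    confusions: Sequence[ConfusionMatrix],
    zero_over_zero: Literal["zero", "half"] = "zero",
) -> list[WeightVector]:
    """Compute the per-view SDF weight vectors.

    View n's winning class m_n selects column m_n from *every* view's
    confusion matrix; alpha_n is view n's own column divided element-wise by
    the sum of all views' columns. Coordinates where that sum is zero carry
    no precision mass from any view: with ``zero_over_zero='zero'`` (default)
    they get weight 0, with ``'half'`` the mass is split equally (1/N each).
    """
    n_views = len(score_vectors)
    if n_views < 2:
        raise ValidationError("fusion requires at least two views")
    if len(confusions) != n_views:
        raise ValidationError(
            f"{n_views} score vectors but {len(confusions)} confusion matrices"
        )
    M = _common_m(score_vectors)
    for cm in confusions:
        if cm.m != M:
            raise ValidationError(f"confusion matrix size {cm.m} != score length {M}")
    out = []
    for n, vec in enumerate(score_vectors):
        m_n = vec.argmax()
        own = confusions[n].column(m_n)
        total = np.sum([cm.column(m_n) for cm in confusions], axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha = np.where(total > 0, own / np.where(total > 0, total, 1.0), 0.0)
        if zero_over_zero == "half":
            alpha = np.where(total > 0, alpha, 1.0 / n_views)
        out.append(WeightVector(alpha))
    return out


def sdf_fuse(
    score_vectors: Sequence[ScoreVector],
    confusions: Sequence[ConfusionMatrix],
    stages: Sequence[StageLabel] | None = None,
    zero_over_zero: Literal["zero", "half"] = "zero",
) -> FusedDecision:
    """Stochastic decision fusion: P = sum_n alpha_n * P_n, normalized, argmax."""
    alphas = sdf_weights(score_vectors, confusions, zero_over_zero)
    M = _common_m(score_vectors)
    if stages is None:
        stages = default_stages(M, confusions[0].class_names if confusions else None)
    fused = np.sum([a.weights * v.scores for a, v in zip(alphas, score_vectors)], axis=0)
    return _decide(fused, score_vectors, stages)
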