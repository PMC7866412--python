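"""Synthetic multi-view score streams for fusion experiments.

Two-view grading rigs photograph each fruit from opposing camera views, and
each view's classifier confuses mostly *adjacent* ripeness stages (ripening
is ordinal: Turning, Pink, Light Red, Red, Deep Red). This module emulates
that setting in score space, without images:

* A **view kernel** is an M x M row-stochastic matrix whose row c is the
  expected score profile the view produces when the true stage is c. The
  :func:`make_view_kernel` constructor places ``accuracy`` on the diagonal,
  ``spill`` on each existing ordinal neighbor, and spreads the remaining
  mass uniformly over the other classes — mirroring the adjacent-stage
  confusion structure observed in real per-view validation matrices.

* :func:`simulate_views` draws, for each sample, a true stage from the class
  priors and then, independently per view, a score vector from
  ``Dirichlet(kappa * (row + eps))`` with smoothing ``eps = 1e-3`` (so rows
  with exact zeros still give valid concentrations). The Dirichlet mean is
  the smoothed, renormalized kernel row, and ``kappa`` controls how sharply
  draws concentrate around it: larger kappa means a more confident view.

Real logistic score vectors need not sum to 1; simplex draws are used here
because the fusion rules accept them unchanged and they make the
kernel-mean property exact and testable.

An optional shared latent perturbation (``view_correlation``) tilts both
views' kernel rows with the same random direction per sample, for robustness
experiments; it defaults off, keeping views conditionally independent given
the true stage.

:func:`simulate_boxes` generates random center-format detections (with
optional jittered duplicates) as fixtures for suppression and loss tests.

The reference dataset profile the generator emulates — 5 stages, 2 views,
2166 training and 548 test samples — is recorded in :data:`DATASET_PROFILE`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types_io import (
    BoundingBox,
    Detection,
    LabeledSample,
    ScoreVector,
    StageLabel,
    ValidationError,
    default_stages,
)

__all__ = [
    "DATASET_PROFILE",
    "ViewKernel",
    "SimConfig",
    "make_view_kernel",
    "simulate_views",
    "simulate_boxes",
]

#: Shape of the emulated grading setting: five ordinal stages, two views.
DATASET_PROFILE = {
    "n_classes": 5,
    "n_views": 2,
    "view_names": ("stem-end", "flower-end"),
    "n_train": 2166,
    "n_test": 548,
}

_ROWSUM_TOL = 1e-9
#: Concentration smoothing: added to kernel rows before scaling by kappa.
SMOOTHING_EPS = 1e-3


@dataclass(frozen=True)
class ViewKernel:
    """Row-stochastic M x M matrix: row c is a view's expected score profile
    when the true stage is c."""

    rows: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.rows, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValidationError(f"kernel must be square, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValidationError("kernel entries must be non-negative")
        sums = arr.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _ROWSUM_TOL):
            raise ValidationError(f"kernel rows must sum to 1, got sums {sums}")
        object.__setattr__(self, "rows", arr)

    @property
    def m(self) -> int:
        return int(self.rows.shape[0])

    def smoothed_row(self, c: int, eps: float = SMOOTHING_EPS) -> np.ndarray:
        """Row c after smoothing and renormalization: the Dirichlet mean of draws."""
        row = self.rows[c] + eps
        return row / row.sum()


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated multi-view stream.

    ``kappa`` is the Dirichlet concentration (unitless, > 0): the draw for a
    sample of true stage c in view v is Dirichlet(kappa * (K_v[c] + eps)).
    ``priors`` is the stage distribution (uniform when omitted).
    ``view_correlation`` in [0, 1] mixes a shared per-sample random tilt
    into every view's kernel row (0 = conditionally independent views).
    """

    n_samples: int
    kernels: tuple[ViewKernel, ...]
    kappa: float = 50.0
    priors: np.ndarray | None = None
    seed: int = 0
    view_names: tuple[str, ...] = ()
    view_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValidationError("n_samples must be >= 0")
        if not self.kernels:
            raise ValidationError("at least one view kernel is required")
        ms = {k.m for k in self.kernels}
        if len(ms) != 1:
            raise ValidationError(f"kernels have mixed sizes {sorted(ms)}")
        if self.kappa <= 0:
            raise ValidationError(f"kappa must be > 0, got {self.kappa}")
        if not (0.0 <= self.view_correlation <= 1.0):
            raise ValidationError("view_correlation must lie in [0, 1]")
        M = ms.pop()
        if self.priors is None:
            priors = np.full(M, 1.0 / M)
        else:
            priors = np.asarray(self.priors, dtype=float)
            if priors.shape != (M,) or np.any(priors < 0):
                raise ValidationError(f"priors must be a length-{M} non-negative vector")
            if abs(priors.sum() - 1.0) > _ROWSUM_TOL:
                raise ValidationError(f"priors must sum to 1, got {priors.sum()!r}")
        object.__setattr__(self, "priors", priors)
        if not self.view_names:
            names = (
                DATASET_PROFILE["view_names"]
                if len(self.kernels) == 2
                else tuple(f"view{i}" for i in range(len(self.kernels)))
            )
            object.__setattr__(self, "view_names", names)
        elif len(self.view_names) != len(self.kernels):
            raise ValidationError("view_names must match kernels in number")

    @property
    def m(self) -> int:
        return self.kernels[0].m


def make_view_kernel(M: int, accuracy: float, spill: float) -> ViewKernel:
    """Ordinal-confusion kernel: ``accuracy`` on the diagonal, ``spill`` on
    each existing ordinal neighbor, remainder spread uniformly over the rest.

    Raises a validation error when any row's remainder would be negative, or
    when mass is left over with no non-neighbor class to put it on.
    """
    if M < 1:
        raise ValidationError("M must be >= 1")
    if accuracy < 0 or spill < 0:
        raise ValidationError("accuracy and spill must be non-negative")
    rows = np.zeros((M, M))
    for c in range(M):
        neighbors = [n for n in (c - 1, c + 1) if 0 <= n < M]
        others = [j for j in range(M) if j != c and j not in neighbors]
        remainder = 1.0 - accuracy - spill * len(neighbors)
        if remainder < -_ROWSUM_TOL:
            raise ValidationError(
                f"row {c}: accuracy {accuracy} + {len(neighbors)} * spill {spill} exceeds 1"
            )
        remainder = max(remainder, 0.0)
        if remainder > _ROWSUM_TOL and not others:
            raise ValidationError(
                f"row {c}: leftover mass {remainder} but no non-neighbor class to receive it"
            )
        rows[c, c] = accuracy
        for n in neighbors:
            rows[c, n] = spill
        for j in others:
            rows[c, j] = remainder / len(others)
        rows[c] /= rows[c].sum()  # exact row-stochasticity despite float rounding
    return ViewKernel(rows)


def simulate_views(config: SimConfig) -> list[LabeledSample]:
    """Draw a labeled multi-view score stream, fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    M = config.m
    stages = default_stages(M)
    truths = rng.choice(M, size=config.n_samples, p=config.priors)
    samples: list[LabeledSample] = []
    for i, c in enumerate(truths):
        per_view: dict[str, ScoreVector] = {}
        tilt = None
        if config.view_correlation > 0:
            shared = rng.dirichlet(np.ones(M))
            tilt = config.view_correlation * shared
        for name, kernel in zip(config.view_names, config.kernels):
            row = kernel.rows[c]
            if tilt is not None:
                row = (1.0 - config.view_correlation) * row + tilt
            conc = config.kappa * (row + SMOOTHING_EPS)
            scores = rng.dirichlet(conc)
            per_view[name] = ScoreVector(scores)
        samples.append(
            LabeledSample(sample_id=f"s{i:06d}", true_stage=stages[int(c)], per_view_scores=per_view)
        )
    return samples


def simulate_boxes(
    n: int,
    seed: int = 0,
    M: int = 5,
    duplicate_fraction: float = 0.5,
    jitter: float = 0.01,
    view: str = "stem-end",
) -> list[Detection]:
    """Random center-format detections, with jittered near-duplicates.

    Roughly ``duplicate_fraction`` of the n detections are copies of an
    earlier box perturbed by Gaussian jitter (sigma = ``jitter`` in
    fractional units) with a lower confidence, so greedy suppression has
    genuine work to do. ``jitter=0`` yields exact duplicates with IoU 1.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[Detection] = []
    for i in range(n):
        if out and rng.random() < duplicate_fraction:
            base = out[rng.integers(len(out))]
            b = base.box
            box = BoundingBox(
                cx=float(np.clip(b.cx + rng.normal(0, jitter), 0.05, 0.95)),
                cy=float(np.clip(b.cy + rng.normal(0, jitter), 0.05, 0.95)),
                w=float(np.clip(b.w * np.exp(rng.normal(0, jitter)), 1e-3, 1.0)),
                h=float(np.clip(b.h * np.exp(rng.normal(0, jitter)), 1e-3, 1.0)),
            )
            confidence = float(base.confidence * rng.uniform(0.5, 1.0))
            scores = base.scores
        else:
            box = BoundingBox(
                cx=float(rng.uniform(0.1, 0.9)),
                cy=float(rng.uniform(0.1, 0.9)),
                w=float(rng.uniform(0.05, 0.4)),
                h=float(rng.uniform(0.05, 0.4)),
            )
            confidence = float(rng.uniform(0.0, 1.0))
            scores = ScoreVector(rng.dirichlet(np.ones(M)))
        out.append(
            Detection(box=box, confidence=confidence, scores=scores, view=view, sample_id=f"d{i:04d}")
        )
    return out
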