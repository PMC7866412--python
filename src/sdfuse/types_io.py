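"""Core domain types and on-disk formats.

The toolkit models a two-phase ripeness-grading pipeline: per-view object
detectors emit localized detections carrying multi-label class scores, and a
decision-fusion stage combines the per-view score vectors into one ripeness
call. This module holds the shared value types (stages, score vectors, boxes,
detections, confusion matrices, labeled samples) and all readers/writers:

* Darknet-style annotation text (``<class> <cx> <cy> <w> <h>``, fractional
  center format),
* detections JSON,
* per-sample multi-view scores JSON,
* column-normalized confusion-matrix CSV,
* ``sample_id,stage_name`` label CSV.

Class indices are 0-based internally; files interchange class *names* so that
on-disk artifacts are unambiguous about ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGE_NAMES",
    "StageLabel",
    "ScoreVector",
    "BoundingBox",
    "Detection",
    "ConfusionMatrix",
    "LabeledSample",
    "default_stages",
    "read_darknet_labels",
    "read_confusion_csv",
    "write_confusion_csv",
    "read_detections_json",
    "write_detections_json",
    "read_labels_csv",
    "write_labels_csv",
    "read_samples_json",
    "write_samples_json",
]

#: The five ordinal USDA ripeness color classes, in ripening order.
STAGE_NAMES: tuple[str, ...] = ("Turning", "Pink", "Light Red", "Red", "Deep Red")

_COLSUM_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class ParseError(ValueError):
    """Raised when an on-disk artifact cannot be parsed."""


@dataclass(frozen=True, order=True)
class StageLabel:
    """One ordinal ripeness stage: 0-based class index plus display name."""

    index: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValidationError(f"stage index must be >= 0, got {self.index}")


def default_stages(M: int = 5, names: Sequence[str] | None = None) -> list[StageLabel]:
    """Stage labels for an M-class problem; the 5-class default uses the USDA names."""
    if names is None:
        names = STAGE_NAMES if M == len(STAGE_NAMES) else [f"class{i}" for i in range(M)]
    if len(names) != M:
        raise ValidationError(f"expected {M} names, got {len(names)}")
    return [StageLabel(i, n) for i, n in enumerate(names)]


@dataclass(frozen=True)
class ScoreVector:
    """Length-M vector of non-negative per-class scores.

    Scores come from independent per-class logistic outputs, so they are not
    required to sum to 1. A vector that is all zero is valid as data but
    cannot support a class decision on its own.
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValidationError("scores must be a non-empty 1-D vector")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("scores must be finite")
        if np.any(arr < 0):
            raise ValidationError("scores must be non-negative")

    @property
    def m(self) -> int:
        return int(self.scores.size)

    def argmax(self) -> int:
        """Winning class index; ties break to the lowest index (earliest stage)."""
        return int(np.argmax(self.scores))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ScoreVector) and np.array_equal(self.scores, other.scores)

    def __hash__(self) -> int:  # frozen dataclass contract
        return hash(self.scores.tobytes())


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in fractional center format (cx, cy, w, h)."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("cx", "cy", "w", "h"):
            object.__setattr__(self, name, float(getattr(self, name)))
        vals = (self.cx, self.cy, self.w, self.h)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError(f"box fields must be finite, got {vals}")
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(f"box extent must be positive, got w={self.w}, h={self.h}")

    def to_corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) corner coordinates."""
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "BoundingBox":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class Detection:
    """One localized object: box, objectness confidence, class scores."""

    box: BoundingBox
    confidence: float
    scores: ScoreVector
    view: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(f"confidence must lie in [0, 1], got {self.confidence}")


class ConfusionMatrix:
    """M x M column-normalized confusion matrix.

    Rows index the true class, columns the predicted class; every column with
    any mass sums to 1, so the diagonal entry of column m is the precision of
    class m. A column may be all-zero only when that class was never
    predicted during calibration — such columns are flagged degenerate.
    """

    def __init__(self, values: np.ndarray, class_names: Sequence[str] | None = None):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValidationError(f"confusion matrix must be square, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("confusion matrix entries must be finite")
        if np.any(arr < 0):
            raise ValidationError("confusion matrix entries must be non-negative")
        if np.any(arr > 1 + _COLSUM_TOL):
            raise ValidationError("normalized confusion entries must lie in [0, 1]")
        sums = arr.sum(axis=0)
        degenerate = sums == 0.0
        bad = ~degenerate & (np.abs(sums - 1.0) > _COLSUM_TOL)
        if np.any(bad):
            j = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"column {j} sums to {sums[j]!r}; every non-degenerate column must sum to 1"
            )
        self.values = arr
        self.m = arr.shape[0]
        self.degenerate_columns = degenerate
        if class_names is None:
            class_names = [s.name for s in default_stages(self.m)]
        if len(class_names) != self.m:
            raise ValidationError("class_names length must match matrix size")
        self.class_names = list(class_names)

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, class_names: Sequence[str] | None = None
    ) -> "ConfusionMatrix":
        """Normalize a raw count matrix column-wise (all-zero columns stay zero)."""
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        sums = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), 0.0)
        return cls(values, class_names)

    def column(self, m: int) -> np.ndarray:
        """Column m as a copy: the score-mass profile of samples predicted as class m."""
        return self.values[:, m].copy()

    def precision(self, m: int) -> float:
        return float(self.values[m, m])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ConfusionMatrix)
            and np.array_equal(self.values, other.values)
            and self.class_names == other.class_names
        )

    def __repr__(self) -> str:
        return f"ConfusionMatrix(m={self.m}, classes={self.class_names})"


@dataclass(frozen=True)
class LabeledSample:
    """One physical sample with its true stage and per-view score vectors."""

    sample_id: str
    true_stage: StageLabel | None
    per_view_scores: Mapping[str, ScoreVector]

    def __post_init__(self) -> None:
        lengths = {v.m for v in self.per_view_scores.values()}
        if len(lengths) > 1:
            raise ValidationError(f"views carry score vectors of mixed lengths {sorted(lengths)}")

    @property
    def views(self) -> list[str]:
        return list(self.per_view_scores)


# ---------------------------------------------------------------------------
# Darknet annotation text
# ---------------------------------------------------------------------------

def read_darknet_labels(path: str | Path, M: int | None = None) -> list[tuple[int, BoundingBox]]:
    """Parse a Darknet annotation file: one ``<class> <cx> <cy> <w> <h>`` per line.

    Coordinates are fractions of image width/height in center format. Line
    order is preserved. Raises :class:`ParseError` naming the offending line
    on malformed input, :class:`ValidationError` when a class index is out of
    range for the given ``M``.
    """
    records: list[tuple[int, BoundingBox]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 5:
            raise ParseError(f"{path}: line {lineno}: expected 5 tokens, got {len(tokens)}")
        try:
            cls = int(tokens[0])
            coords = [float(t) for t in tokens[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        if cls < 0 or (M is not None and cls >= M):
            raise ValidationError(f"{path}: line {lineno}: class index {cls} out of range")
        records.append((cls, BoundingBox(*coords)))
    return records


def write_darknet_labels(records: Iterable[tuple[int, BoundingBox]], path: str | Path) -> None:
    lines = [f"{c} {b.cx!r} {b.cy!r} {b.w!r} {b.h!r}" for c, b in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Confusion-matrix CSV
# ---------------------------------------------------------------------------

def read_confusion_csv(path: str | Path, raw_counts: bool = False) -> ConfusionMatrix:
    """Read a confusion matrix CSV: header of M class names, M rows of M reals.

    The default dialect is column-normalized and validated; with
    ``raw_counts=True`` the body holds unnormalized counts which are
    column-normalized on load.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    body = df.to_numpy(dtype=float)
    if body.shape[0] != body.shape[1]:
        raise ValidationError(
            f"{path}: confusion body must be square, got {body.shape[0]}x{body.shape[1]}"
        )
    names = [str(c) for c in df.columns]
    if raw_counts:
        return ConfusionMatrix.from_counts(body, names)
    return ConfusionMatrix(body, names)


def write_confusion_csv(matrix: ConfusionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.class_names)
    # 17 significant digits: lossless float round-trip through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Detections JSON
# ---------------------------------------------------------------------------

def write_detections_json(
    detections: Sequence[Detection],
    path: str | Path,
    class_names: Sequence[str] | None = None,
) -> None:
    """Serialize detections; floats use shortest exact repr so round-trips are lossless."""
    lengths = {d.scores.m for d in detections}
    if len(lengths) > 1:
        raise ValidationError(f"detections carry score vectors of mixed lengths {sorted(lengths)}")
    M = lengths.pop() if lengths else None
    if class_names is None and M is not None:
        class_names = [s.name for s in default_stages(M)]
    payload = [
        {
            "sample_id": d.sample_id,
            "view": d.view,
            "box": {"cx": d.box.cx, "cy": d.box.cy, "w": d.box.w, "h": d.box.h},
            "confidence": d.confidence,
            "scores": d.scores.scores.tolist(),
            "class_names": list(class_names) if class_names is not None else [],
        }
        for d in detections
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_detections_json(path: str | Path) -> list[Detection]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(payload, list):
        raise ParseError(f"{path}: top level must be a list of detection records")
    out = []
    for rec in payload:
        out.append(
            Detection(
                box=BoundingBox(**rec["box"]),
                confidence=float(rec["confidence"]),
                scores=ScoreVector(np.asarray(rec["scores"], dtype=float)),
                view=str(rec.get("view", "")),
                sample_id=str(rec.get("sample_id", "")),
            )
        )
    lengths = {d.scores.m for d in out}
    if len(lengths) > 1:
        raise ValidationError(f"{path}: mixed score-vector lengths {sorted(lengths)}")
    return out


# ---------------------------------------------------------------------------
# Label CSV and multi-view sample JSON
# ---------------------------------------------------------------------------

def write_labels_csv(labels: Mapping[str, StageLabel], path: str | Path) -> None:
    """Write ``sample_id,stage_name`` rows (insertion order preserved)."""
    df = pd.DataFrame(
        {"sample_id": list(labels), "stage_name": [s.name for s in labels.values()]}
    )
    df.to_csv(path, index=False)


def read_labels_csv(
    path: str | Path, stages: Sequence[StageLabel] | None = None
) -> dict[str, StageLabel]:
    df = pd.read_csv(path, dtype=str)
    missing = {"sample_id", "stage_name"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if stages is None:
        stages = default_stages()
    by_name = {s.name: s for s in stages}
    out: dict[str, StageLabel] = {}
    for _, row in df.iterrows():
        name = row["stage_name"]
        if name not in by_name:
            raise ValidationError(f"{path}: unknown stage name {name!r}")
        out[str(row["sample_id"])] = by_name[name]
    return out


def write_samples_json(
    samples: Sequence[LabeledSample],
    path: str | Path,
    class_names: Sequence[str] | None = None,
) -> None:
    """Serialize multi-view labeled samples (true stage optional, per-view scores)."""
    lengths = {v.m for s in samples for v in s.per_view_scores.values()}
    if len(lengths) > 1:
        raise ValidationError(f"samples carry score vectors of mixed lengths {sorted(lengths)}")
    M = lengths.pop() if lengths else None
    if class_names is None and M is not None:
        class_names = [s.name for s in default_stages(M)]
    payload = {
        "class_names": list(class_names) if class_names is not None else [],
        "samples": [
            {
                "sample_id": s.sample_id,
                "true_stage": s.true_stage.name if s.true_stage is not None else None,
                "scores": {v: sv.scores.tolist() for v, sv in s.per_view_scores.items()},
            }
            for s in samples
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_samples_json(path: str | Path) -> tuple[list[LabeledSample], list[str]]:
    """Returns (samples, class_names)."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    names = [str(n) for n in payload.get("class_names", [])]
    stages = {n: StageLabel(i, n) for i, n in enumerate(names)}
    samples = []
    for rec in payload["samples"]:
        true_name = rec.get("true_stage")
        true_stage = stages.get(true_name) if true_name is not None else None
        if true_name is not None and true_stage is None:
            raise ValidationError(f"{path}: unknown stage name {true_name!r}")
        samples.append(
            LabeledSample(
                sample_id=str(rec["sample_id"]),
                true_stage=true_stage,
                per_view_scores={
                    str(v): ScoreVector(np.asarray(sc, dtype=float))
                    for v, sc in rec["scores"].items()
                },
            )
        )
    return samples, names
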