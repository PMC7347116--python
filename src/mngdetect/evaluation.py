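"""Object-level evaluation: detection-annotation matching, confusion counts,
precision / recall / F1, FP:FN ratios, and cross-fold aggregates.

True positives are reference MNGs successfully identified by the detector;
false negatives are reference MNGs the detector missed; false positives are
detections with no matching reference MNG. F1 is the harmonic mean of
precision and recall. Matching is one-to-one: a detection covering two
annotations credits one true positive and leaves one annotation unmatched.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean as _mean
from typing import Sequence

import numpy as np

from .postprocess import DetectionSet
from .slides import MNGAnnotation, rasterize_annotations

__all__ = [
    "ConfusionCounts",
    "EvaluationResult",
    "UndefinedMetricError",
    "match_detections",
    "precision_recall_f1",
    "fp_fn_ratio",
    "aggregate",
]


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric is undefined (e.g. no objects at all)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class EvaluationResult:
    precision: float
    recall: float
    f1: float


def match_detections(
    detections: DetectionSet,
    annotations: Sequence[MNGAnnotation],
    shape: tuple[int, int],
    min_overlap: int = 1,
    ann_masks: list[np.ndarray] | None = None,
) -> ConfusionCounts:
    """One-to-one matching between detections and annotations.

    A (detection, annotation) pair is a candidate when the detection's pixel
    set overlaps the annotation's filled polygon by at least ``min_overlap``
    pixels, or the detection centroid lies inside the polygon. True positives
    are the maximum-cardinality one-to-one matching over the candidate graph
    (computed exactly), so a detection straddling two annotations still
    credits only one of them. The resulting counts are deterministic: they
    depend only on the matching size, never on tie-breaking.

    ``shape`` is the (height, width) of the image both refer to.
    ``ann_masks`` optionally supplies precomputed per-annotation boolean
    masks (callers evaluating many cutoff combinations cache these).
    """
    h, w = shape
    if ann_masks is None:
        ann_masks = [
            rasterize_annotations([ann], (h, w)).pixels.astype(bool)
            for ann in annotations
        ]

    candidates = []  # (overlap, det_idx, ann_idx)
    for di, region in enumerate(detections.regions):
        xs = region.pixel_set[:, 0]
        ys = region.pixel_set[:, 1]
        ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        cx, cy = region.centroid
        icx, icy = int(round(cx)), int(round(cy))
        for ai, amask in enumerate(ann_masks):
            overlap = int(amask[ys[ok], xs[ok]].sum())
            centroid_in = (
                0 <= icx < w and 0 <= icy < h and bool(amask[icy, icx])
            )
            if overlap >= min_overlap or centroid_in:
                candidates.append((overlap, di, ai))

    if candidates and annotations:
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import maximum_bipartite_matching

        rows = [di for _, di, _ in candidates]
        cols = [ai for _, _, ai in candidates]
        graph = csr_matrix(
            (np.ones(len(candidates)), (rows, cols)),
            shape=(len(detections.regions), len(annotations)),
        )
        matching = maximum_bipartite_matching(graph, perm_type="column")
        tp = int((matching >= 0).sum())
    else:
        tp = 0
    return ConfusionCounts(
        tp=tp,
        fp=len(detections.regions) - tp,
        fn=len(annotations) - tp,
    )


def precision_recall_f1(counts: ConfusionCounts) -> EvaluationResult:
    """precision = tp/(tp+fp), recall = tp/(tp+fn), F1 = 2pr/(p+r).

    With tp = 0 but some fp or fn present, all three metrics are 0. With no
    objects at all the metrics are undefined and an error is raised rather
    than silently reporting 0.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp == fp == fn == 0:
        raise UndefinedMetricError(
            "precision/recall/F1 undefined: no detections and no annotations"
        )
    if tp == 0:
        return EvaluationResult(0.0, 0.0, 0.0)
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return EvaluationResult(p, r, 2 * p * r / (p + r))


def fp_fn_ratio(counts: ConfusionCounts) -> float:
    """False-positive to false-negative ratio, fp/fn."""
    if counts.fn == 0:
        raise UndefinedMetricError("FP:FN ratio undefined when fn = 0")
    return counts.fp / counts.fn


def aggregate(values: Sequence[float]) -> tuple[float, float | None]:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    The standard deviation is None for a single value.
    """
    if len(values) == 0:
        raise ValueError("cannot aggregate an empty list")
    m = _mean(values)
    if len(values) < 2:
        return float(m), None
    sd = float(np.std(values, ddof=1))
    return float(m), sd
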