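"""Detection and counting metrics.

Detection quality is average precision at IoU >= 0.5 (single class, so mAP
equals AP): detections are greedily matched to ground truth in descending
score order, the precision-recall curve is traced over all score cuts, and
AP is the area under the monotone precision envelope (all-point
interpolation).  Count agreement between predicted and true per-image object
counts is summarised by Pearson's r and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .geometry import Box, ScoredBox, iou

__all__ = [
    "MatchResult",
    "match_detections",
    "precision_recall",
    "average_precision",
    "evaluate_detections",
    "pearson_r",
    "rmse",
    "density_counts",
]


@dataclass(frozen=True, slots=True)
class MatchResult:
    """Per-detection TP/FP flags (aligned with ``scores``) plus the FN count."""

    scores: tuple[float, ...]
    is_tp: tuple[bool, ...]
    n_fn: int
    iou_threshold: float = 0.5

    @property
    def n_tp(self) -> int:
        return sum(self.is_tp)

    @property
    def n_fp(self) -> int:
        return len(self.is_tp) - self.n_tp

    @property
    def n_gt(self) -> int:
        return self.n_tp + self.n_fn


def match_detections(
    dets: Sequence[ScoredBox], gts: Sequence[Box], iou_threshold: float = 0.5
) -> MatchResult:
    """Greedy score-ordered matching: each detection claims the unmatched
    ground-truth box of highest IoU if that IoU >= threshold, else it is a
    false positive; each ground truth is matched at most once and duplicates
    on an already-claimed box count as false positives.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    matched = [False] * len(gts)
    scores: list[float] = []
    flags: list[bool] = []
    for i in order:
        d = dets[i]
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if matched[j]:
                continue
            v = iou(d.box, g)
            if v > best_iou:
                best_iou, best_j = v, j
        ok = best_j >= 0 and best_iou >= iou_threshold
        if ok:
            matched[best_j] = True
        scores.append(d.score)
        flags.append(ok)
    return MatchResult(
        scores=tuple(scores),
        is_tp=tuple(flags),
        n_fn=matched.count(False),
        iou_threshold=iou_threshold,
    )


def precision_recall(
    matches: Iterable[MatchResult],
) -> tuple[np.ndarray, np.ndarray]:
    """Precision/recall at every distinct score cut over a set of images.

    Detections are pooled, sorted by descending score, and the cumulative
    precision = TP/(TP+FP) and recall = TP/(TP+FN) are evaluated once per
    distinct score value (the operating points of the detector).
    Raises ``ValueError`` when there is no ground truth (recall undefined).
    """
    matches = list(matches)
    n_gt = sum(m.n_gt for m in matches)
    if n_gt == 0:
        raise ValueError("precision/recall undefined with zero ground-truth boxes")
    scores = np.concatenate([np.asarray(m.scores, dtype=float) for m in matches]) if matches else np.array([])
    flags = np.concatenate([np.asarray(m.is_tp, dtype=bool) for m in matches]) if matches else np.array([], dtype=bool)
    if scores.size == 0:
        return np.array([]), np.array([])
    order = np.argsort(-scores, kind="stable")
    scores, flags = scores[order], flags[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    # keep only the last entry of each distinct score (the full cut)
    last_of_cut = np.r_[scores[1:] != scores[:-1], True]
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_gt
    return precision[last_of_cut], recall[last_of_cut]


def average_precision(precision: np.ndarray, recall: np.ndarray) -> float:
    """Area under the monotone precision envelope (all-point interpolation).

    Precision is replaced by its running maximum from high recall downwards,
    then integrated over the recall steps.
    """
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    if precision.size == 0:
        return 0.0
    order = np.argsort(recall, kind="stable")
    recall, precision = recall[order], precision[order]
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_r) * envelope))


def evaluate_detections(
    per_image: Iterable[tuple[Sequence[ScoredBox], Sequence[Box]]],
    iou_threshold: float = 0.5,
) -> float:
    """AP@IoU over (detections, ground-truth) pairs for a set of images."""
    matches = [match_detections(d, g, iou_threshold) for d, g in per_image]
    p, r = precision_recall(matches)
    return average_precision(p, r)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation between two count sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson_r needs two equal-length sequences, n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r undefined for a constant sequence")
    return float(np.corrcoef(x, y)[0, 1])


def rmse(x: Sequence[float], y: Sequence[float]) -> float:
    """Root-mean-square error between two count sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("rmse needs two equal-length, non-empty sequences")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def density_counts(
    detections_per_image: Iterable[Sequence[ScoredBox]], score_cut: float = 0.5
) -> list[int]:
    """Per-image predicted object counts at a score threshold."""
    return [
        sum(1 for sb in dets if sb.score >= score_cut)
        for dets in detections_per_image
    ]
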