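"""Image-level uncertainty scoring.

Two families of query scores:

* Click-conditioned metrics over RPF proposal groups — max-variance (``mv``),
  max-entropy (``me``) and their linear combination max-ent-var (``mev``).
  The hypothesis: a model that is confident about an object assigns stable,
  saturated objectness scores to the proposals around it, so high variance or
  high binary entropy within a group flags an uncertain object.  The image
  score is the maximum over its clicks.

* Classical pool-based baselines over final detections — least confidence,
  margin and categorical entropy.

The variance of probabilities is bounded by 0.25 (Bhatia-Davis with support
[0, 1]) while binary entropy is bounded by 1 bit, so the default ``mev``
weights (1, 4) put the two terms on a common [0, 1] scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .geometry import Click, ScoredBox
from .rpf import ProposalGroup

__all__ = [
    "MevWeights",
    "UncertaintyReport",
    "group_variance",
    "group_mean_entropy",
    "u_max_variance",
    "u_max_entropy",
    "u_max_ent_var",
    "baseline_least_confident",
    "baseline_margin",
    "baseline_entropy",
    "detections_to_distributions",
    "select_top_k",
]

MAX_GROUP_VARIANCE = 0.25  # Bhatia-Davis bound for values in [0,1]
MAX_GROUP_ENTROPY = 1.0  # log2(2) bits for a binary outcome

EmptyPolicy = Literal["max", "skip"]


@dataclass(frozen=True, slots=True)
class MevWeights:
    """Coefficients of the entropy and variance terms in the mev score.

    The default (1, 4) rescales the variance term, whose attainable range is
    [0, 0.25], onto the entropy term's [0, 1] range.
    """

    lambda1: float = 1.0
    lambda2: float = 4.0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0 or (self.lambda1 == 0 and self.lambda2 == 0):
            raise ValueError(f"weights must be >= 0 and not both zero: {self!r}")


@dataclass(frozen=True, slots=True)
class UncertaintyReport:
    """One image's uncertainty value, with the per-click breakdown."""

    image_id: str
    method: str
    value: float
    per_click: tuple[float, ...] = ()


def _scores_array(scores: Sequence[float]) -> np.ndarray:
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score group; apply the empty-group policy upstream")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("scores must be probabilities in [0, 1]")
    return arr


def group_variance(scores: Sequence[float]) -> float:
    """Population variance of a group's objectness scores (in [0, 0.25])."""
    arr = _scores_array(scores)
    return float(np.mean((arr - arr.mean()) ** 2))


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    # 0*log2(0) := 0
    out = np.zeros_like(p)
    interior = (p > 0) & (p < 1)
    q = p[interior]
    out[interior] = -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    return out


def group_mean_entropy(scores: Sequence[float]) -> float:
    """Mean binary entropy (bits) of a group's objectness scores (in [0, 1])."""
    arr = _scores_array(scores)
    return float(np.mean(_binary_entropy(arr)))


def _max_over_groups(
    groups: Mapping[Click, ProposalGroup],
    metric,
    empty_value: float,
    empty_policy: EmptyPolicy,
) -> float:
    if not groups:
        raise ValueError("need at least one click group")
    values = []
    for g in groups.values():
        if len(g) == 0:
            if empty_policy == "max":
                values.append(empty_value)
            continue
        values.append(metric(g.scores))
    if not values:  # all groups empty under the skip policy
        return 0.0
    return max(values)


def u_max_variance(
    groups: Mapping[Click, ProposalGroup], empty_policy: EmptyPolicy = "max"
) -> float:
    """Max over clicks of the group score variance.

    Under the default ``empty_policy="max"`` a click whose group survived no
    proposals contributes the metric's maximum 0.25: an object the detector
    proposed nothing for signals maximal ignorance.
    """
    return _max_over_groups(groups, group_variance, MAX_GROUP_VARIANCE, empty_policy)


def u_max_entropy(
    groups: Mapping[Click, ProposalGroup], empty_policy: EmptyPolicy = "max"
) -> float:
    """Max over clicks of the group mean binary entropy (empty group -> 1 bit)."""
    return _max_over_groups(groups, group_mean_entropy, MAX_GROUP_ENTROPY, empty_policy)


def u_max_ent_var(
    groups: Mapping[Click, ProposalGroup],
    weights: MevWeights = MevWeights(),
    empty_policy: EmptyPolicy = "max",
) -> float:
    """lambda1 * max-entropy + lambda2 * max-variance."""
    return weights.lambda1 * u_max_entropy(groups, empty_policy) + weights.lambda2 * u_max_variance(
        groups, empty_policy
    )


def baseline_least_confident(detections: Sequence[ScoredBox]) -> float:
    """1 - (highest detection probability); 1.0 for an empty image."""
    if not detections:
        return 1.0
    return 1.0 - max(sb.score for sb in detections)


def detections_to_distributions(
    detections: Sequence[ScoredBox],
) -> list[tuple[float, float]]:
    """Single-class detections as per-box (object, background) distributions."""
    return [(sb.score, 1.0 - sb.score) for sb in detections]


def baseline_margin(class_distributions: Sequence[Sequence[float]]) -> float:
    """Sum over boxes of (top-1 minus top-2 probability); LOWER = more uncertain.

    An image without detections scores 0.0 (treated as maximally uncertain,
    consistent with the ascending selection direction).
    """
    if not class_distributions:
        warnings.warn("margin on an image with no detections; returning 0.0")
        return 0.0
    total = 0.0
    for dist in class_distributions:
        top = sorted(dist, reverse=True)
        total += top[0] - top[1]
    return total


def baseline_entropy(class_distributions: Sequence[Sequence[float]]) -> float:
    """Sum over boxes of categorical entropy (bits) of the class distribution."""
    if not class_distributions:
        warnings.warn("entropy on an image with no detections; returning 0.0")
        return 0.0
    total = 0.0
    for dist in class_distributions:
        p = np.asarray(dist, dtype=float)
        pos = p[p > 0]
        total += float(-(pos * np.log2(pos)).sum())
    return total


def select_top_k(
    scores: Mapping[str, float], k: int, direction: Literal["desc", "asc"] = "desc"
) -> list[str]:
    """The ``k`` image ids with the most extreme scores, ties broken by id.

    ``desc`` picks the highest scores (lc/ent/mv/me/mev), ``asc`` the lowest
    (margin).  If ``k`` exceeds the pool, all ids are returned with a warning.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(scores):
        warnings.warn(f"requested k={k} > pool size {len(scores)}; taking all")
        k = len(scores)
    sign = -1.0 if direction == "desc" else 1.0
    ranked = sorted(scores, key=lambda i: (sign * scores[i], i))
    return ranked[:k]
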