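"""Region Proposal Filtering (RPF).

Given an image's centre clicks (weak labels) and its region proposals, RPF
keeps, per click, only the proposals plausibly enclosing that object:

1. the proposal must contain the click location;
2. its centre must lie within ``epsilon`` pixels of the click;
3. its area must not exceed ``alpha`` square pixels (inclusive);
4. it must not contain any *other* click of the same image — a proposal
   covering two objects at once is dropped entirely, never duplicated.

``epsilon`` and ``alpha`` are estimated from the initial strong-labeled pool:
``epsilon`` as a low percentile of the nearest-neighbour distance between box
centres (so a retained proposal rarely reaches a second object), ``alpha`` as
a high percentile of box areas (so the true box is rarely filtered out).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data import ImageRecord
from .geometry import (
    Click,
    ScoredBox,
    box_area,
    box_center,
    center_to_point_distance,
    contains_point,
)

__all__ = [
    "RpfParams",
    "ProposalGroup",
    "filter_and_group",
    "estimate_epsilon",
    "estimate_alpha",
]


@dataclass(frozen=True, slots=True)
class RpfParams:
    """RPF hyperparameters: centre-distance bound (px) and area cap (px^2)."""

    epsilon: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.epsilon > 0 and self.alpha > 0):
            raise ValueError(f"epsilon and alpha must be > 0, got {self!r}")


@dataclass(frozen=True, slots=True)
class ProposalGroup:
    """The proposals surviving RPF for one click, with their scores."""

    click: Click
    boxes: tuple[ScoredBox, ...] = field(default=())

    @property
    def scores(self) -> tuple[float, ...]:
        return tuple(sb.score for sb in self.boxes)

    def __len__(self) -> int:
        return len(self.boxes)


def filter_and_group(
    image: ImageRecord,
    proposals: Sequence[ScoredBox] | None = None,
    params: RpfParams | None = None,
) -> dict[Click, ProposalGroup]:
    """Apply the four RPF conditions and group survivors per click.

    ``proposals`` defaults to ``image.proposals``.  Groups may be empty (the
    detector proposed nothing near that object); every proposal lands in at
    most one group because a proposal containing a second click is dropped.

    Raises ``ValueError`` on an image without clicks — RPF is only defined
    for weakly annotated images.
    """
    if params is None:
        raise TypeError("filter_and_group requires RpfParams")
    if not image.clicks:
        raise ValueError(
            f"image {image.id!r} has no clicks; RPF needs Type-1 annotations"
        )
    if proposals is None:
        proposals = image.proposals

    clicks = list(image.clicks)
    kept: dict[Click, list[ScoredBox]] = {c: [] for c in clicks}
    for sb in proposals:
        b = sb.box
        if box_area(b) > params.alpha:
            continue
        containing = [c for c in clicks if contains_point(b, c)]
        if len(containing) != 1:
            continue  # contains no click, or more than one (other-weak-label filter)
        c = containing[0]
        if center_to_point_distance(b, c) <= params.epsilon:
            kept[c].append(sb)
    return {c: ProposalGroup(c, tuple(boxes)) for c, boxes in kept.items()}


def _round_nearest_10(x: float) -> float:
    return 10.0 * round(x / 10.0)


def _round_2_sig_figs(x: float) -> float:
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return float(round(x, -(exponent - 1)))


_ROUNDERS = {
    "nearest-10": _round_nearest_10,
    "2-significant-figures": _round_2_sig_figs,
    "none": lambda x: float(x),
}


def _nearest_neighbour_center_distances(images: Iterable[ImageRecord]) -> np.ndarray:
    """Per box, the distance to the nearest other box centre in its image."""
    dists: list[float] = []
    for img in images:
        centers = np.asarray([box_center(b) for b in img.gt_boxes], dtype=float)
        if len(centers) < 2:
            continue
        diff = centers[:, None, :] - centers[None, :, :]
        d = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(d, np.inf)
        dists.extend(d.min(axis=1))
    return np.asarray(dists, dtype=float)


def estimate_epsilon(
    gt_images: Iterable[ImageRecord],
    percentile: float = 20.0,
    rounding: str = "nearest-10",
) -> float:
    """Estimate the centre-distance bound from strong-labeled images.

    Takes the given percentile (linear interpolation) of the distribution of
    nearest-neighbour distances between box centres, then rounds (default:
    to the nearest multiple of 10).  A low percentile keeps retained
    proposals from straddling two objects most of the time.
    """
    dists = _nearest_neighbour_center_distances(gt_images)
    if dists.size == 0:
        raise ValueError(
            "estimating epsilon needs at least one image with >= 2 objects"
        )
    raw = float(np.percentile(dists, percentile))
    return _ROUNDERS[rounding](raw)


def estimate_alpha(
    gt_images: Iterable[ImageRecord],
    percentile: float = 90.0,
    rounding: str = "2-significant-figures",
) -> float:
    """Estimate the area cap from strong-labeled images.

    Takes the given percentile of all ground-truth box areas, then rounds
    (default: to two significant figures).  A high percentile means the true
    box itself is rarely larger than the cap.
    """
    areas = np.asarray(
        [box_area(b) for img in gt_images for b in img.gt_boxes], dtype=float
    )
    if areas.size == 0:
        raise ValueError("estimating alpha needs at least one ground-truth box")
    raw = float(np.percentile(areas, percentile))
    return _ROUNDERS[rounding](raw)
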