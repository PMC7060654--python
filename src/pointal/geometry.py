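"""Axis-aligned box and click primitives.

Coordinates are continuous pixels with the origin at the top-left corner,
x increasing rightwards and y downwards.  Boxes are half-open,
``[xmin, xmax) x [ymin, ymax)``, so shared edges between adjacent boxes are
never double-counted and a point lies in at most one cell of a tiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Box",
    "Click",
    "ScoredBox",
    "box_area",
    "box_center",
    "contains_point",
    "center_to_point_distance",
    "iou",
]


@dataclass(frozen=True, slots=True)
class Box:
    """A bounding box ``[xmin, xmax) x [ymin, ymax)`` in pixel coordinates.

    Degenerate (zero-area) and negative-coordinate boxes are rejected at
    construction time.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        for v in (self.xmin, self.ymin, self.xmax, self.ymax):
            if not math.isfinite(v):
                raise ValueError(f"box coordinates must be finite, got {self!r}")
            if v < 0:
                raise ValueError(f"box coordinates must be >= 0, got {self!r}")
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"box must satisfy xmin < xmax and ymin < ymax, got {self!r}"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin


@dataclass(frozen=True, slots=True)
class Click:
    """An object-centre click (a Type-1 / weak annotation)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"click coordinates must be finite, got {self!r}")


@dataclass(frozen=True, slots=True)
class ScoredBox:
    """A box with an objectness / detection probability in ``[0, 1]``.

    Used both for region proposals (RPN objectness serves as the binary
    object probability) and for final detections.
    """

    box: Box
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


def box_area(b: Box) -> float:
    """Area of ``b`` in square pixels."""
    return (b.xmax - b.xmin) * (b.ymax - b.ymin)


def box_center(b: Box) -> tuple[float, float]:
    """Centre point of ``b``."""
    return (0.5 * (b.xmin + b.xmax), 0.5 * (b.ymin + b.ymax))


def contains_point(b: Box, c: Click) -> bool:
    """Whether the half-open box ``b`` contains the click location."""
    return b.xmin <= c.x < b.xmax and b.ymin <= c.y < b.ymax


def center_to_point_distance(b: Box, c: Click) -> float:
    """Euclidean distance from the centre of ``b`` to the click, in pixels."""
    cx, cy = box_center(b)
    return math.hypot(cx - c.x, cy - c.y)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 for disjoint boxes."""
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = box_area(a) + box_area(b) - inter
    return inter / union
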