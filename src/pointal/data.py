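"""Shared data model: images, per-object difficulty, and the three AL pools."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .geometry import Box, Click, ScoredBox

__all__ = ["ObjectAttributes", "ImageRecord", "PoolState"]


@dataclass(frozen=True, slots=True)
class ObjectAttributes:
    """Per-object difficulty proxies, each in ``[0, 1]``.

    ``blur``, ``occlusion`` and ``lighting`` stand in for the visual
    conditions that make crop heads hard to detect in field imagery.
    ``overall`` (their mean) is the scalar difficulty the simulated
    detector consumes.
    """

    blur: float = 0.0
    occlusion: float = 0.0
    lighting: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.blur, self.occlusion, self.lighting):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"difficulty attributes must lie in [0,1]: {self!r}")

    @property
    def overall(self) -> float:
        return (self.blur + self.occlusion + self.lighting) / 3.0


@dataclass(slots=True)
class ImageRecord:
    """One image's identity, geometry and (possibly partial) annotations.

    ``clicks`` are Type-1 weak labels, ``gt_boxes`` Type-2 strong labels.
    ``proposals`` and ``detections`` cache the most recent detector output.
    ``difficulties`` (parallel to ``gt_boxes``) is only populated by the
    synthetic scene generator.
    """

    id: str
    width: float
    height: float
    clicks: list[Click] = field(default_factory=list)
    gt_boxes: list[Box] = field(default_factory=list)
    proposals: list[ScoredBox] = field(default_factory=list)
    detections: list[ScoredBox] = field(default_factory=list)
    difficulties: list[ObjectAttributes] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"image {self.id!r}: non-positive size")
        for c in self.clicks:
            self._check_inside(c.x, c.y, "click")
        for b in self.gt_boxes:
            self._check_inside(b.xmin, b.ymin, "box")
            if b.xmax > self.width or b.ymax > self.height:
                raise ValueError(
                    f"image {self.id!r}: box {b} exceeds image bounds "
                    f"({self.width}x{self.height})"
                )

    def _check_inside(self, x: float, y: float, what: str) -> None:
        if not (0 <= x <= self.width and 0 <= y <= self.height):
            raise ValueError(
                f"image {self.id!r}: {what} at ({x}, {y}) outside "
                f"[0,{self.width}]x[0,{self.height}]"
            )

    @property
    def difficulty(self) -> float:
        """Mean per-object difficulty; 0 for images without attributes."""
        if not self.difficulties:
            return 0.0
        return sum(a.overall for a in self.difficulties) / len(self.difficulties)


def _as_frozenset(ids: Iterable[str]) -> frozenset[str]:
    return ids if isinstance(ids, frozenset) else frozenset(ids)


@dataclass(frozen=True, slots=True)
class PoolState:
    """The disjoint labeled / weakly-labeled / unlabeled pools.

    ``labeled_ids`` is the strong pool the detector trains on,
    ``weak_ids`` holds images with clicks only, ``unlabeled_ids`` the rest.
    The union is constant across an experiment.
    """

    labeled_ids: frozenset[str]
    weak_ids: frozenset[str]
    unlabeled_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labeled_ids", _as_frozenset(self.labeled_ids))
        object.__setattr__(self, "weak_ids", _as_frozenset(self.weak_ids))
        object.__setattr__(self, "unlabeled_ids", _as_frozenset(self.unlabeled_ids))
        if (
            self.labeled_ids & self.weak_ids
            or self.labeled_ids & self.unlabeled_ids
            or self.weak_ids & self.unlabeled_ids
        ):
            raise ValueError("pools must be pairwise disjoint")

    @property
    def all_ids(self) -> frozenset[str]:
        return self.labeled_ids | self.weak_ids | self.unlabeled_ids

    def move_to_weak(self, ids: Iterable[str]) -> "PoolState":
        ids = frozenset(ids)
        if not ids <= self.unlabeled_ids:
            raise ValueError("can only weak-label ids from the unlabeled pool")
        return PoolState(self.labeled_ids, self.weak_ids | ids, self.unlabeled_ids - ids)

    def move_to_labeled(self, ids: Iterable[str], *, from_weak: bool = True) -> "PoolState":
        ids = frozenset(ids)
        if from_weak:
            if not ids <= self.weak_ids:
                raise ValueError("can only strong-label ids from the weak pool")
            return PoolState(self.labeled_ids | ids, self.weak_ids - ids, self.unlabeled_ids)
        if not ids <= self.unlabeled_ids:
            raise ValueError("can only strong-label ids from the unlabeled pool")
        return PoolState(self.labeled_ids | ids, self.weak_ids, self.unlabeled_ids - ids)

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.labeled_ids), len(self.weak_ids), len(self.unlabeled_ids))


Dataset = Mapping[str, ImageRecord]
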