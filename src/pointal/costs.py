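"""Annotation-time accounting for weak (click) and strong (box) labels.

Unit times are ImageNet crowd-sourcing medians: 25.5 s to draw one box,
9.0 s to verify it, 7.8 s to check an image for further objects, 3.0 s to
click an object's centre.  Hence a Type-1 (weak) label costs
``7.8 s/image + 3.0 s/object`` and a Type-2 (strong) label costs
``25.5 + 9.0 = 34.5 s/object`` — the per-image check is not repeated because
it already happened when the clicks were collected.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CostConstants",
    "DEFAULT_COSTS",
    "baseline_batch_time",
    "proposed_batch_time",
    "seconds_to_hours",
]


@dataclass(frozen=True, slots=True)
class CostConstants:
    """Per-action annotation times in seconds."""

    box_draw: float = 25.5
    box_verify: float = 9.0
    image_check: float = 7.8
    center_click: float = 3.0

    def __post_init__(self) -> None:
        for v in (self.box_draw, self.box_verify, self.image_check, self.center_click):
            if v <= 0:
                raise ValueError(f"cost constants must be > 0: {self!r}")

    @property
    def type1_per_object(self) -> float:
        return self.center_click

    @property
    def type1_per_image(self) -> float:
        return self.image_check

    @property
    def type2_per_object(self) -> float:
        return self.box_draw + self.box_verify


DEFAULT_COSTS = CostConstants()


def _check_counts(**counts: int) -> None:
    for name, v in counts.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")


def baseline_batch_time(
    q: int, b_q: int, constants: CostConstants = DEFAULT_COSTS
) -> float:
    """Seconds to strong-label a batch of ``q`` images holding ``b_q`` objects
    under standard pool-based AL (no prior weak labels):
    ``image_check * q + (draw + verify) * b_q``.
    """
    _check_counts(q=q, b_q=b_q)
    return constants.image_check * q + constants.type2_per_object * b_q


def proposed_batch_time(
    q_w: int,
    b_qw: int,
    b_qs: int,
    constants: CostConstants = DEFAULT_COSTS,
) -> float:
    """Seconds for a point-supervision batch: ``q_w`` images weak-labeled with
    ``b_qw`` clicked objects, plus ``b_qs`` objects promoted to strong labels:
    ``image_check * q_w + (draw + verify) * b_qs + click * b_qw``.

    The per-image check and per-object click are charged once, at weak-label
    time; promotion to a strong label later adds only the box time.
    """
    _check_counts(q_w=q_w, b_qw=b_qw, b_qs=b_qs)
    return (
        constants.image_check * q_w
        + constants.type2_per_object * b_qs
        + constants.center_click * b_qw
    )


def seconds_to_hours(seconds: float) -> float:
    return seconds / 3600.0
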