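"""Experiment configuration: validated, YAML round-trippable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ExperimentConfig", "load_config", "save_config"]

_STAGE1 = ("rand", "lc", "mar", "ent")
_STAGE2 = ("mv", "me", "mev", "none")


@dataclass(slots=True)
class ExperimentConfig:
    """Everything a run needs besides the dataset and detector objects.

    ``stage2="none"`` selects standard pool-based AL (no weak pool); any
    other value runs the point-supervision pipeline and the method is named
    ``{stage1}_{stage2}`` (e.g. ``ent_mev``).
    """

    # synthetic dataset
    n_images: int = 300
    scene_seed: int = 0
    # budgets
    b_weak: int = 20
    b_strong: int = 10
    initial_labeled: int = 50
    max_episodes: int = 10
    # query method
    stage1: str = "rand"
    stage2: str = "mev"
    lambda1: float = 1.0
    lambda2: float = 4.0
    empty_group_policy: str = "max"
    # RPF
    rpf_epsilon: float | None = None
    rpf_alpha: float | None = None
    rpf_auto_estimate: bool = True
    # evaluation / misc
    test_fraction: float = 0.4
    iou_threshold: float = 0.5
    click_jitter_sd: float = 3.0
    seed: int = 0
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.stage1 not in _STAGE1:
            raise ValueError(f"stage1 must be one of {_STAGE1}, got {self.stage1!r}")
        if self.stage2 not in _STAGE2:
            raise ValueError(f"stage2 must be one of {_STAGE2}, got {self.stage2!r}")
        if not (0 < self.b_strong <= self.b_weak):
            raise ValueError("budgets must satisfy 0 < b_strong <= b_weak")
        if self.initial_labeled < 1:
            raise ValueError("initial_labeled must be >= 1")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        if not self.rpf_auto_estimate and (
            self.rpf_epsilon is None or self.rpf_alpha is None
        ):
            raise ValueError("rpf_epsilon/rpf_alpha required when auto-estimate is off")

    @property
    def method_name(self) -> str:
        return self.stage1 if self.stage2 == "none" else f"{self.stage1}_{self.stage2}"

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return ExperimentConfig.from_dict(data)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
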