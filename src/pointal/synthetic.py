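"""Synthetic crop scenes, a click oracle, and a simulated two-stage detector.

Real panicle datasets (wheat ears, sorghum heads) are dense single-class
scenes: hundreds of 500x500 tiles, each holding tens of small objects whose
detectability varies with blur, occlusion and lighting.  This module emulates
that structure *at the box/score level* — no pixels are rendered — so the
whole active-learning stack can be exercised end to end on a laptop.

The simulated detector implements the two-stage contract (train / propose /
detect).  Its single latent quantity is a competence ``c = m / (m + kappa)``
where ``m`` is the accumulated training mass of the strong-labeled pool;
hard images carry extra mass (``1 + beta * difficulty``), so *which* images
get labeled matters, not just how many.  Per object, competence is discounted
by difficulty, ``c_obj = c * (1 - gamma * difficulty)``.  Proposal objectness
scores are Beta-distributed with mean ``0.5 + 0.5 * c_obj`` and concentration
growing with ``c_obj``: an untrained model scores proposals near-uniformly
(high entropy, high variance) while a competent one saturates towards 1 with
vanishing spread — exactly the behaviour the click-conditioned uncertainty
metrics are designed to detect.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data import ImageRecord, ObjectAttributes
from .geometry import Box, Click, ScoredBox, box_center

__all__ = [
    "SceneParams",
    "SimDetectorParams",
    "SimModelState",
    "SimulatedDetector",
    "generate_scene",
    "generate_pool",
    "simulate_clicks",
    "lognormal_area_percentile",
]


@dataclass(frozen=True, slots=True)
class SceneParams:
    """Parameters of a synthetic crop tile.

    ``side_log_mean``/``side_log_sd`` parametrise a log-normal over box side
    lengths (default median 40 px — small objects on a 500 px tile, like
    wheat ears after 2x downsampling).  Object counts span 5-60 per tile,
    reflecting that field images routinely hold tens of heads.  Difficulty
    attributes are Beta(2, 6) draws, i.e. most objects are easy, a tail is
    hard.  ``min_separation`` keeps box centres apart so clicks are
    resolvable.
    """

    width: float = 500.0
    height: float = 500.0
    n_objects_range: tuple[int, int] = (5, 60)
    side_log_mean: float = float(np.log(40.0))
    side_log_sd: float = 0.25
    min_side: float = 8.0
    max_side: float = 160.0
    min_separation: float = 25.0
    difficulty_beta: tuple[float, float] = (2.0, 6.0)
    difficulty_object_sd: float = 0.08

    def __post_init__(self) -> None:
        lo, hi = self.n_objects_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad object count range {self.n_objects_range}")
        if self.min_separation < 0 or self.min_side <= 0:
            raise ValueError(f"bad geometry params: {self!r}")


def lognormal_area_percentile(params: SceneParams, q: float) -> float:
    """Analytic ``q``-th percentile of box area under ``params``.

    Width and height are independent log-normals, so their product is
    log-normal with doubled log-mean and sqrt(2)-scaled log-sd.  Ignores the
    side clipping, which is mild at the defaults.
    """
    from scipy.stats import norm  # local import keeps scipy optional at import time

    z = norm.ppf(q / 100.0)
    mu = 2.0 * params.side_log_mean
    sd = float(np.sqrt(2.0)) * params.side_log_sd
    return float(np.exp(mu + sd * z))


def _draw_side(rng: np.random.Generator, params: SceneParams, n: int) -> np.ndarray:
    s = rng.lognormal(params.side_log_mean, params.side_log_sd, size=n)
    return np.clip(s, params.min_side, params.max_side)


def generate_scene(
    params: SceneParams, seed: int | np.random.SeedSequence, image_id: str = "scene-0"
) -> ImageRecord:
    """One reproducible synthetic tile with boxes and per-object difficulty.

    Centres are placed by rejection sampling under the minimum-separation
    constraint; if the tile cannot fit the drawn count, fewer objects are
    placed and a warning is emitted.

    Difficulty is hierarchical: each image draws a scene-level base per
    attribute (blur, occlusion and lighting are largely properties of the
    whole photograph), and each object perturbs that base — so images differ
    meaningfully in overall difficulty, as real field tiles do.
    """
    rng = np.random.default_rng(seed)
    lo, hi = params.n_objects_range
    n_target = int(rng.integers(lo, hi + 1))

    centers: list[tuple[float, float]] = []
    widths: list[float] = []
    heights: list[float] = []
    attempts = 0
    max_attempts = 200 * n_target
    while len(centers) < n_target and attempts < max_attempts:
        attempts += 1
        w, h = _draw_side(rng, params, 2)
        w = min(w, params.width - 2.0)
        h = min(h, params.height - 2.0)
        cx = rng.uniform(w / 2, params.width - w / 2)
        cy = rng.uniform(h / 2, params.height - h / 2)
        if any(
            np.hypot(cx - ox, cy - oy) < params.min_separation for ox, oy in centers
        ):
            continue
        centers.append((cx, cy))
        widths.append(w)
        heights.append(h)
    if len(centers) < n_target:
        import warnings

        warnings.warn(
            f"{image_id}: placed {len(centers)}/{n_target} objects "
            f"(separation {params.min_separation} px infeasible)"
        )

    boxes = [
        Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        for (cx, cy), w, h in zip(centers, widths, heights)
    ]
    a, b = params.difficulty_beta
    scene_base = rng.beta(a, b, size=3)
    attrs = [
        ObjectAttributes(
            *np.clip(
                scene_base + rng.normal(0.0, params.difficulty_object_sd, size=3),
                0.0,
                1.0,
            )
        )
        for _ in boxes
    ]
    return ImageRecord(
        id=image_id,
        width=params.width,
        height=params.height,
        gt_boxes=boxes,
        difficulties=attrs,
    )


def generate_pool(
    n_images: int,
    params: SceneParams = SceneParams(),
    seed: int = 0,
    id_prefix: str = "img",
) -> dict[str, ImageRecord]:
    """A dict of ``n_images`` independent scenes keyed by zero-padded id."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_images)
    width = len(str(max(n_images - 1, 0)))
    pool = {}
    for i, child in enumerate(children):
        iid = f"{id_prefix}-{i:0{width}d}"
        pool[iid] = generate_scene(params, child, image_id=iid)
    return pool


def simulate_clicks(
    gt_boxes: Sequence[Box],
    jitter_sd: float = 3.0,
    seed: int | np.random.SeedSequence = 0,
) -> list[Click]:
    """The click oracle: one click per box, near its centre.

    Clicks are the box centre plus isotropic Gaussian noise of scale
    ``jitter_sd`` (annotators aim for the centre but miss by a few pixels),
    clamped to stay strictly inside the box so the click always identifies
    its object.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    clicks = []
    for b in gt_boxes:
        cx, cy = box_center(b)
        x = cx + rng.normal(0.0, jitter_sd)
        y = cy + rng.normal(0.0, jitter_sd)
        eps_x = 1e-6 * max(b.width, 1.0)
        eps_y = 1e-6 * max(b.height, 1.0)
        clicks.append(
            Click(
                float(np.clip(x, b.xmin, b.xmax - eps_x)),
                float(np.clip(y, b.ymin, b.ymax - eps_y)),
            )
        )
    return clicks


@dataclass(frozen=True, slots=True)
class SimDetectorParams:
    """Knobs of the simulated detector.

    ``kappa`` sets how much training mass yields competence 0.5 (saturating
    learning curve ``m/(m+kappa)``); ``beta_mass`` is the extra training
    value of hard images; ``gamma`` discounts per-object competence by
    difficulty.  ``proposals_per_object`` (K), the centre/size jitters and
    the score concentration ``nu`` shape the RPN-like proposal clusters;
    background proposals/detections model clutter that fades as the model
    improves.  All values are simulator conventions chosen to make the
    qualitative phenomena of detector training reproducible, not estimates
    of any real crop system.
    """

    kappa: float = 30.0
    beta_mass: float = 2.0
    gamma: float = 0.5
    proposals_per_object: int = 12
    center_jitter_frac: float = 0.10
    size_jitter_sd: float = 0.35
    score_concentration: float = 40.0
    background_rate: float = 4.0
    detect_floor: float = 0.15
    detect_gain: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


@dataclass(frozen=True, slots=True)
class SimModelState:
    """Opaque trained-model state: accumulated training mass."""

    mass: float = 0.0
    n_images: int = 0


class SimulatedDetector:
    """Two-stage detector stand-in honouring the train/propose/detect contract.

    Deterministic: every propose/detect call derives its RNG from
    ``(params.seed, image id, stage)``, so repeated calls with the same model
    state and image give identical output.
    """

    def __init__(self, params: SimDetectorParams = SimDetectorParams()):
        self.params = params

    # -- contract ----------------------------------------------------------
    def train(self, labeled: Iterable[ImageRecord]) -> SimModelState:
        p = self.params
        mass = 0.0
        n = 0
        for img in labeled:
            mass += 1.0 + p.beta_mass * img.difficulty
            n += 1
        return SimModelState(mass=mass, n_images=n)

    def propose(self, model: SimModelState, image: ImageRecord) -> list[ScoredBox]:
        p = self.params
        rng = self._rng(model, image.id, "propose")
        c = self.competence(model)
        out: list[ScoredBox] = []
        for j, b in enumerate(image.gt_boxes):
            c_obj = self._object_competence(c, image, j)
            cx, cy = box_center(b)
            for _ in range(p.proposals_per_object):
                jx = rng.normal(0.0, p.center_jitter_frac * b.width)
                jy = rng.normal(0.0, p.center_jitter_frac * b.height)
                sw = b.width * float(np.exp(rng.normal(0.0, p.size_jitter_sd)))
                sh = b.height * float(np.exp(rng.normal(0.0, p.size_jitter_sd)))
                box = self._clipped_box(image, cx + jx, cy + jy, sw, sh)
                if box is None:
                    continue
                out.append(ScoredBox(box, self._draw_score(rng, c_obj)))
        n_bg = rng.poisson(p.background_rate)
        out.extend(self._background_boxes(rng, image, n_bg, c))
        return out

    def detect(self, model: SimModelState, image: ImageRecord) -> list[ScoredBox]:
        p = self.params
        rng = self._rng(model, image.id, "detect")
        c = self.competence(model)
        out: list[ScoredBox] = []
        for j, b in enumerate(image.gt_boxes):
            c_obj = self._object_competence(c, image, j)
            p_det = float(np.clip(p.detect_floor + p.detect_gain * c_obj, 0.0, 0.98))
            if rng.uniform() >= p_det:
                continue
            jx = rng.normal(0.0, 0.05 * b.width)
            jy = rng.normal(0.0, 0.05 * b.height)
            cx, cy = box_center(b)
            box = self._clipped_box(image, cx + jx, cy + jy, b.width, b.height)
            if box is None:
                continue
            out.append(ScoredBox(box, self._draw_score(rng, c_obj)))
        n_bg = rng.poisson(p.background_rate * (1.0 - c))
        out.extend(self._background_boxes(rng, image, n_bg, c))
        return out

    # -- internals ---------------------------------------------------------
    def competence(self, model: SimModelState) -> float:
        return model.mass / (model.mass + self.params.kappa)

    def _object_competence(self, c: float, image: ImageRecord, j: int) -> float:
        d = image.difficulties[j].overall if j < len(image.difficulties) else 0.0
        return c * (1.0 - self.params.gamma * d)

    def _draw_score(self, rng: np.random.Generator, c_obj: float) -> float:
        mu = float(np.clip(0.5 + 0.5 * c_obj, 0.05, 0.97))
        nu = 2.0 + self.params.score_concentration * c_obj
        a = mu * nu
        b = (1.0 - mu) * nu
        return float(np.clip(rng.beta(a, b), 0.0, 1.0))

    def _background_boxes(
        self, rng: np.random.Generator, image: ImageRecord, n: int, c: float
    ) -> list[ScoredBox]:
        out = []
        for _ in range(n):
            w = rng.uniform(10.0, 0.3 * image.width)
            h = rng.uniform(10.0, 0.3 * image.height)
            cx = rng.uniform(w / 2, image.width - w / 2)
            cy = rng.uniform(h / 2, image.height - h / 2)
            box = self._clipped_box(image, cx, cy, w, h)
            if box is None:
                continue
            score = float(np.clip(rng.beta(1.5, 8.0), 0.0, 1.0))
            out.append(ScoredBox(box, score))
        return out

    @staticmethod
    def _clipped_box(
        image: ImageRecord, cx: float, cy: float, w: float, h: float
    ) -> Box | None:
        xmin = max(0.0, cx - w / 2)
        ymin = max(0.0, cy - h / 2)
        xmax = min(image.width, cx + w / 2)
        ymax = min(image.height, cy + h / 2)
        if xmax - xmin < 1e-6 or ymax - ymin < 1e-6:
            return None
        return Box(xmin, ymin, xmax, ymax)

    def _rng(self, model: SimModelState, image_id: str, stage: str) -> np.random.Generator:
        key = zlib.crc32(f"{stage}|{image_id}".encode())
        mass_key = int(round(model.mass * 1000)) & 0xFFFFFFFF
        return np.random.default_rng(
            np.random.SeedSequence((self.params.seed & 0x7FFFFFFF, key, mass_key))
        )
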