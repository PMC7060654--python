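"""The three-pool active-learning cycle with point supervision.

Each episode of the proposed pipeline:

1. a stage-1 criterion (random / least-confidence / margin / entropy over the
   current detections) queries ``b_weak`` images from the unlabeled pool for
   centre clicks and moves them to the weak pool;
2. the model proposes regions on every weak-pool image (including leftovers
   from earlier episodes), RPF groups the proposals per click, and a stage-2
   metric (mv / me / mev) scores each image;
3. the ``b_strong`` most uncertain weak images receive bounding boxes and
   move to the labeled pool;
4. the detector retrains on the labeled pool and is evaluated on the held-out
   test split;
5. annotation seconds accrue: clicks and the per-image check at weak time,
   box drawing at strong time — Type-1 time is never charged twice.

``stage2="none"`` degrades to standard pool-based AL: ``b_weak`` images per
episode move straight from unlabeled to labeled and costs follow the
no-clicks formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Iterable, Protocol, Sequence

import numpy as np

from .config import ExperimentConfig
from .costs import CostConstants, DEFAULT_COSTS, baseline_batch_time, proposed_batch_time
from .data import Dataset, ImageRecord, PoolState
from .evaluation import evaluate_detections
from .geometry import Click, ScoredBox
from .rpf import RpfParams, estimate_alpha, estimate_epsilon, filter_and_group
from .uncertainty import (
    MevWeights,
    baseline_entropy,
    baseline_least_confident,
    baseline_margin,
    detections_to_distributions,
    select_top_k,
    u_max_ent_var,
    u_max_entropy,
    u_max_variance,
)

__all__ = [
    "Budgets",
    "DetectorContract",
    "EpisodeLog",
    "ExperimentResult",
    "run_episode",
    "run_experiment",
]


@dataclass(frozen=True, slots=True)
class Budgets:
    """Per-episode query budgets and experiment extent."""

    b_weak: int
    b_strong: int
    initial_labeled: int = 50
    max_episodes: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.b_strong <= self.b_weak):
            raise ValueError("budgets must satisfy 0 < b_strong <= b_weak")
        if self.initial_labeled < 1:
            raise ValueError("initial_labeled must be >= 1")
        if self.max_episodes < 0:
            raise ValueError("max_episodes must be >= 0")


class DetectorContract(Protocol):
    """What any detector must provide to drive the loop."""

    def train(self, labeled: Iterable[ImageRecord]) -> Any: ...

    def propose(self, model: Any, image: ImageRecord) -> list[ScoredBox]: ...

    def detect(self, model: Any, image: ImageRecord) -> list[ScoredBox]: ...


ClickOracle = Callable[[ImageRecord, np.random.Generator], list[Click]]


@dataclass(frozen=True, slots=True)
class EpisodeLog:
    """One episode's moves, costs and test performance."""

    episode: int
    method: str
    to_weak: tuple[str, ...]
    to_strong: tuple[str, ...]
    n_labeled: int
    n_weak: int
    n_unlabeled: int
    n_clicks_added: int
    n_boxes_added: int
    episode_seconds: float
    cumulative_seconds: float
    ap: float


@dataclass(frozen=True, slots=True)
class ExperimentResult:
    logs: tuple[EpisodeLog, ...]
    pools: PoolState
    test_ids: tuple[str, ...]
    rpf_params: RpfParams | None
    config: ExperimentConfig


_STAGE1_DESC = {"lc": "desc", "ent": "desc", "mar": "asc"}


def _stage1_scores(
    method: str,
    detector: DetectorContract,
    model: Any,
    dataset: Dataset,
    ids: Iterable[str],
) -> dict[str, float]:
    scores: dict[str, float] = {}
    for iid in ids:
        img = dataset[iid]
        dets = detector.detect(model, img)
        img.detections = list(dets)
        if method == "lc":
            scores[iid] = baseline_least_confident(dets)
        elif method == "mar":
            scores[iid] = baseline_margin(detections_to_distributions(dets))
        elif method == "ent":
            scores[iid] = baseline_entropy(detections_to_distributions(dets))
        else:
            raise ValueError(f"unknown stage-1 criterion {method!r}")
    return scores


def _stage2_score(
    method: str,
    groups,
    weights: MevWeights,
    empty_policy: str,
) -> float:
    if method == "mv":
        return u_max_variance(groups, empty_policy)
    if method == "me":
        return u_max_entropy(groups, empty_policy)
    if method == "mev":
        return u_max_ent_var(groups, weights, empty_policy)
    raise ValueError(f"unknown stage-2 metric {method!r}")


def _select_stage1(
    method: str,
    detector: DetectorContract,
    model: Any,
    dataset: Dataset,
    pool_ids: frozenset[str],
    k: int,
    rng: np.random.Generator,
) -> list[str]:
    k = min(k, len(pool_ids))
    if k == 0:
        return []
    if method == "rand":
        ordered = sorted(pool_ids)
        picked = rng.choice(len(ordered), size=k, replace=False)
        return [ordered[i] for i in sorted(picked)]
    scores = _stage1_scores(method, detector, model, dataset, sorted(pool_ids))
    return select_top_k(scores, k, _STAGE1_DESC[method])


def _evaluate(
    detector: DetectorContract,
    model: Any,
    dataset: Dataset,
    test_ids: Sequence[str],
    iou_threshold: float,
) -> float:
    pairs = []
    for iid in test_ids:
        img = dataset[iid]
        pairs.append((detector.detect(model, img), img.gt_boxes))
    return evaluate_detections(pairs, iou_threshold)


def run_episode(
    pools: PoolState,
    dataset: Dataset,
    detector: DetectorContract,
    model: Any,
    budgets: Budgets,
    rpf_params: RpfParams | None,
    *,
    stage1: str = "rand",
    stage2: str = "mev",
    weights: MevWeights = MevWeights(),
    empty_policy: str = "max",
    click_oracle: ClickOracle | None = None,
    costs: CostConstants = DEFAULT_COSTS,
    rng: np.random.Generator | None = None,
    test_ids: Sequence[str] = (),
    iou_threshold: float = 0.5,
    episode: int = 1,
    cumulative_seconds: float = 0.0,
) -> tuple[PoolState, Any, EpisodeLog]:
    """Run one query-annotate-retrain cycle; returns updated pools, model, log."""
    if not pools.unlabeled_ids and not pools.weak_ids:
        raise RuntimeError("experiment complete: unlabeled and weak pools empty")
    rng = rng if rng is not None else np.random.default_rng(0)
    method = stage1 if stage2 == "none" else f"{stage1}_{stage2}"
    seconds = 0.0
    n_clicks = 0
    n_boxes = 0

    if stage2 == "none":
        # standard pool-based AL: straight to strong labels
        to_strong = _select_stage1(
            stage1, detector, model, dataset, pools.unlabeled_ids, budgets.b_weak, rng
        )
        pools = pools.move_to_labeled(to_strong, from_weak=False)
        n_boxes = sum(len(dataset[i].gt_boxes) for i in to_strong)
        seconds += baseline_batch_time(len(to_strong), n_boxes, costs)
        to_weak: list[str] = []
    else:
        if rpf_params is None:
            raise ValueError("point-supervision methods need RpfParams")
        # stage 1: weak queries U -> W, oracle clicks
        to_weak = _select_stage1(
            stage1, detector, model, dataset, pools.unlabeled_ids, budgets.b_weak, rng
        )
        for iid in to_weak:
            img = dataset[iid]
            if click_oracle is not None:
                img.clicks = list(click_oracle(img, rng))
            if not img.clicks:
                raise ValueError(f"click oracle produced no clicks for {iid!r}")
            n_clicks += len(img.clicks)
        pools = pools.move_to_weak(to_weak)
        seconds += proposed_batch_time(len(to_weak), n_clicks, 0, costs)

        # stage 2: RPF + uncertainty on the whole weak pool, W -> L
        u_scores: dict[str, float] = {}
        for iid in sorted(pools.weak_ids):
            img = dataset[iid]
            proposals = detector.propose(model, img)
            img.proposals = list(proposals)
            groups = filter_and_group(img, proposals, rpf_params)
            u_scores[iid] = _stage2_score(stage2, groups, weights, empty_policy)
        to_strong = select_top_k(u_scores, min(budgets.b_strong, len(u_scores)), "desc")
        pools = pools.move_to_labeled(to_strong, from_weak=True)
        n_boxes = sum(len(dataset[i].gt_boxes) for i in to_strong)
        seconds += proposed_batch_time(0, 0, n_boxes, costs)

    model = detector.train([dataset[i] for i in sorted(pools.labeled_ids)])
    ap = (
        _evaluate(detector, model, dataset, test_ids, iou_threshold)
        if len(test_ids)
        else float("nan")
    )
    n_l, n_w, n_u = pools.sizes()
    log = EpisodeLog(
        episode=episode,
        method=method,
        to_weak=tuple(to_weak),
        to_strong=tuple(to_strong),
        n_labeled=n_l,
        n_weak=n_w,
        n_unlabeled=n_u,
        n_clicks_added=n_clicks,
        n_boxes_added=n_boxes,
        episode_seconds=seconds,
        cumulative_seconds=cumulative_seconds + seconds,
        ap=ap,
    )
    return pools, model, log


def run_experiment(
    dataset: Dataset,
    detector: DetectorContract,
    config: ExperimentConfig,
    seed: int | None = None,
    click_oracle: ClickOracle | None = None,
) -> ExperimentResult:
    """Full experiment: split, seed pool, then episodes until budgets or pools
    are exhausted.  Deterministic for a fixed seed.
    """
    from .synthetic import simulate_clicks  # default oracle

    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    ss_split, ss_sampler, ss_clicks = root.spawn(3)
    split_rng = np.random.default_rng(ss_split)
    sampler_rng = np.random.default_rng(ss_sampler)
    clicks_rng = np.random.default_rng(ss_clicks)

    if click_oracle is None:

        def click_oracle(img: ImageRecord, _rng: np.random.Generator) -> list[Click]:
            return simulate_clicks(img.gt_boxes, config.click_jitter_sd, clicks_rng)

    all_ids = sorted(dataset)
    perm = split_rng.permutation(len(all_ids))
    n_test = int(round(config.test_fraction * len(all_ids)))
    test_ids = tuple(sorted(all_ids[i] for i in perm[:n_test]))
    pool_ids = [all_ids[i] for i in perm[n_test:]]

    budgets = Budgets(
        config.b_weak, config.b_strong, config.initial_labeled, config.max_episodes
    )
    n_seed = min(budgets.initial_labeled, len(pool_ids))
    seed_ids = frozenset(pool_ids[:n_seed])
    pools = PoolState(seed_ids, frozenset(), frozenset(pool_ids[n_seed:]))

    seed_records = [dataset[i] for i in sorted(seed_ids)]
    if config.rpf_auto_estimate:
        rpf_params = RpfParams(
            estimate_epsilon(seed_records), estimate_alpha(seed_records)
        )
    else:
        rpf_params = (
            RpfParams(config.rpf_epsilon, config.rpf_alpha)
            if config.rpf_epsilon is not None
            else None
        )

    model = detector.train(seed_records)
    seed_boxes = sum(len(r.gt_boxes) for r in seed_records)
    seed_cost = baseline_batch_time(len(seed_records), seed_boxes)
    logs = [
        EpisodeLog(
            episode=0,
            method=config.method_name,
            to_weak=(),
            to_strong=tuple(sorted(seed_ids)),
            n_labeled=len(seed_ids),
            n_weak=0,
            n_unlabeled=len(pool_ids) - n_seed,
            n_clicks_added=0,
            n_boxes_added=seed_boxes,
            episode_seconds=seed_cost,
            cumulative_seconds=seed_cost,
            ap=_evaluate(detector, model, dataset, test_ids, config.iou_threshold),
        )
    ]

    weights = MevWeights(config.lambda1, config.lambda2)
    for ep in range(1, budgets.max_episodes + 1):
        if not pools.unlabeled_ids and not pools.weak_ids:
            break
        pools, model, log = run_episode(
            pools,
            dataset,
            detector,
            model,
            budgets,
            rpf_params,
            stage1=config.stage1,
            stage2=config.stage2,
            weights=weights,
            empty_policy=config.empty_group_policy,
            click_oracle=click_oracle,
            rng=sampler_rng,
            test_ids=test_ids,
            iou_threshold=config.iou_threshold,
            episode=ep,
            cumulative_seconds=logs[-1].cumulative_seconds,
        )
        logs.append(log)

    return ExperimentResult(
        logs=tuple(logs),
        pools=pools,
        test_ids=test_ids,
        rpf_params=rpf_params,
        config=config,
    )
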