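import numpy as np
import pytest

from pointal import (
    Budgets,
    ExperimentConfig,
    PoolState,
    RpfParams,
    SimDetectorParams,
    SimulatedDetector,
    run_episode,
    run_experiment,
    simulate_clicks,
)
from pointal.loop import ExperimentResult


def _oracle(img, rng):
    return simulate_clicks(img.gt_boxes, 2.0, rng)


def _episode(pool, pools, detector, budgets, **kw):
    recs = [pool[i] for i in sorted(pools.labeled_ids)]
    model = detector.train(recs)
    rpf = RpfParams(40.0, 5000.0)
    return run_episode(
        pools,
        pool,
        detector,
        model,
        budgets,
        rpf,
        click_oracle=_oracle,
        rng=np.random.default_rng(0),
        **kw,
    )


class TestPoolState:
    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            PoolState({"a"}, {"a"}, set())

    def test_moves(self):
        pools = PoolState({"a"}, set(), {"b", "c"})
        pools = pools.move_to_weak(["b"])
        pools = pools.move_to_labeled(["b"])
        assert pools.sizes() == (2, 0, 1)
        with pytest.raises(ValueError):
            pools.move_to_weak(["a"])


class TestBudgets:
    def test_validation(self):
        with pytest.raises(ValueError):
            Budgets(b_weak=5, b_strong=10)
        with pytest.raises(ValueError):
            Budgets(b_weak=5, b_strong=5, initial_labeled=0)
        Budgets(b_weak=5, b_strong=5)


class TestEpisode:
    def test_weak_pool_net_growth(self, small_pool, detector):
        ids = sorted(small_pool)
        pools = PoolState(frozenset(ids[:5]), frozenset(), frozenset(ids[5:65]))
        budgets = Budgets(b_weak=20, b_strong=10, initial_labeled=5)
        new_pools, _, log = _episode(small_pool, pools, detector, budgets)
        assert len(new_pools.weak_ids) == 20 - 10
        assert len(log.to_weak) == 20 and len(log.to_strong) == 10

    def test_clamp_when_unlabeled_small(self, small_pool, detector):
        ids = sorted(small_pool)
        pools = PoolState(frozenset(ids[:5]), frozenset(), frozenset(ids[5:8]))
        budgets = Budgets(b_weak=50, b_strong=2, initial_labeled=5)
        new_pools, _, log = _episode(small_pool, pools, detector, budgets)
        assert len(log.to_weak) == 3
        assert new_pools.sizes() == (7, 1, 0)

    def test_traced_moves_three_image_pool(self, small_pool, detector):
        ids = sorted(small_pool)[:3]
        pools = PoolState(frozenset(ids[:1]), frozenset(), frozenset(ids[1:]))
        budgets = Budgets(b_weak=2, b_strong=1, initial_labeled=1)
        new_pools, _, _ = _episode(small_pool, pools, detector, budgets)
        assert new_pools.sizes() == (2, 1, 0)

    def test_exhausted_pools_signal_completion(self, small_pool, detector):
        ids = sorted(small_pool)[:4]
        pools = PoolState(frozenset(ids), frozenset(), frozenset())
        with pytest.raises(RuntimeError, match="complete"):
            _episode(small_pool, pools, detector, Budgets(2, 1, 1))

    def test_baseline_mode_bypasses_weak_pool(self, small_pool, detector):
        ids = sorted(small_pool)
        pools = PoolState(frozenset(ids[:5]), frozenset(), frozenset(ids[5:40]))
        budgets = Budgets(b_weak=10, b_strong=5, initial_labeled=5)
        new_pools, _, log = _episode(
            small_pool, pools, detector, budgets, stage1="lc", stage2="none"
        )
        assert new_pools.sizes() == (15, 0, 25)
        assert log.to_weak == ()
        assert log.n_clicks_added == 0
        # standard-PBAL cost: image check + box time only
        assert log.episode_seconds == pytest.approx(
            7.8 * 10 + 34.5 * log.n_boxes_added
        )


def _conf(**kw):
    base = dict(
        n_images=0,  # dataset supplied directly
        b_weak=10,
        b_strong=5,
        initial_labeled=10,
        max_episodes=3,
        stage1="rand",
        stage2="mev",
        test_fraction=0.25,
        seed=5,
    )
    base.update(kw)
    return ExperimentConfig(**base)


@pytest.fixture(scope="module")
def experiment(small_pool) -> ExperimentResult:
    detector = SimulatedDetector(SimDetectorParams(seed=5))
    return run_experiment(small_pool, detector, _conf())


class TestExperiment:
    def test_pool_conservation_every_episode(self, experiment, small_pool):
        n_total = len(small_pool) - len(experiment.test_ids)
        for log in experiment.logs:
            assert log.n_labeled + log.n_weak + log.n_unlabeled == n_total

    def test_costs_accumulate_without_double_charging(self, experiment):
        cum = 0.0
        for log in experiment.logs:
            cum += log.episode_seconds
            assert log.cumulative_seconds == pytest.approx(cum)
        assert all(
            b.cumulative_seconds >= a.cumulative_seconds
            for a, b in zip(experiment.logs, experiment.logs[1:])
        )

    def test_strong_labels_only_after_weak(self, experiment):
        seen_weak = set()
        for log in experiment.logs[1:]:
            seen_weak.update(log.to_weak)
            assert set(log.to_strong) <= seen_weak

    def test_labeled_growth_arithmetic(self, experiment):
        # 10 seed + 5 strong per episode over 3 episodes
        assert experiment.logs[-1].n_labeled == 10 + 5 * 3

    def test_same_seed_reproduces_logs(self, small_pool, experiment):
        again = run_experiment(
            small_pool, SimulatedDetector(SimDetectorParams(seed=5)), _conf()
        )
        assert again.logs == experiment.logs

    def test_ap_evaluated_on_held_out_split(self, experiment):
        assert len(experiment.test_ids) == round(0.25 * 80)
        for log in experiment.logs:
            assert 0.0 <= log.ap <= 1.0
        assert not (set(experiment.test_ids) & experiment.pools.all_ids)

    def test_zero_episodes_keeps_seed_log_only(self, small_pool):
        res = run_experiment(
            small_pool,
            SimulatedDetector(SimDetectorParams(seed=1)),
            _conf(max_episodes=0),
        )
        assert len(res.logs) == 1 and res.logs[0].episode == 0

    def test_stage1_variants_run(self, small_pool):
        for stage1 in ("lc", "mar", "ent"):
            res = run_experiment(
                small_pool,
                SimulatedDetector(SimDetectorParams(seed=2)),
                _conf(stage1=stage1, max_episodes=1),
            )
            assert res.logs[-1].method == f"{stage1}_mev"
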