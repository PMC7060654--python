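import numpy as np
import pytest

from pointal import (
    Box,
    ScoredBox,
    average_precision,
    density_counts,
    evaluate_detections,
    match_detections,
    pearson_r,
    precision_recall,
    rmse,
)


def _sb(x, y, size, score):
    return ScoredBox(Box(x, y, x + size, y + size), score)


GT2 = [Box(0, 0, 10, 10), Box(50, 50, 60, 60)]


class TestMatching:
    def test_exact_hit(self):
        m = match_detections([_sb(0, 0, 10, 0.9)], [Box(0, 0, 10, 10)])
        assert (m.n_tp, m.n_fp, m.n_fn) == (1, 0, 0)

    def test_duplicate_detection_is_fp(self):
        dets = [_sb(0, 0, 10, 0.9), _sb(0, 0, 10, 0.8)]
        m = match_detections(dets, [Box(0, 0, 10, 10)])
        assert (m.n_tp, m.n_fp, m.n_fn) == (1, 1, 0)
        assert m.is_tp == (True, False)

    def test_no_detections(self):
        m = match_detections([], [Box(0, 0, 1, 1)] * 0 + GT2 + [Box(80, 80, 90, 90)])
        assert (m.n_tp, m.n_fp, m.n_fn) == (0, 0, 3)

    def test_tp_plus_fn_equals_gt(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            gts = [
                Box(x, y, x + 10, y + 10)
                for x, y in rng.uniform(0, 200, size=(rng.integers(1, 8), 2))
            ]
            dets = [
                _sb(x, y, 10, rng.uniform())
                for x, y in rng.uniform(0, 200, size=(rng.integers(0, 12), 2))
            ]
            m = match_detections(dets, gts)
            assert m.n_tp + m.n_fn == len(gts)


class TestPrecisionRecall:
    def test_enumerated_example(self):
        # dets: 0.9 TP, 0.8 FP, 0.7 TP over two ground truths
        dets = [_sb(0, 0, 10, 0.9), _sb(100, 100, 10, 0.8), _sb(50, 50, 10, 0.7)]
        m = match_detections(dets, GT2)
        p, r = precision_recall([m])
        assert p == pytest.approx([1.0, 0.5, 2 / 3])
        assert r == pytest.approx([0.5, 0.5, 1.0])

    def test_all_tp(self):
        m = match_detections([_sb(0, 0, 10, 0.9), _sb(50, 50, 10, 0.8)], GT2)
        p, r = precision_recall([m])
        assert p[-1] == 1.0 and r[-1] == 1.0

    def test_zero_gt_signalled(self):
        m = match_detections([_sb(0, 0, 10, 0.9)], [])
        with pytest.raises(ValueError):
            precision_recall([m])


def _ap_oracle(matches):
    """Brute-force AP: recompute each operating point by direct threshold
    filtering, then integrate the explicit max-precision envelope."""
    scores = [s for m in matches for s in m.scores]
    flags = {s: [] for s in scores}
    for m in matches:
        for s, f in zip(m.scores, m.is_tp):
            flags[s].append(f)
    n_gt = sum(m.n_gt for m in matches)
    pts = []
    for cut in sorted(set(scores), reverse=True):
        kept = [(s, f) for m in matches for s, f in zip(m.scores, m.is_tp) if s >= cut]
        tp = sum(f for _, f in kept)
        pts.append((tp / len(kept), tp / n_gt))
    ap = 0.0
    prev_r = 0.0
    for p, r in sorted(pts, key=lambda t: t[1]):
        env = max(pp for pp, rr in pts if rr >= r)
        ap += (r - prev_r) * env
        prev_r = r
    return ap


class TestAveragePrecision:
    def test_perfect_detector(self):
        m = match_detections([_sb(0, 0, 10, 0.9), _sb(50, 50, 10, 0.8)], GT2)
        assert average_precision(*precision_recall([m])) == 1.0

    def test_no_tp(self):
        m = match_detections([_sb(100, 100, 10, 0.9)], GT2)
        assert average_precision(*precision_recall([m])) == 0.0

    def test_three_detection_example_matches_oracle(self):
        dets = [_sb(0, 0, 10, 0.9), _sb(100, 100, 10, 0.8), _sb(50, 50, 10, 0.7)]
        m = match_detections(dets, GT2)
        ap = average_precision(*precision_recall([m]))
        assert ap == pytest.approx(_ap_oracle([m]), abs=1e-12)
        assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(120):
            gts = [
                Box(x, y, x + 10, y + 10)
                for x, y in rng.uniform(0, 300, size=(rng.integers(1, 6), 2))
            ]
            dets = [
                _sb(x, y, 10, round(rng.uniform(), 2))
                for x, y in rng.uniform(0, 300, size=(rng.integers(1, 20), 2))
            ]
            # mix in near-hits on the ground truth
            for g in gts:
                if rng.uniform() < 0.7:
                    dets.append(_sb(g.xmin + 1, g.ymin + 1, 10, round(rng.uniform(), 2)))
            m = match_detections(dets, gts)
            ap = average_precision(*precision_recall([m]))
            assert ap == pytest.approx(_ap_oracle([m]), abs=1e-9)

    def test_invariant_to_monotone_score_rescaling(self):
        rng = np.random.default_rng(23)
        gts = [Box(x, y, x + 10, y + 10) for x, y in rng.uniform(0, 300, size=(5, 2))]
        dets = [_sb(g.xmin, g.ymin, 10, rng.uniform()) for g in gts]
        dets += [_sb(x, y, 10, rng.uniform()) for x, y in rng.uniform(0, 300, size=(8, 2))]
        base = average_precision(*precision_recall([match_detections(dets, gts)]))
        rescaled = [ScoredBox(d.box, 0.1 + 0.8 * d.score) for d in dets]
        again = average_precision(*precision_recall([match_detections(rescaled, gts)]))
        assert again == pytest.approx(base, abs=1e-12)


class TestCounts:
    def test_pearson(self):
        assert pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)
        x, y = [1, 2, 3], [2, 2, 4]
        mx, my = 2.0, 8 / 3
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
        assert pearson_r(x, y) == pytest.approx(num / den)

    def test_pearson_affine_invariance(self):
        x = [1.0, 4.0, 2.0, 8.0]
        y = [2.0, 3.0, 5.0, 7.0]
        assert pearson_r([3 * v + 1 for v in x], y) == pytest.approx(pearson_r(x, y))

    def test_pearson_degenerate(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_rmse(self):
        assert rmse([1, 2], [1, 2]) == 0.0
        assert rmse([0, 0], [3, 4]) == pytest.approx((12.5) ** 0.5)
        assert rmse([2], [5]) == 3.0
        with pytest.raises(ValueError):
            rmse([1], [1, 2])

    def test_density_counts(self):
        dets = [_sb(0, 0, 5, s) for s in (0.9, 0.6, 0.5, 0.4)]
        assert density_counts([dets, []], score_cut=0.5) == [3, 0]


def test_evaluate_detections_end_to_end():
    per_image = [
        ([_sb(0, 0, 10, 0.9)], [Box(0, 0, 10, 10)]),
        ([], [Box(5, 5, 15, 15)]),
    ]
    assert 0.0 < evaluate_detections(per_image) <= 1.0
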