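"""Detection metrics: IoU, greedy matching, AP integration — checked
against brute-force enumeration and the defining identities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ginsengdet.metrics import average_precision, evaluate, iou, match


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_hand_value_one_seventh(self):
        assert np.isclose(iou((0, 0, 2, 2), (1, 1, 3, 3)), 1 / 7)

    def test_degenerate_box_overlaps_nothing(self):
        assert iou((1, 1, 1, 3), (0, 0, 2, 2)) == 0.0

    def test_symmetry_and_range(self, rng):
        for _ in range(50):
            a = np.sort(rng.uniform(0, 10, 4)).reshape(2, 2).T.reshape(-1)
            b = np.sort(rng.uniform(0, 10, 4)).reshape(2, 2).T.reshape(-1)
            a = (a[0], a[2], a[1], a[3])
            b = (b[0], b[2], b[1], b[3])
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert np.isclose(v, iou(b, a))


def brute_force_max_matching(det_boxes, gt_boxes, thr=0.5):
    """Maximum TP count over all one-to-one assignments (exhaustive)."""
    m, n = len(det_boxes), len(gt_boxes)
    best = 0
    for perm in itertools.permutations(range(n), min(m, n)):
        dets = list(range(m))[:len(perm)] if m >= n else range(m)
        tp = sum(1 for d, g in zip(itertools.islice(dets, len(perm)), perm)
                 if iou(det_boxes[d], gt_boxes[g]) > thr)
        best = max(best, tp)
    # also try every subset pairing when m < n handled above; m > n: choose
    # which detections participate
    if m > n:
        for sub in itertools.permutations(range(m), n):
            tp = sum(1 for d, g in zip(sub, range(n))
                     if iou(det_boxes[d], gt_boxes[g]) > thr)
            best = max(best, tp)
    return best


class TestMatch:
    def test_single_true_positive(self):
        tp, order, fn = match([[0, 0, 10, 10]], [0.9], [[1, 1, 10, 10]])
        assert tp.tolist() == [True] and fn == 0

    def test_one_to_one_rule_duplicate_detection(self):
        dets = [[0, 0, 10, 10], [0.5, 0.5, 10, 10]]
        tp, order, fn = match(dets, [0.6, 0.9], [[0, 0, 10, 10]])
        # higher-confidence det (index 1) wins; the other is FP
        assert tp.tolist() == [True, False]
        assert order.tolist() == [1, 0]
        assert fn == 0

    def test_unmatched_ground_truths_are_fn(self):
        tp, _, fn = match([[0, 0, 2, 2]], [0.5],
                          [[0, 0, 2, 2], [5, 5, 8, 8]])
        assert fn == 1

    def test_greedy_vs_bruteforce_on_random_small_cases(self, rng):
        """Greedy confidence-ordered matching never beats the optimal
        assignment and achieves it on clean (well-separated) cases."""
        for trial in range(30):
            m = int(rng.integers(1, 5))
            n = int(rng.integers(1, 5))
            dets = np.stack([_rand_box(rng) for _ in range(m)])
            gts = np.stack([_rand_box(rng) for _ in range(n)])
            conf = rng.uniform(0.1, 1, m)
            tp, _, fn = match(dets, conf, gts)
            opt = brute_force_max_matching(dets, gts)
            assert tp.sum() <= opt
            assert fn == len(gts) - tp.sum()

    def test_greedy_matches_bruteforce_on_disjoint_layout(self):
        gts = np.array([[0, 0, 10, 10], [20, 20, 30, 30], [40, 0, 50, 10]],
                       dtype=float)
        dets = gts + 0.5
        tp, _, fn = match(dets, [0.9, 0.8, 0.7], gts)
        assert tp.sum() == brute_force_max_matching(dets, gts) == 3
        assert fn == 0


def _rand_box(rng):
    x, y = rng.uniform(0, 20, 2)
    w, h = rng.uniform(2, 10, 2)
    return np.array([x, y, x + w, y + h])


def exhaustive_step_ap(tp_flags, n_gt):
    """Independent AP: exact integral of the envelope step curve computed
    point-by-point (no vectorised tricks)."""
    tp, fp = 0, 0
    pts = [(0.0, 1.0)]
    for flag in tp_flags:
        tp, fp = tp + bool(flag), fp + (not flag)
        pts.append((tp / n_gt, tp / (tp + fp)))
    # monotone envelope from the right
    env = []
    best = 0.0
    for r, p in reversed(pts):
        best = max(best, p)
        env.append((r, best))
    env.reverse()
    ap = 0.0
    for (r0, _), (r1, p1) in zip(env[:-1], env[1:]):
        ap += (r1 - r0) * p1
    return ap


class TestAveragePrecision:
    def test_single_tp(self):
        ap, _, _ = average_precision([True], [0.9], 1)
        assert ap == 1.0

    def test_fp_then_tp_gives_half(self):
        ap, _, _ = average_precision([False, True], [0.9, 0.8], 1)
        assert np.isclose(ap, 0.5)

    def test_tp_then_fp_gives_one(self):
        ap, _, _ = average_precision([True, False], [0.9, 0.8], 1)
        assert np.isclose(ap, 1.0)

    def test_zero_gt_is_an_error(self):
        with pytest.raises(ValueError):
            average_precision([True], [0.9], 0)

    @given(st.lists(st.booleans(), min_size=1, max_size=6),
           st.integers(min_value=1, max_value=4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exhaustive_step_integration(self, flags, extra_gt):
        n_gt = max(sum(flags), 1) + extra_gt - 1
        conf = np.linspace(0.9, 0.1, len(flags))
        ap, _, _ = average_precision(flags, conf, n_gt)
        assert np.isclose(ap, exhaustive_step_ap(flags, n_gt), atol=1e-9)

    @given(st.lists(st.booleans(), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_to_monotone_confidence_rescaling(self, flags):
        n_gt = max(sum(flags), 1)
        conf = np.linspace(0.9, 0.1, len(flags))
        ap1, _, _ = average_precision(flags, conf, n_gt)
        ap2, _, _ = average_precision(flags, np.tanh(conf * 3) + 7, n_gt)
        assert np.isclose(ap1, ap2)

    @given(st.lists(st.booleans(), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_appending_lowest_conf_fp_never_increases_ap(self, flags):
        n_gt = max(sum(flags), 1)
        conf = np.linspace(0.9, 0.2, len(flags))
        ap1, _, _ = average_precision(flags, conf, n_gt)
        ap2, _, _ = average_precision(flags + [False],
                                      np.append(conf, 0.05), n_gt)
        assert ap2 <= ap1 + 1e-12

    @given(st.lists(st.booleans(), min_size=1, max_size=8),
           st.integers(min_value=0, max_value=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_inserting_tp_never_decreases_ap(self, flags, pos):
        n_gt = sum(flags) + 1
        pos = min(pos, len(flags))
        conf = np.linspace(0.9, 0.2, len(flags))
        ap1, _, _ = average_precision(flags, conf, n_gt)
        flags2 = flags[:pos] + [True] + flags[pos:]
        conf2 = np.insert(conf, pos, conf[pos] if pos < len(flags)
                          else conf[-1] - 0.01)
        ap2, _, _ = average_precision(flags2, conf2, n_gt)
        assert ap2 >= ap1 - 1e-12

    def test_pr_identities_along_curve(self, rng):
        flags = rng.uniform(0, 1, 20) > 0.4
        conf = rng.uniform(0, 1, 20)
        n_gt = int(flags.sum()) + 3
        _, rec, pre = average_precision(flags, conf, n_gt)
        order = np.argsort(-conf, kind="stable")
        tp_c = np.cumsum(flags[order])
        fp_c = np.cumsum(~flags[order])
        assert np.allclose(pre, tp_c / (tp_c + fp_c))
        assert np.allclose(rec, tp_c / n_gt)
        assert (np.diff(rec) >= 0).all()


class TestEvaluate:
    def test_hand_built_three_image_fixture(self):
        from ginsengdet.model import DetectionSet
        from ginsengdet.synthetic import LabeledImage

        size = 100
        img = np.zeros((size, size, 3), dtype=np.uint8)
        # image 1: one gt, perfectly hit; image 2: one gt missed + one FP;
        # image 3: two gts, one hit
        items = [
            LabeledImage(img, [[0, 0.3, 0.3, 0.2, 0.2]]),
            LabeledImage(img, [[0, 0.7, 0.7, 0.2, 0.2]]),
            LabeledImage(img, [[0, 0.2, 0.2, 0.2, 0.2],
                               [0, 0.8, 0.8, 0.1, 0.1]]),
        ]
        preds = [
            DetectionSet(np.array([[20., 20, 40, 40]]), np.array([0.9]),
                         np.array([0])),
            DetectionSet(np.array([[5., 5, 15, 15]]), np.array([0.8]),
                         np.array([0])),
            DetectionSet(np.array([[10., 10, 30, 30]]), np.array([0.7]),
                         np.array([0])),
        ]
        res = evaluate(None, items, predictions=preds)
        # 2 TP, 1 FP, 2 FN at the F1-optimal point
        assert (res.tp, res.fp, res.fn) == (2, 1, 2)
        assert np.isclose(res.precision, 2 / 3)
        assert np.isclose(res.recall, 2 / 4)

    def test_empty_predictions_zero_recall(self):
        from ginsengdet.model import DetectionSet
        from ginsengdet.synthetic import LabeledImage

        img = np.zeros((50, 50, 3), dtype=np.uint8)
        items = [LabeledImage(img, [[0, 0.5, 0.5, 0.2, 0.2]])]
        preds = [DetectionSet(np.zeros((0, 4)), np.zeros(0),
                              np.zeros(0, dtype=int))]
        res = evaluate(None, items, predictions=preds)
        assert res.recall == 0.0 and res.ap == 0.0
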