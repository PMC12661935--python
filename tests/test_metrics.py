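"""Metric suite: IoU, matching, P/R/F1 (incl. published worked examples),
AP integration, mAP, R² and accuracy."""

import numpy as np
import pytest

from tflos.boxes import box_iou
from tflos.metrics import (ConfusionCounts, accuracy, average_precision,
                           evaluate_detections, f1, match_detections, mean_ap,
                           pr_curve, precision, r_squared, recall)


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------

class TestIoU:
    def test_identical_boxes(self):
        assert box_iou((1, 1, 4, 5), (1, 1, 4, 5)) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou((0, 0, 1, 1), (2, 2, 3, 3)) == 0.0

    def test_partial_overlap_exact_value(self):
        # rasterized oracle: unit grid count gives 1/7
        assert box_iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_symmetry(self, rng):
        for _ in range(50):
            a = np.sort(rng.uniform(0, 10, 4))[[0, 1, 2, 3]]
            boxa = (a[0], a[1], a[2] + 0.1, a[3] + 0.1)
            b = np.sort(rng.uniform(0, 10, 4))
            boxb = (b[0], b[1], b[2] + 0.1, b[3] + 0.1)
            assert box_iou(boxa, boxb) == pytest.approx(box_iou(boxb, boxa))

    def test_rasterized_area_oracle(self, rng):
        # compare against a fine-grid pixel count
        a = (0.0, 0.0, 3.0, 2.0)
        b = (1.5, 0.5, 4.0, 3.0)
        n = 400
        ys, xs = np.mgrid[0:4:n * 1j, 0:4:n * 1j]
        in_a = (xs >= a[0]) & (xs < a[2]) & (ys >= a[1]) & (ys < a[3])
        in_b = (xs >= b[0]) & (xs < b[2]) & (ys >= b[1]) & (ys < b[3])
        approx = (in_a & in_b).sum() / (in_a | in_b).sum()
        assert box_iou(a, b) == pytest.approx(approx, abs=5e-3)


# ---------------------------------------------------------------------------
# F1 worked examples from published detector evaluations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,r,expected", [
    (0.788, 0.761, 0.774),     # all classes
    (0.866, 0.778, 0.820),     # bud
    (0.782, 0.760, 0.771),     # blooming flower
    (0.717, 0.745, 0.731),     # withered flower
    (0.759, 0.685, 0.720),     # baseline detector
    (0.799, 0.716, 0.755),     # enhanced detector
])
def test_f1_matches_published_rows_to_three_decimals(p, r, expected):
    assert round(f1(p, r), 3) == expected


def test_f1_of_equal_precision_recall_is_that_value():
    assert f1(0.6, 0.6) == pytest.approx(0.6)


def test_f1_bounds():
    for p, r in [(0.9, 0.1), (0.5, 0.7), (0.2, 0.2)]:
        v = f1(p, r)
        assert v <= (p + r) / 2 + 1e-12
        assert v <= 2 * min(p, r) + 1e-12


def test_precision_recall_zero_denominator_conventions():
    assert precision(ConfusionCounts()) == 0.0
    assert recall(ConfusionCounts()) == 0.0
    assert f1(0.0, 0.0) == 0.0


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

class TestMatching:
    def test_perfect_predictions(self):
        gts = [(0, 0, 2, 2), (5, 5, 7, 7)]
        dets = [((0, 0, 2, 2), 0.9), ((5, 5, 7, 7), 0.8)]
        c = match_detections(dets, gts, 0.5)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_no_predictions(self):
        c = match_detections([], [(0, 0, 1, 1)] * 3, 0.5)
        assert (c.tp, c.fp, c.fn) == (0, 0, 3)

    def test_two_detections_one_truth(self):
        dets = [((0, 0, 2, 2), 0.9), ((0, 0, 2, 2), 0.7)]
        c = match_detections(dets, [(0, 0, 2, 2)], 0.5)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_greedy_matches_exhaustive_on_small_cases(self, rng):
        """On <=4-box instances, greedy TP never exceeds the optimal
        bipartite matching and agrees with it in the vast majority of
        cases (greedy is the committed behaviour; discrepancies logged)."""

        def optimal_tp(dets, gts, thr):
            # augmenting-path maximum bipartite matching
            adj = [[j for j, g in enumerate(gts)
                    if box_iou(box, g) >= thr] for box, _ in dets]
            match_g = [-1] * len(gts)

            def augment(i, seen):
                for j in adj[i]:
                    if j in seen:
                        continue
                    seen.add(j)
                    if match_g[j] < 0 or augment(match_g[j], seen):
                        match_g[j] = i
                        return True
                return False

            return sum(augment(i, set()) for i in range(len(dets)))

        agree = total = 0
        for _ in range(200):
            n_d, n_g = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            dets = []
            for _ in range(n_d):
                x, y = rng.uniform(0, 6, 2)
                w, h = rng.uniform(1, 4, 2)
                dets.append(((x, y, x + w, y + h), float(rng.uniform(0.1, 1))))
            gts = []
            for _ in range(n_g):
                x, y = rng.uniform(0, 6, 2)
                w, h = rng.uniform(1, 4, 2)
                gts.append((x, y, x + w, y + h))
            c = match_detections(dets, gts, 0.3)
            best = optimal_tp(dets, gts, 0.3)
            assert c.tp <= best
            total += 1
            agree += c.tp == best
        assert agree / total > 0.9

    def test_confusion_counts_add_across_batches(self):
        a = ConfusionCounts(tp=2, fp=1, fn=0)
        b = ConfusionCounts(tp=1, fp=0, fn=3)
        s = a + b
        assert (s.tp, s.fp, s.fn) == (3, 1, 3)


# ---------------------------------------------------------------------------
# AP / mAP
# ---------------------------------------------------------------------------

class TestAP:
    def test_perfect_detector_ap_is_one(self):
        gts = [[(0, 0, 2, 2)], [(1, 1, 3, 3)]]
        dets = [[((0, 0, 2, 2), 0.9)], [((1, 1, 3, 3), 0.8)]]
        assert pr_curve(dets, gts, 0.5).ap == pytest.approx(1.0)

    def test_zero_tp_detector_ap_is_zero(self):
        gts = [[(0, 0, 2, 2)]]
        dets = [[((10, 10, 12, 12), 0.9)]]
        assert pr_curve(dets, gts, 0.5).ap == 0.0

    def test_scripted_case_matches_hand_integral(self):
        """5 detections, 3 truths; the step function is integrated by hand.

        Sweep (conf desc): TP, FP, TP, FP, TP ->
        recalls 1/3, 1/3, 2/3, 2/3, 1; precisions 1, 1/2, 2/3, 1/2, 3/5.
        Envelope at recall 1/3 -> 1, at 2/3 -> 2/3, at 1 -> 3/5.
        AP = (1/3)(1) + (1/3)(2/3) + (1/3)(3/5) = 0.7555...
        """
        gts = [[(0, 0, 2, 2), (10, 10, 12, 12), (20, 20, 22, 22)]]
        dets = [[((0, 0, 2, 2), 0.95),        # TP
                 ((40, 40, 42, 42), 0.90),    # FP
                 ((10, 10, 12, 12), 0.85),    # TP
                 ((50, 50, 52, 52), 0.80),    # FP
                 ((20, 20, 22, 22), 0.75)]]   # TP
        expected = (1 / 3) * 1 + (1 / 3) * (2 / 3) + (1 / 3) * (3 / 5)
        assert pr_curve(dets, gts, 0.5).ap == pytest.approx(expected)

    def test_recall_nondecreasing_along_sweep(self, rng):
        gts = [[(i * 5, 0, i * 5 + 3, 3) for i in range(4)]]
        dets = [[((i * 5 + rng.uniform(-1, 1), 0, i * 5 + 3, 3),
                  float(rng.uniform())) for i in range(4)] * 2]
        curve = pr_curve(dets, gts, 0.5)
        assert np.all(np.diff(curve.recalls) >= -1e-12)

    def test_ap_invariant_to_duplicate_confidence_input_order(self):
        """Detections sharing a confidence are ordered by the documented
        tie rule (higher IoU, then input order), so permuting the input
        leaves AP unchanged."""
        gts = [[(0, 0, 4, 4), (10, 10, 14, 14), (20, 20, 24, 24)]]
        dets = [((0, 0, 4, 4), 0.8), ((50, 50, 54, 54), 0.8),
                ((10, 10, 14, 14), 0.8), ((20, 21, 24, 25), 0.8)]
        ap_fwd = pr_curve([dets], gts, 0.5).ap
        ap_rev = pr_curve([dets[::-1]], gts, 0.5).ap
        assert ap_fwd == pytest.approx(ap_rev)

    def test_mean_ap_rules(self):
        assert mean_ap([0.7]) == pytest.approx(0.7)
        assert mean_ap([1.0, 0.0, 0.5]) == pytest.approx(0.5)
        assert mean_ap([0.8, float("nan")]) == pytest.approx(0.8)

    def test_interp101_close_to_exact_on_dense_curve(self, rng):
        gts = [[(i * 10, 0, i * 10 + 4, 4) for i in range(20)]]
        dets = [[((i * 10 + rng.uniform(-2, 2), 0, i * 10 + 4, 4),
                  float(rng.uniform())) for i in range(20)]]
        from tflos.metrics import _sweep
        flags, _, n = _sweep([dets[0]], [gts[0]], 0.5)
        tp = np.cumsum(flags)
        fp = np.cumsum(~flags)
        rec, prec = tp / n, tp / (tp + fp)
        exact = average_precision(prec, rec, "all_point")
        interp = average_precision(prec, rec, "interp101")
        assert abs(exact - interp) < 0.05


# ---------------------------------------------------------------------------
# R² and accuracy
# ---------------------------------------------------------------------------

class TestR2:
    def test_perfect_prediction(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_is_zero(self):
        assert r_squared([1, 2, 3], [2, 2, 2]) == 0.0

    def test_worked_example(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_can_be_negative(self):
        assert r_squared([1, 2, 3], [30, -10, 7]) < 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2, 2], [1, 3])
        with pytest.raises(ValueError):
            r_squared([1], [1])


class TestAccuracy:
    def test_diagonal_matrix_is_one(self):
        assert accuracy(np.diag([3, 1, 4, 1, 5])) == 1.0

    def test_uniform_five_class_matrix(self):
        assert accuracy(np.ones((5, 5))) == pytest.approx(0.2)

    def test_binary_worked_example(self):
        assert accuracy(np.array([[8, 2], [3, 7]])) == pytest.approx(0.75)
        assert accuracy(ConfusionCounts(tp=8, fn=2, fp=3, tn=7)) == \
            pytest.approx(0.75)


# ---------------------------------------------------------------------------
# dataset-level report
# ---------------------------------------------------------------------------

def test_label_dir_self_evaluation_is_perfect(tmp_path):
    """Feeding a label directory to itself as predictions scores 1.0."""
    from tflos.metrics import evaluate_label_dirs
    from tflos.yolo_io import write_labels

    rng = np.random.default_rng(11)
    truth = tmp_path / "truth"
    truth.mkdir()
    for i in range(6):
        boxes = [(int(rng.integers(0, 3)), *rng.uniform(0.3, 0.5, 2),
                  *rng.uniform(0.05, 0.15, 2)) for _ in range(2 + i)]
        write_labels(truth / f"im{i}.txt", boxes)
    rep = evaluate_label_dirs(truth, truth)
    assert rep["map50"] == 1.0 and rep["f1"] == 1.0
    assert rep["count_r2"] == 1.0


def test_evaluating_truth_as_predictions_is_perfect():
    rng = np.random.default_rng(7)
    truths = []
    for _ in range(10):
        img = []
        for _ in range(int(rng.integers(1, 6))):
            x, y = rng.uniform(0, 100, 2)
            w, h = rng.uniform(3, 20, 2)
            img.append((int(rng.integers(0, 3)), (x, y, x + w, y + h)))
        truths.append(img)
    dets = [[(cls, box, 1.0) for cls, box in img] for img in truths]
    rep = evaluate_detections(dets, truths)
    for key in ("precision", "recall", "f1", "map50", "map50_95"):
        assert rep[key] == pytest.approx(1.0), key
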