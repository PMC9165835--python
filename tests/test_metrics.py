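import math

import numpy as np
import pytest

from cowpose.boxes import BoundingBox
from cowpose.metrics import (
    ConfusionMatrix3,
    average_precision,
    classify_detections,
    compute_oks,
    confusion_metrics,
    oks_ap,
)

from conftest import make_skeleton


def box(x0, y0, x1, y1, conf=1.0):
    return BoundingBox(x0, y0, x1, y1, confidence=conf)


class TestClassifyDetections:
    def test_perfect_predictions(self):
        gts = [box(0, 0, 2, 2), box(5, 5, 8, 8)]
        out = classify_detections(list(gts), gts, 0.5)
        assert (out.tp, out.fp, out.fn) == (2, 0, 0)
        assert out.precision == 1.0 and out.recall == 1.0

    def test_no_predictions_all_false_negative(self):
        gts = [box(0, 0, 1, 1), box(2, 2, 3, 3), box(5, 5, 6, 6)]
        out = classify_detections([], gts, 0.5)
        assert out.fn == 3 and out.recall == 0.0

    def test_handcrafted_scene_counts(self):
        # GT: two boxes. Pred: one exact hit, one weak overlap, one far away.
        gts = [box(0, 0, 4, 4), box(10, 0, 14, 4)]
        preds = [
            box(0, 0, 4, 4, 0.9),      # IoU 1 with gt0 -> TP
            box(13, 0, 17, 4, 0.8),    # IoU 4/28 with gt1 -> FP (below 0.5)
            box(30, 30, 34, 34, 0.7),  # IoU 0 with everything -> FP
        ]
        out = classify_detections(preds, gts, 0.5)
        # gt1 overlaps a prediction, so under the literal rule it is not a FN
        assert (out.tp, out.fp, out.fn) == (1, 2, 0)
        coco = classify_detections(preds, gts, 0.5, mode="coco")
        assert (coco.tp, coco.fp, coco.fn) == (1, 2, 1)

    def test_unoverlapped_gt_is_false_negative(self):
        gts = [box(0, 0, 4, 4), box(50, 50, 54, 54)]
        preds = [box(0, 0, 4, 4, 0.9)]
        out = classify_detections(preds, gts, 0.5)
        assert (out.tp, out.fp, out.fn) == (1, 0, 1)


class TestAveragePrecision:
    def test_perfect_curve(self):
        assert average_precision([(1.0, 0.5), (1.0, 1.0)]) == 1.0

    def test_single_point_step(self):
        assert average_precision([(1.0, 0.5)]) == 0.5

    def test_empty_is_zero(self):
        assert average_precision([]) == 0.0

    def test_matches_step_sum_oracle(self, rng):
        for _ in range(30):
            pts = [(float(rng.uniform()), float(rng.uniform())) for _ in range(8)]
            # oracle: direct step sum over sorted unique recalls with envelope max
            rs = sorted({r for _, r in pts})
            expected, prev = 0.0, 0.0
            for r in rs:
                env = max(p for p, rr in pts if rr >= r)
                expected += (r - prev) * env
                prev = r
            assert average_precision(pts) == pytest.approx(expected)


def offset_skeleton(base, dx, dy):
    return base.translated(dx, dy)


class TestComputeOks:
    def test_identical_skeletons_score_one(self, standing_skeleton):
        assert compute_oks(standing_skeleton, standing_skeleton).value == 1.0

    def test_single_keypoint_at_scale_distance(self):
        coords = [(0, 0)] * 16
        vis = [2] + [0] * 15
        gt = make_skeleton(coords, vis)
        s, k = 10.0, 0.1
        pred_coords = [(s * k, 0)] + [(0, 0)] * 15
        pred = make_skeleton(pred_coords, vis)
        out = compute_oks(pred, gt, s=s, k=k)
        assert out.value == pytest.approx(math.exp(-0.5), abs=1e-9)

    def test_doubling_error_decreases_score(self, standing_skeleton):
        near = offset_skeleton(standing_skeleton, 3, 0)
        far = offset_skeleton(standing_skeleton, 6, 0)
        assert compute_oks(far, standing_skeleton).value < compute_oks(near, standing_skeleton).value

    def test_missing_predicted_part_contributes_zero(self, standing_skeleton):
        kps = list(standing_skeleton.keypoints)
        from cowpose.skeleton import Keypoint

        kps[0] = Keypoint(1, 0, 0, 0)
        pred = make_skeleton([(kp.x, kp.y) for kp in kps], [kp.visibility for kp in kps])
        out = compute_oks(pred, standing_skeleton)
        assert out.value == pytest.approx(15 / 16)

    def test_rigid_translation_invariance(self, standing_skeleton):
        pred = offset_skeleton(standing_skeleton, 2, 1)
        a = compute_oks(pred, standing_skeleton, s=50.0)
        b = compute_oks(offset_skeleton(pred, 100, 50), offset_skeleton(standing_skeleton, 100, 50), s=50.0)
        assert a.value == pytest.approx(b.value)

    def test_unlabeled_ground_truth_rejected(self):
        empty = make_skeleton([(0, 0)] * 16, [0] * 16)
        with pytest.raises(ValueError):
            compute_oks(empty, empty)


class TestOksAp:
    def test_perfect_recovery(self, standing_skeleton):
        gts = [offset_skeleton(standing_skeleton, 200 * i, 0) for i in range(5)]
        assert oks_ap(list(gts), gts) == 1.0

    def test_no_predictions(self, standing_skeleton):
        assert oks_ap([], [standing_skeleton]) == 0.0

    def test_partial_recovery_fraction(self, standing_skeleton):
        gts = [offset_skeleton(standing_skeleton, 300 * i, 0) for i in range(3)]
        preds = [
            offset_skeleton(standing_skeleton, 0, 0),     # high OKS vs gt0
            offset_skeleton(standing_skeleton, 300, 40),  # displaced: low OKS vs gt1
        ]
        lo = compute_oks(preds[1], gts[1]).value
        assert lo < 0.5 < compute_oks(preds[0], gts[0]).value
        assert oks_ap(preds, gts) == pytest.approx(1 / 3)


class TestConfusionMetrics:
    def test_reported_confusion_matrix_reproduction(self):
        cm = ConfusionMatrix3([[121, 9, 0], [10, 119, 1], [1, 0, 129]])
        met = confusion_metrics(cm)
        assert met.n_correct == 369
        assert met.accuracy == pytest.approx(369 / 390)
        assert met.precision == pytest.approx([121 / 132, 119 / 128, 129 / 130])
        assert met.recall == pytest.approx([121 / 130, 119 / 130, 129 / 130])
        assert met.column_share[1, 0] == pytest.approx(10 / 132)
        assert met.column_share[0, 1] == pytest.approx(9 / 128)

    def test_diagonal_matrix_perfect_accuracy(self):
        met = confusion_metrics(ConfusionMatrix3(np.diag([130, 130, 130])))
        assert met.accuracy == 1.0
        assert np.allclose(met.precision, 1.0) and np.allclose(met.recall, 1.0)

    def test_permutation_matrix_with_positive_diagonal(self):
        met = confusion_metrics(ConfusionMatrix3([[5, 0, 0], [0, 7, 0], [0, 0, 2]]))
        assert met.accuracy == 1.0

    def test_zero_column_flagged_not_zero(self):
        met = confusion_metrics(ConfusionMatrix3([[3, 2, 0], [1, 4, 0], [0, 0, 0]]))
        assert np.isnan(met.precision[2]) and np.isnan(met.recall[2])

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionMatrix3(np.zeros((3, 3), dtype=int)))
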