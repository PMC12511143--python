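"""Detection metric correctness, invariances, and agreement with the
independent loop-based reference evaluator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from giwtnet.metrics import (
    DetectionBox,
    GroundTruthBox,
    average_precision,
    iou,
    map_suite,
    match_detections,
    nms,
    precision_recall_f1,
    IOU_THRESHOLDS_50_95,
)

from _reference_eval import reference_ap, reference_map_suite


class TestIoU:
    def test_identical_and_disjoint(self):
        assert iou((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_hand_computed_overlap(self):
        assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_degenerate_box_is_zero(self, caplog):
        assert iou((0, 0, 0, 1), (0, 0, 1, 1)) == 0.0

    @given(st.floats(0, 50), st.floats(0, 50), st.floats(1, 20), st.floats(1, 20))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, x, y, w, h):
        a = (x, y, x + w, y + h)
        b = (10.0, 10.0, 25.0, 30.0)
        v = iou(a, b)
        assert v == pytest.approx(iou(b, a))
        assert 0.0 <= v <= 1.0


class TestMatching:
    def test_single_perfect_match(self):
        tp, _, fn = match_detections(
            [DetectionBox(0, (0, 0, 4, 4), 0.9)], [GroundTruthBox(0, (0, 0, 4, 4))], 0.5
        )
        assert tp.tolist() == [True] and fn == 0

    def test_duplicate_detections_one_tp_one_fp(self):
        dets = [
            DetectionBox(0, (0, 0, 4, 4), 0.6),
            DetectionBox(0, (0.2, 0, 4.2, 4), 0.9),
        ]
        gts = [GroundTruthBox(0, (0, 0, 4, 4))]
        tp, sorted_dets, fn = match_detections(dets, gts, 0.5)
        assert sorted_dets[0].confidence == 0.9
        assert tp.tolist() == [True, False] and fn == 0

    def test_wrong_class_is_fp_and_fn(self):
        tp, _, fn = match_detections(
            [DetectionBox(1, (0, 0, 4, 4), 0.9)], [GroundTruthBox(0, (0, 0, 4, 4))], 0.5
        )
        assert tp.tolist() == [False] and fn == 1


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "p,r,expected",
        [(84.7, 82.2, 83.4), (82.5, 79.8, 81.1), (88.4, 81.0, 84.5)],
    )
    def test_published_f1_rows_reproduced(self, p, r, expected):
        """F1 recomputed from printed precision/recall pairs matches the
        printed F1 to one decimal."""
        tp, fp, fn = p * r, r * (100 - p), p * (100 - r)
        _, _, f1 = precision_recall_f1(tp, fp, fn)
        assert round(100 * f1, 1) == expected

    def test_zero_convention(self):
        assert precision_recall_f1(0, 0, 0) == (0.0, 0.0, 0.0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_harmonic_mean_symmetry(self, tp, fp, fn):
        p1, r1, f1a = precision_recall_f1(tp, fp, fn)
        p2, r2, f1b = precision_recall_f1(tp, fn, fp)  # swaps P and R
        assert f1a == pytest.approx(f1b)


class TestAveragePrecision:
    def test_perfect_detector(self):
        assert average_precision([True, True, True], 3) == 1.0

    def test_no_detections(self):
        assert average_precision([], 3) == 0.0

    def test_three_point_curve_matches_reference(self):
        flags = [True, False, True]
        got = average_precision(flags, 2)
        want = reference_ap([(0.9, True), (0.8, False), (0.7, True)], 2)
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx((51 * 1.0 + 50 * (2 / 3)) / 101)

    def test_exact_envelope_variant(self):
        flags = [True, False, True]
        exact = average_precision(flags, 2, interpolation="exact")
        assert exact == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_random_flag_sequences_match_reference(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 15))
            flags = rng.uniform(size=n) > 0.5
            confs = np.sort(rng.uniform(size=n))[::-1]
            gt = max(int(flags.sum()), 1) + int(rng.integers(0, 3))
            got = average_precision(flags, gt)
            want = reference_ap(list(zip(confs, flags)), gt)
            assert got == pytest.approx(want, abs=1e-9)


def _random_eval_fixture(rng, n_images=3, n_classes=3):
    dets, gts = {}, {}
    for img in range(n_images):
        gts[img] = []
        dets[img] = []
        for _ in range(int(rng.integers(0, 6))):
            x, y = rng.uniform(0, 80, 2)
            w, h = rng.uniform(5, 30, 2)
            cls = int(rng.integers(0, n_classes))
            gts[img].append(GroundTruthBox(cls, (x, y, x + w, y + h)))
            if rng.uniform() < 0.8:  # noisy detection of this object
                dx, dy = rng.uniform(-6, 6, 2)
                dw, dh = rng.uniform(0.7, 1.3, 2)
                dcls = cls if rng.uniform() < 0.85 else int(rng.integers(0, n_classes))
                dets[img].append(DetectionBox(
                    dcls, (x + dx, y + dy, x + dx + w * dw, y + dy + h * dh),
                    float(rng.uniform(0.05, 1.0)),
                ))
        for _ in range(int(rng.integers(0, 3))):  # background false positives
            x, y = rng.uniform(0, 80, 2)
            w, h = rng.uniform(5, 25, 2)
            dets[img].append(DetectionBox(
                int(rng.integers(0, n_classes)), (x, y, x + w, y + h),
                float(rng.uniform(0.05, 1.0)),
            ))
    if not any(gts.values()):
        gts[0].append(GroundTruthBox(0, (1, 1, 9, 9)))
    return dets, gts


class TestMapSuite:
    def test_perfect_detector_scores_one(self, rng):
        _, gts = _random_eval_fixture(rng)
        dets = {
            img: [DetectionBox(g.class_id, g.box, 1.0) for g in gs]
            for img, gs in gts.items()
        }
        res = map_suite(dets, gts)
        assert res.map50 == pytest.approx(1.0)
        assert res.map50_95 == pytest.approx(1.0)

    def test_jitter_between_50_and_55_isolates_first_threshold(self):
        """Boxes whose IoU with truth is in (0.50, 0.55) pass only the 0.50
        threshold, so mAP@50 = 1 while mAP@50~95 = 0.1."""
        gts = {0: [GroundTruthBox(0, (0, 0, 100, 10))]}
        # shift a 100x10 box right by 32: IoU = 68/132 ~ 0.515
        dets = {0: [DetectionBox(0, (32, 0, 132, 10), 0.9)]}
        res = map_suite(dets, gts)
        assert res.map50 == pytest.approx(1.0)
        assert res.map50_95 == pytest.approx(0.1)

    def test_detection_order_invariance(self, rng):
        dets, gts = _random_eval_fixture(rng)
        res1 = map_suite(dets, gts)
        shuffled = {img: list(rng.permutation(len(ds))) for img, ds in dets.items()}
        dets2 = {img: [dets[img][i] for i in idx] for img, idx in shuffled.items()}
        res2 = map_suite(dets2, gts)
        assert res1.map50 == pytest.approx(res2.map50)
        assert res1.map50_95 == pytest.approx(res2.map50_95)
        assert (res1.tp, res1.fp, res1.fn) == (res2.tp, res2.fp, res2.fn)

    def test_ap_non_increasing_in_iou_threshold(self, rng):
        for _ in range(5):
            dets, gts = _random_eval_fixture(rng)
            res = map_suite(dets, gts)
            for cls, by_thr in res.per_class_ap.items():
                thrs = sorted(by_thr)
                aps = [by_thr[t] for t in thrs]
                assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))

    def test_agrees_with_reference_evaluator_on_50_fixtures(self, rng):
        """The mAP suite matches the independent loop-based evaluator within
        1e-4 across 50 random detection/ground-truth fixtures."""
        for _ in range(50):
            dets, gts = _random_eval_fixture(rng)
            res = map_suite(dets, gts)
            ref50, ref5095 = reference_map_suite(dets, gts, IOU_THRESHOLDS_50_95)
            assert abs(res.map50 - ref50) <= 1e-4
            assert abs(res.map50_95 - ref5095) <= 1e-4


class TestNms:
    def test_suppresses_overlapping_keeps_distinct(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [50, 50, 60, 60]])
        keep = nms(boxes, np.array([0.9, 0.8, 0.7]), 0.45)
        assert sorted(keep.tolist()) == [0, 2]

    def test_keeps_all_when_disjoint(self):
        boxes = np.array([[0, 0, 5, 5], [10, 10, 15, 15]])
        assert len(nms(boxes, np.array([0.5, 0.6]), 0.45)) == 2


def test_validation_of_boxes():
    with pytest.raises(ValueError, match="positive area"):
        GroundTruthBox(0, (5, 5, 5, 9))
    with pytest.raises(ValueError, match="confidence"):
        DetectionBox(0, (0, 0, 1, 1), 1.5)
    with pytest.raises(ValueError, match="finite"):
        DetectionBox(0, (0, 0, np.inf, 1), 0.5)
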