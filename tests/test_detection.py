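"""IoU, greedy matching, AP/mAP and the reference phantom detector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsaflow import detection
from dsaflow.dataio import new_detection_table
from dsaflow.detection import (
    BoundingBox,
    average_precision,
    evaluate_detections,
    iou,
    match_greedy,
    mean_average_precision,
    reference_detect,
)


def ap_envelope_oracle(flags, n_truth):
    """Independent AP computation: explicit double-loop precision envelope.

    AP = sum over true positives of (1/n_truth) * max precision at any
    rank at or below that TP's rank.
    """
    tp = 0
    precisions = []
    for k, f in enumerate(flags, start=1):
        tp += bool(f)
        precisions.append(tp / k)
    ap = 0.0
    for k, f in enumerate(flags):
        if f:
            ap += max(precisions[k:]) / n_truth
    return ap


def _boxes_table(rows):
    return new_detection_table(rows)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0

    def test_half_overlap_worked_value(self):
        # [0,10)x[0,10) vs [5,15)x[0,10): intersection 50, union 150
        assert iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_disjoint(self):
        assert iou((0, 0, 5, 5), (10, 10, 20, 20)) == 0.0

    def test_degenerate_box_rejected_by_type(self):
        with pytest.raises(ValueError):
            BoundingBox(5, 0, 5, 10)

    @given(st.lists(st.integers(0, 50), min_size=8, max_size=8))
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_and_range(self, coords):
        ax0, ay0, bx0, by0, aw, ah, bw, bh = coords
        a = (ax0, ay0, ax0 + aw + 1, ay0 + ah + 1)
        b = (bx0, by0, bx0 + bw + 1, by0 + bh + 1)
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0


class TestMatchGreedy:
    def test_double_detection_single_match(self):
        truths = _boxes_table([("c", 0, "vein", 0, 0, 10, 10, np.nan)])
        preds = _boxes_table([
            ("c", 0, "vein", 1, 0, 11, 10, 0.8),
            ("c", 0, "vein", 0, 0, 10, 10, 0.9),
        ])
        flags, unmatched = match_greedy(preds, truths, 0.5)
        assert flags == [True, False]  # higher score wins the single truth
        assert unmatched == 0

    def test_prediction_on_truthless_frame_is_fp(self):
        truths = _boxes_table([("c", 0, "vein", 0, 0, 10, 10, np.nan)])
        preds = _boxes_table([("c", 5, "vein", 0, 0, 10, 10, 0.9)])
        flags, unmatched = match_greedy(preds, truths, 0.5)
        assert flags == [False] and unmatched == 1

    def test_strict_iou_threshold(self):
        truths = _boxes_table([("c", 0, "vein", 0, 0, 100, 10, np.nan)])
        # overlap 49x10 of union 151x10 -> IoU 0.3245 < 0.5
        preds = _boxes_table([("c", 0, "vein", 51, 0, 151, 10, 0.9)])
        flags, _ = match_greedy(preds, truths, 0.5)
        assert flags == [False]


class TestAveragePrecision:
    def test_perfect_predictions(self):
        truths = _boxes_table([
            ("c", f, "vein", 0, 0, 10, 10, np.nan) for f in range(3)
        ])
        preds = _boxes_table([
            ("c", f, "vein", 0, 0, 10, 10, 1.0) for f in range(3)
        ])
        assert average_precision(preds, truths) == 1.0

    def test_worked_tp_fp_tp_sequence(self):
        # 2 truths; ranked TP, FP, TP -> AP = 0.5*1 + 0.5*(2/3)
        truths = _boxes_table([
            ("c", 0, "vein", 0, 0, 10, 10, np.nan),
            ("c", 1, "vein", 0, 0, 10, 10, np.nan),
        ])
        preds = _boxes_table([
            ("c", 0, "vein", 0, 0, 10, 10, 0.9),   # TP
            ("c", 2, "vein", 0, 0, 10, 10, 0.8),   # FP (no truth on frame 2)
            ("c", 1, "vein", 0, 0, 10, 10, 0.7),   # TP
        ])
        assert average_precision(preds, truths) == pytest.approx(
            0.5 * 1.0 + 0.5 * (2 / 3)
        )

    def test_all_false_positives(self):
        truths = _boxes_table([("c", 0, "vein", 0, 0, 10, 10, np.nan)])
        preds = _boxes_table([("c", 3, "vein", 0, 0, 10, 10, 0.9)])
        assert average_precision(preds, truths) == 0.0

    def test_matches_bruteforce_envelope_on_random_instances(self):
        """All-point interpolation equals the explicit envelope oracle."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_truth = int(rng.integers(1, 5))
            n_pred = int(rng.integers(0, 7))
            truths = _boxes_table([
                ("c", int(rng.integers(0, 3)), "vein",
                 x := int(rng.integers(0, 20)), y := int(rng.integers(0, 20)),
                 x + int(rng.integers(4, 12)), y + int(rng.integers(4, 12)),
                 np.nan)
                for _ in range(n_truth)
            ])
            preds = _boxes_table([
                ("c", int(rng.integers(0, 3)), "vein",
                 x := int(rng.integers(0, 20)), y := int(rng.integers(0, 20)),
                 x + int(rng.integers(4, 12)), y + int(rng.integers(4, 12)),
                 round(float(rng.random()), 2))
                for _ in range(n_pred)
            ])
            ap = average_precision(preds, truths, 0.5)
            flags, _ = match_greedy(preds, truths, 0.5)
            assert ap == pytest.approx(ap_envelope_oracle(flags, n_truth), abs=1e-9)

    def test_score_rescaling_invariance(self):
        truths = _boxes_table([
            ("c", f, "vein", 0, 0, 10, 10, np.nan) for f in range(3)
        ])
        preds_rows = [("c", 0, "vein", 0, 0, 10, 10, 0.9),
                      ("c", 5, "vein", 0, 0, 10, 10, 0.6),
                      ("c", 1, "vein", 1, 0, 11, 10, 0.3)]
        ap1 = average_precision(_boxes_table(preds_rows), truths)
        scaled = [(c, f, l, a, b, x, y, s * 0.5) for c, f, l, a, b, x, y, s in preds_rows]
        ap2 = average_precision(_boxes_table(scaled), truths)
        assert ap1 == ap2


class TestMeanAveragePrecision:
    def test_mean(self):
        assert mean_average_precision({"a": 1.0, "b": 0.5}) == 0.75

    def test_single_class(self):
        assert mean_average_precision({"a": 0.7}) == pytest.approx(0.7)

    def test_no_classes_is_error(self):
        with pytest.raises(ValueError):
            mean_average_precision({})

    def test_map_between_min_and_max_ap(self):
        rng = np.random.default_rng(3)
        aps = {f"c{i}": float(rng.random()) for i in range(5)}
        m = mean_average_precision(aps)
        assert min(aps.values()) <= m <= max(aps.values())


class TestReferenceDetector:
    def test_capillary_gap_frames_empty(self, normal_case):
        det = reference_detect(normal_case.frames)
        s = normal_case.schedule
        gap = set(range(s.arterial_end + 1, s.venous_start))
        assert not set(det["frame"]).intersection(gap)

    def test_arterial_frame_boxes_match_truth(self, normal_case):
        det = reference_detect(normal_case.frames)
        s = normal_case.schedule
        f = s.onset["carotid_artery"] + 2  # fully ramped arterial frame
        got = det[det["frame"] == f]
        assert set(got["label"]) == {"carotid_artery", "willis_circle"}
        truth = normal_case.truth_boxes.query("frame == @f")
        for _, row in got.iterrows():
            t = truth[truth["label"] == row["label"]].iloc[0]
            v = iou(
                (row["x_min"], row["y_min"], row["x_max"], row["y_max"]),
                (t["x_min"], t["y_min"], t["x_max"], t["y_max"]),
            )
            assert v >= 0.9

    @pytest.mark.parametrize("which", ["avm_case", "normal_case"])
    def test_noise_free_case_scores_perfect_ap(self, which, request):
        case = request.getfixturevalue(which)
        det = reference_detect(case.frames)
        result = evaluate_detections(det, case.truth_boxes)
        for cls, ap in result.per_class_ap.items():
            assert ap == 1.0, cls
        assert result.map == 1.0

    def test_deterministic(self, avm_case):
        a = reference_detect(avm_case.frames)
        b = reference_detect(avm_case.frames)
        import pandas as pd

        pd.testing.assert_frame_equal(a, b)
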