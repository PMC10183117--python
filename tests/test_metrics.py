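"""IoU matching, precision/recall sweep and AP against enumeration oracles."""

import itertools

import numpy as np
import pytest

from spikecam import (
    ConfigurationError,
    Detection,
    GroundTruthBox,
    PRCurve,
    StatisticsError,
    average_precision,
    evaluate_detections,
    iou,
    match_detections,
    precision_recall,
)


def det(x0, y0, x1, y1, conf, image_id="img"):
    return Detection(image_id=image_id, x_min=x0, y_min=y0, x_max=x1, y_max=y1,
                     confidence=conf)


def gt(x0, y0, x1, y1, image_id="img", box_id="b"):
    return GroundTruthBox(image_id=image_id, box_id=box_id,
                          x_min=x0, y_min=y0, x_max=x1, y_max=y1)


def brute_force_match(dets, gts, thr):
    """Enumerate every injective detection->GT assignment and select the one
    a confidence-descending greedy pass would produce, by lexicographic
    preference (higher IoU first, then earlier GT index) per detection."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    choices = [list(range(len(gts))) + [None] for _ in order]
    best_key, best_assign = None, None
    for assign in itertools.product(*choices):
        used = [g for g in assign if g is not None]
        if len(used) != len(set(used)):
            continue
        key = []
        ok = True
        for di, g in zip(order, assign):
            if g is None:
                key.append((-1.0, 0))
                continue
            if dets[di].image_id != gts[g].image_id:
                ok = False
                break
            v = iou(dets[di], gts[g])
            if v < thr:
                ok = False
                break
            key.append((v, -g))
        if not ok:
            continue
        key = tuple(key)
        if best_key is None or key > best_key:
            best_key, best_assign = key, assign
    flags = [(dets[di].confidence, g is not None) for di, g in zip(order, best_assign)]
    return flags


class TestIoU:
    def test_identical_boxes(self):
        assert iou(det(0, 0, 4, 4, 0.9), gt(0, 0, 4, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(det(0, 0, 2, 2, 0.9), gt(5, 5, 7, 7)) == 0.0

    def test_half_offset_unit_squares(self):
        a = det(0.0, 0.0, 1.0, 1.0, 0.9)
        b = det(0.5, 0.0, 1.5, 1.0, 0.9)
        assert iou(a, b) == pytest.approx(1 / 3)


class TestMatching:
    def test_perfect_detections_all_tp(self):
        gts = [gt(0, 0, 4, 4, box_id="a"), gt(10, 10, 14, 14, box_id="b")]
        dets = [det(0, 0, 4, 4, 0.9), det(10, 10, 14, 14, 0.8)]
        out = match_detections(dets, gts)
        assert out.tp == 2 and out.fp == 0 and out.fn == 0

    def test_no_detections_all_fn(self):
        out = match_detections([], [gt(0, 0, 4, 4)])
        assert out.fn == 1 and out.tp == 0

    def test_three_dets_two_gts_matches_enumeration(self):
        gts = [gt(0, 0, 10, 10, box_id="a"), gt(8, 0, 18, 10, box_id="b")]
        dets = [
            det(1, 0, 11, 10, 0.9),   # overlaps both, best for gt 0
            det(7, 0, 17, 10, 0.8),   # best remaining is gt 1
            det(0, 0, 10, 10, 0.7),   # both gts taken -> FP
        ]
        out = match_detections(dets, gts, 0.5)
        assert out.flags == brute_force_match(dets, gts, 0.5)
        assert (out.tp, out.fp, out.fn) == (2, 1, 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_d, n_g = int(rng.integers(0, 6)), int(rng.integers(0, 5))
        gts = []
        for i in range(n_g):
            x0, y0 = rng.integers(0, 20, size=2)
            gts.append(gt(x0, y0, x0 + int(rng.integers(3, 10)),
                          y0 + int(rng.integers(3, 10)), box_id=f"g{i}"))
        dets = []
        for _ in range(n_d):
            x0, y0 = rng.integers(0, 20, size=2)
            dets.append(det(x0, y0, x0 + int(rng.integers(3, 10)),
                            y0 + int(rng.integers(3, 10)),
                            round(float(rng.uniform(0.1, 1.0)), 2)))
        out = match_detections(dets, gts, 0.3)
        assert out.flags == brute_force_match(dets, gts, 0.3)
        assert out.tp + out.fn == n_g  # conservation

    def test_cross_image_boxes_never_match(self):
        out = match_detections([det(0, 0, 4, 4, 0.9, image_id="x")],
                               [gt(0, 0, 4, 4, image_id="y")])
        assert out.tp == 0 and out.fp == 1 and out.fn == 1

    @pytest.mark.parametrize("thr", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_threshold_rejected(self, thr):
        with pytest.raises(ConfigurationError):
            match_detections([], [], iou_threshold=thr)


class TestPrecisionRecall:
    def test_precision_arithmetic(self):
        gts = [gt(i * 10, 0, i * 10 + 5, 5, box_id=f"g{i}") for i in range(3)]
        dets = [det(i * 10, 0, i * 10 + 5, 5, 0.9 - 0.1 * i) for i in range(3)]
        dets.append(det(50, 50, 55, 55, 0.5))  # FP last
        curve = precision_recall(match_detections(dets, gts))
        assert curve.precisions[-1] == pytest.approx(0.75)  # TP=3, FP=1

    def test_recall_arithmetic(self):
        gts = [gt(i * 10, 0, i * 10 + 5, 5, box_id=f"g{i}") for i in range(4)]
        dets = [det(i * 10, 0, i * 10 + 5, 5, 0.9 - 0.1 * i) for i in range(3)]
        curve = precision_recall(match_detections(dets, gts))
        assert curve.recalls[-1] == pytest.approx(0.75)  # TP=3, FN=1

    def test_five_detection_sweep_matches_hand_tabulation(self):
        gts = [gt(i * 10, 0, i * 10 + 6, 6, box_id=f"g{i}") for i in range(4)]
        # TP, FP, TP, FP, TP at confidences 0.9 .. 0.5
        dets = [
            det(0, 0, 6, 6, 0.9),
            det(40, 40, 46, 46, 0.8),
            det(10, 0, 16, 6, 0.7),
            det(50, 50, 56, 56, 0.6),
            det(20, 0, 26, 6, 0.5),
        ]
        curve = precision_recall(match_detections(dets, gts))
        np.testing.assert_allclose(curve.recalls, [0.25, 0.25, 0.5, 0.5, 0.75])
        np.testing.assert_allclose(curve.precisions, [1.0, 0.5, 2 / 3, 0.5, 0.6])

    def test_empty_problem_rejected(self):
        with pytest.raises(StatisticsError):
            precision_recall(match_detections([], []))

    def test_recall_nondecreasing(self, rng):
        gts = [gt(i * 10, 0, i * 10 + 6, 6, box_id=f"g{i}") for i in range(5)]
        starts = [int(rng.integers(0, 50)) for _ in range(8)]
        dets = [det(x0, 0, x0 + 6, 6, float(rng.uniform(0.1, 1))) for x0 in starts]
        curve = precision_recall(match_detections(dets, gts))
        assert (np.diff(curve.recalls) >= 0).all()


def ap_oracle(recalls, precisions):
    """Direct step-area sum over the interpolated-precision envelope."""
    pts = sorted(zip(recalls, precisions))
    area, prev_r = 0.0, 0.0
    for r, _ in pts:
        if r > prev_r:
            env = max(p for rr, p in pts if rr >= r)
            area += (r - prev_r) * env
            prev_r = r
    return area


class TestAveragePrecision:
    def test_perfect_detector_ap_one(self):
        gts = [gt(i * 10, 0, i * 10 + 5, 5, box_id=f"g{i}") for i in range(3)]
        dets = [det(i * 10, 0, i * 10 + 5, 5, 1.0 - 0.1 * i) for i in range(3)]
        assert evaluate_detections(dets, gts).ap == pytest.approx(1.0)

    def test_all_false_positives_ap_zero(self):
        gts = [gt(0, 0, 5, 5)]
        dets = [det(50, 50, 55, 55, 0.9), det(60, 60, 65, 65, 0.8)]
        assert evaluate_detections(dets, gts).ap == 0.0

    def test_two_point_curve_closed_form(self):
        curve = PRCurve(recalls=np.array([0.5, 1.0]),
                        precisions=np.array([1.0, 0.5]),
                        confidences=np.array([0.9, 0.8]))
        assert average_precision(curve) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_step_area_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gts = [gt(i * 12, 0, i * 12 + 6, 6, box_id=f"g{i}") for i in range(4)]
        dets = []
        for _ in range(int(rng.integers(1, 6))):
            if rng.uniform() < 0.6:
                g = gts[int(rng.integers(4))]
                dets.append(det(g.x_min, 0, g.x_max, 6, float(rng.uniform(0.2, 1))))
            else:
                dets.append(det(100, 100, 106, 106, float(rng.uniform(0.2, 1))))
        curve = precision_recall(match_detections(dets, gts))
        got = average_precision(curve)
        assert got == pytest.approx(ap_oracle(curve.recalls, curve.precisions), abs=1e-12)
        assert 0.0 <= got <= 1.0

    def test_invariant_under_monotone_confidence_rescale(self):
        gts = [gt(i * 12, 0, i * 12 + 6, 6, box_id=f"g{i}") for i in range(3)]
        dets = [det(0, 0, 6, 6, 0.9), det(12, 0, 18, 6, 0.6), det(90, 90, 96, 96, 0.4)]
        ap1 = evaluate_detections(dets, gts).ap
        squeezed = [Detection(d.image_id, d.x_min, d.y_min, d.x_max, d.y_max,
                              d.confidence ** 3) for d in dets]
        assert evaluate_detections(squeezed, gts).ap == pytest.approx(ap1)

    def test_eleven_point_variant_close_to_all_point(self):
        gts = [gt(i * 12, 0, i * 12 + 6, 6, box_id=f"g{i}") for i in range(4)]
        dets = [det(i * 12, 0, i * 12 + 6, 6, 0.9 - 0.1 * i) for i in range(3)]
        curve = precision_recall(match_detections(dets, gts))
        a_all = average_precision(curve, "interp_all")
        a_11 = average_precision(curve, "interp_11")
        assert abs(a_all - a_11) < 0.15

    def test_empty_curve_rejected(self):
        with pytest.raises(StatisticsError):
            average_precision(PRCurve(recalls=np.empty(0), precisions=np.empty(0),
                                      confidences=np.empty(0)))
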