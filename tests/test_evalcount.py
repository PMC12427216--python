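"""NMS, counting metrics and detection metrics against brute-force oracles."""

import numpy as np
import pytest

from pigletdet.config import BoundingBox, Detection
from pigletdet.evalcount import (average_precision, count_from_detections,
                                 counting_metrics, counting_report,
                                 detection_metrics, nms)


def _det(cls, cx, cy, w, h, score):
    return Detection(BoundingBox(cls, cx, cy, w, h), score)


# ---------------------------------------------------------------------------
# NMS
# ---------------------------------------------------------------------------

def test_nms_keeps_higher_scored_duplicate():
    dets = [_det(0, 0.5, 0.5, 0.2, 0.2, 0.9), _det(0, 0.5, 0.5, 0.2, 0.2, 0.8)]
    kept = nms(dets, 0.5)
    assert len(kept) == 1 and kept[0].score == 0.9


def test_nms_keeps_disjoint_boxes():
    dets = [_det(0, 0.2, 0.2, 0.1, 0.1, 0.9), _det(0, 0.8, 0.8, 0.1, 0.1, 0.3),
            _det(1, 0.2, 0.2, 0.1, 0.1, 0.5)]
    assert len(nms(dets, 0.5)) == 3


def brute_force_nms(dets, thr):
    """O(n^2) oracle: repeatedly take the best unsuppressed detection."""
    def iou(a, b):
        ax1, ay1, ax2, ay2 = a.box.as_xyxy()
        bx1, by1, bx2, by2 = b.box.as_xyxy()
        iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
        ih = max(0.0, min(ay2, by2) - max(ay1, by1))
        inter = iw * ih
        ua = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
        return inter / ua if ua > 0 else 0.0

    remaining = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(dets[best])
        remaining = [i for i in remaining
                     if dets[i].box.class_id != dets[best].box.class_id
                     or iou(dets[i], dets[best]) <= thr]
    return kept


def test_nms_agrees_with_brute_force_oracle(rng):
    for _ in range(100):
        dets = []
        for _i in range(int(rng.integers(1, 12))):
            w, h = rng.uniform(0.05, 0.4, 2)
            dets.append(_det(int(rng.integers(0, 2)),
                             rng.uniform(w / 2, 1 - w / 2),
                             rng.uniform(h / 2, 1 - h / 2), w, h,
                             float(rng.uniform(0, 1))))
        got = nms(dets, 0.45)
        want = brute_force_nms(dets, 0.45)
        assert [(d.score, d.box.cx) for d in got] == [(d.score, d.box.cx) for d in want]


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def test_count_from_detections():
    dets = [_det(0, 0.2, 0.2, 0.1, 0.1, 0.9)] * 3 + [_det(1, 0.5, 0.1, 0.1, 0.1, 0.8)]
    assert count_from_detections(dets, 0) == 3
    assert count_from_detections(dets, 1) == 1
    assert count_from_detections([], 0) == 0


def test_count_monotone_in_confidence_cutoff(rng):
    dets = [_det(0, 0.5, 0.5, 0.1, 0.1, float(s)) for s in rng.uniform(0, 1, 20)]
    counts = [count_from_detections(dets, 0, c) for c in np.linspace(0, 1, 11)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_counting_metrics_hand_computed_case():
    r = counting_metrics([5, 4], [4, 6])
    assert r.mae == pytest.approx(1.5)
    assert r.mse == pytest.approx(2.5)
    assert r.mar == pytest.approx(115.0)


def test_counting_metrics_perfect_prediction():
    r = counting_metrics([3, 7, 1], [3, 7, 1])
    assert (r.mae, r.mse, r.mar) == (0.0, 0.0, pytest.approx(100.0))


def test_counting_metrics_zero_ground_truth_errors():
    with pytest.raises(ValueError, match="exclude"):
        counting_metrics([2, 0], [2, 1])


def test_counting_report_excludes_zero_gt_from_mar_only():
    r = counting_report([2, 0, 4], [2, 1, 2], 0)
    assert r.mae == pytest.approx(1.0)          # keeps the zero-gt image
    assert r.mar == pytest.approx((1.0 + 0.5) / 2 * 100)  # excludes it


def test_mse_dominates_squared_mae(rng):
    """Jensen: MSE >= MAE^2 on arbitrary count vectors."""
    for _ in range(50):
        y = rng.integers(1, 10, 8)
        yh = rng.integers(0, 12, 8)
        r = counting_metrics(y, yh)
        assert r.mse >= r.mae**2 - 1e-12


def test_mar_is_linear_in_prediction_scale():
    y = [2, 5, 4]
    yh = np.array([3, 4, 6])
    base = counting_metrics(y, yh).mar
    assert counting_metrics(y, 3 * yh).mar == pytest.approx(3 * base)


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------

def _gt(cls, cx, cy, w, h):
    return BoundingBox(cls, cx, cy, w, h)


def test_perfect_detector_scores_one(rng):
    all_dets, all_gts = [], []
    for _ in range(5):
        gts = []
        dets = []
        for _i in range(int(rng.integers(1, 5))):
            w, h = rng.uniform(0.08, 0.3, 2)
            cx = rng.uniform(w / 2, 1 - w / 2)
            cy = rng.uniform(h / 2, 1 - h / 2)
            cls = int(rng.integers(0, 2))
            gts.append(_gt(cls, cx, cy, w, h))
            dets.append(_det(cls, cx, cy, w, h, 0.99))
        all_dets.append(dets)
        all_gts.append(gts)
    m = detection_metrics(all_dets, all_gts)
    assert m.precision == pytest.approx(1.0)
    assert m.recall == pytest.approx(1.0)
    assert m.map50 == pytest.approx(1.0)
    assert m.map50_95 == pytest.approx(1.0)


def test_one_tp_one_fp_precision_recall():
    gts = [[_gt(0, 0.5, 0.5, 0.2, 0.2)]]
    dets = [[_det(0, 0.5, 0.5, 0.2, 0.2, 0.9),
             _det(0, 0.1, 0.1, 0.1, 0.1, 0.5)]]
    m = detection_metrics(dets, gts, conf_threshold=0.0)
    assert m.precision == pytest.approx(0.5)
    assert m.recall == pytest.approx(1.0)


def reference_ap(scored, n_gt):
    """Independent 101-point interpolated AP (explicit loop formulation)."""
    pairs = sorted(scored, key=lambda x: -x[0])
    tps = np.array([1 if t else 0 for _, t in pairs], dtype=float)
    fps = 1 - tps
    ctp, cfp = np.cumsum(tps), np.cumsum(fps)
    rec = ctp / n_gt
    prec = ctp / np.maximum(ctp + cfp, 1e-12)
    total = 0.0
    for r in np.linspace(0, 1, 101):
        ps = [p for p, rr in zip(prec, rec) if rr >= r]
        total += max(ps) if ps else 0.0
    return total / 101


def test_ap_agrees_with_independent_reference(rng):
    for _ in range(20):
        n_gt = int(rng.integers(1, 10))
        scored = [(float(rng.uniform(0, 1)), bool(rng.integers(0, 2)))
                  for _ in range(int(rng.integers(1, 25)))]
        got = average_precision(scored, n_gt)
        assert got == pytest.approx(reference_ap(scored, n_gt), abs=1e-6)


def test_ap_invariant_to_zero_score_duplicates(rng):
    scored = [(0.9, True), (0.6, False), (0.5, True)]
    base = average_precision(scored, 3)
    padded = scored + [(0.0, False)] * 5
    # zero-score false positives only extend the tail of the PR curve at
    # recall levels already reached, leaving interpolated AP unchanged
    assert average_precision(padded, 3) == pytest.approx(base, abs=1e-9)


def test_adding_true_positive_never_lowers_recall():
    gts = [[_gt(0, 0.5, 0.5, 0.2, 0.2), _gt(0, 0.2, 0.2, 0.1, 0.1)]]
    dets = [[_det(0, 0.5, 0.5, 0.2, 0.2, 0.9)]]
    before = detection_metrics(dets, gts, conf_threshold=0.0).recall
    dets2 = [dets[0] + [_det(0, 0.2, 0.2, 0.1, 0.1, 0.8)]]
    after = detection_metrics(dets2, gts, conf_threshold=0.0).recall
    assert after >= before
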