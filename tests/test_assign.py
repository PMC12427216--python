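"""CIoU, the alignment metric, the dynamic-alpha schedule, the task-aligned
assigner (against an exhaustive-search oracle) and the composite loss."""

import numpy as np
import pytest

from pigletdet.assign import (AssignmentState, alignment_metric, assign, ciou,
                              ciou_matrix, dynamic_alpha, total_loss)
from pigletdet.config import BoundingBox, ModelConfig
from pigletdet.data_io import AnnotationRecord
from pigletdet.head import HeadOutputs, make_anchor_points
from pigletdet.nn.autograd import Tensor


# ---------------------------------------------------------------------------
# CIoU
# ---------------------------------------------------------------------------

def test_ciou_identical_boxes_is_one():
    b = BoundingBox(0, 0.5, 0.5, 0.2, 0.3)
    assert ciou(b, b) == pytest.approx(1.0, abs=1e-6)


def test_ciou_hand_computed_offset_squares():
    """Equal unit-aspect boxes offset by half a width: closed-form value."""
    a = (0.0, 0.0, 2.0, 2.0)
    b = (1.0, 0.0, 3.0, 2.0)
    # IoU = 2/6; enclosing diag^2 = 3^2+2^2 = 13; centre dist^2 = 1; v = 0
    assert ciou(a, b) == pytest.approx(2 / 6 - 1 / 13, abs=1e-9)


def test_ciou_far_separated_is_negative():
    assert ciou((0, 0, 0.1, 0.1), (5, 5, 5.1, 5.1)) < 0


def test_ciou_never_exceeds_iou(rng):
    boxes = rng.uniform(0, 1, (20, 4))
    boxes[:, 2:] = boxes[:, :2] + rng.uniform(0.05, 0.5, (20, 2))
    c = ciou_matrix(boxes, boxes)
    # plain IoU for comparison
    from pigletdet.evalcount import _iou_xyxy
    for i in range(20):
        ious = _iou_xyxy(boxes[i], boxes)
        assert np.all(c[i] <= ious + 1e-9)


def test_ciou_rejects_degenerate_box():
    with pytest.raises(ValueError, match="degenerate"):
        ciou((0, 0, 0, 1), (0, 0, 1, 1))


# ---------------------------------------------------------------------------
# alignment metric
# ---------------------------------------------------------------------------

def test_alignment_metric_values():
    assert alignment_metric(1.0, 1.0, 0.7, 3.0) == pytest.approx(1.0)
    assert alignment_metric(0.5, 0.8, 0.5, 6.0) == pytest.approx(0.5**0.5 * 0.8**6)
    assert alignment_metric(0.5, 0.8, 0.5, 6.0) == pytest.approx(0.18537, abs=1e-5)
    # alpha = 0: classification ignored entirely
    assert alignment_metric(0.123, 0.8, 0.0, 6.0) == pytest.approx(0.8**6)
    # negative overlap clamps to zero
    assert alignment_metric(0.9, -0.4, 0.5, 6.0) == 0.0


def test_alignment_metric_monotone(rng):
    s = rng.uniform(0, 1, 50)
    u = rng.uniform(0, 1, 50)
    t = alignment_metric(s, u, 0.5, 6.0)
    t_s = alignment_metric(np.minimum(s + 0.05, 1.0), u, 0.5, 6.0)
    t_u = alignment_metric(s, u + 0.05, 0.5, 6.0)
    assert np.all(t_s >= t) and np.all(t_u >= t)


# ---------------------------------------------------------------------------
# dynamic alpha
# ---------------------------------------------------------------------------

def test_dynamic_alpha_endpoints_and_linearity():
    assert dynamic_alpha(0, 100, 0.5) == 0.5
    assert dynamic_alpha(100, 100, 0.5) == 0.0
    assert dynamic_alpha(25, 100, 0.5) == pytest.approx(0.375)
    grid = np.array([dynamic_alpha(e, 100, 0.5) for e in range(101)])
    assert np.allclose(grid, 0.5 * (100 - np.arange(101)) / 100)
    assert np.all(np.diff(grid) < 0)  # strictly decreasing


def test_dynamic_alpha_rejects_out_of_range():
    with pytest.raises(ValueError):
        dynamic_alpha(101, 100, 0.5)
    with pytest.raises(ValueError):
        dynamic_alpha(0, 0, 0.5)


def test_late_training_alignment_depends_on_overlap_only():
    """At the alpha = 0 endpoint, t = u^beta regardless of s."""
    u = 0.63
    t1 = alignment_metric(0.05, u, dynamic_alpha(100, 100), 6.0)
    t2 = alignment_metric(0.95, u, dynamic_alpha(100, 100), 6.0)
    assert t1 == pytest.approx(t2) == pytest.approx(u**6)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def brute_force_assign(anchor_points, gt_boxes, gt_classes, cls_scores,
                       overlaps, state):
    """Exhaustive oracle: independent top-k + conflict resolution."""
    m = len(gt_boxes)
    t = np.zeros((m, len(anchor_points)))
    chosen = []
    for gi in range(m):
        x1, y1, x2, y2 = gt_boxes[gi]
        scores = []
        for ai, (ax, ay) in enumerate(anchor_points):
            if not (x1 < ax < x2 and y1 < ay < y2):
                continue
            s = cls_scores[ai, gt_classes[gi]]
            u = max(overlaps[gi, ai], 0.0)
            t[gi, ai] = s**state.alpha * u**state.beta
            scores.append((t[gi, ai], ai))
        scores.sort(key=lambda p: (-p[0], p[1]))
        chosen.append([ai for _, ai in scores[:state.topk]])
    final = [[] for _ in range(m)]
    all_anchors = sorted({ai for sel in chosen for ai in sel})
    for ai in all_anchors:
        claimants = [gi for gi in range(m) if ai in chosen[gi]]
        best = max(claimants, key=lambda gi: (t[gi, ai], -gi))
        final[best].append(ai)
    return [np.array(sorted(f), dtype=int) for f in final]


def _random_scene(rng, n_anchors=64, max_gt=4):
    side = int(np.sqrt(n_anchors))
    anchors = make_anchor_points(side, side)
    m = int(rng.integers(1, max_gt + 1))
    centres = rng.uniform(1, side - 1, (m, 2))
    sizes = rng.uniform(1.0, side / 2, (m, 2))
    gt = np.stack([centres[:, 0] - sizes[:, 0] / 2, centres[:, 1] - sizes[:, 1] / 2,
                   centres[:, 0] + sizes[:, 0] / 2, centres[:, 1] + sizes[:, 1] / 2],
                  axis=1)
    gt_cls = rng.integers(0, 2, m)
    scores = rng.uniform(0, 1, (len(anchors), 2))
    overlaps = rng.uniform(-0.2, 1.0, (m, len(anchors)))
    return anchors, gt, gt_cls, scores, overlaps


def test_assign_selects_top_k_by_alignment():
    anchors = np.array([[0.5, 0.5], [1.5, 0.5], [2.5, 0.5], [3.5, 0.5], [4.5, 0.5]])
    gt = np.array([[0.0, 0.0, 5.0, 1.0]])
    scores = np.array([[0.9], [0.8], [0.7], [0.2], [0.1]])
    overlaps = np.array([[0.9, 0.8, 0.7, 0.2, 0.1]])
    pos, _ = assign(anchors, gt, np.array([0]), scores, overlaps,
                    AssignmentState(topk=3))
    assert list(pos[0]) == [0, 1, 2]


def test_assign_agrees_with_exhaustive_oracle():
    state = AssignmentState(default_alpha=0.5, beta=6.0, topk=5,
                            current_epoch=20, max_epochs=100)
    rng = np.random.default_rng(7)
    for _ in range(100):
        anchors, gt, gt_cls, scores, overlaps = _random_scene(rng)
        got = assign(anchors, gt, gt_cls, scores, overlaps, state)[0]
        want = brute_force_assign(anchors, gt, gt_cls, scores, overlaps, state)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert np.array_equal(g, w)
            assert len(g) <= state.topk


def test_assign_no_ground_truths_is_empty():
    pos, t = assign(make_anchor_points(4, 4), np.zeros((0, 4)), np.zeros(0, int),
                    np.zeros((16, 2)), np.zeros((0, 16)), AssignmentState())
    assert pos == [] and t.shape == (0, 16)


def test_assign_conflict_tie_goes_to_lower_gt_index():
    anchors = np.array([[1.0, 1.0]])
    gt = np.tile([0.0, 0.0, 2.0, 2.0], (2, 1))  # two identical gts claim it
    scores = np.array([[0.5, 0.5]])
    overlaps = np.array([[0.8], [0.8]])
    pos, _ = assign(anchors, gt, np.array([0, 1]), scores, overlaps,
                    AssignmentState(topk=3))
    assert list(pos[0]) == [0] and list(pos[1]) == []


def test_assign_monotone_under_score_increase():
    """Raising a selected candidate's s or u never evicts it."""
    state = AssignmentState(topk=3, current_epoch=0, max_epochs=100)
    rng = np.random.default_rng(11)
    for _ in range(20):
        anchors, gt, gt_cls, scores, overlaps = _random_scene(rng)
        pos, _ = assign(anchors, gt, gt_cls, scores, overlaps, state)
        for gi, sel in enumerate(pos):
            for ai in sel[:2]:
                s2 = scores.copy()
                s2[ai, gt_cls[gi]] = min(1.0, s2[ai, gt_cls[gi]] + 0.2)
                o2 = overlaps.copy()
                o2[gi, ai] = min(1.0, o2[gi, ai] + 0.2)
                pos2, _ = assign(anchors, gt, gt_cls, s2, o2, state)
                assert ai in pos2[gi]


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _head_outputs(cls_logits, box_dist, grid=4):
    return HeadOutputs(Tensor(cls_logits), Tensor(box_dist),
                       make_anchor_points(grid, grid), 8, (grid, grid))


def test_loss_zero_for_perfect_point_mass_predictions():
    """Saturated correct scores + point-mass distributions at the true side
    distances drive the box and distribution terms to ~0."""
    cfg = ModelConfig(num_classes=2, reg_max=8, topk=4)
    grid = 4
    # gt with corners at half-integers (0.5, 0.5)..(3.5, 3.5) in grid units so
    # anchor-to-side distances are exact integers representable by point masses
    rec = AnnotationRecord("img", [BoundingBox(0, 0.5, 0.5, 0.75, 0.75)])
    a = grid * grid
    anchors = make_anchor_points(grid, grid)
    box_dist = np.full((1, a, 4, 9), -20.0)
    inside = []
    for ai, (ax, ay) in enumerate(anchors):
        d = [ax - 0.5, ay - 0.5, 3.5 - ax, 3.5 - ay]
        if all(x > 0 for x in d):
            inside.append(ai)
        for side, dist in enumerate(d):
            b = int(round(np.clip(dist, 0, 8)))
            box_dist[0, ai, side, b] = 20.0
    cls_logits = np.full((1, a, 2), -20.0)
    cls_logits[0, inside, 0] = 20.0
    loss = total_loss(_head_outputs(cls_logits, box_dist), [rec], cfg,
                      AssignmentState(topk=4))
    assert loss.num_pos > 0
    assert loss.box < 1e-3
    assert loss.dfl < 1e-3


def test_loss_finite_on_random_inputs(rng):
    cfg = ModelConfig(num_classes=2, reg_max=8)
    state = AssignmentState()
    for _ in range(20):
        cls = rng.standard_normal((2, 16, 2)) * 4
        dist = rng.standard_normal((2, 16, 4, 9)) * 4
        recs = []
        for _i in range(2):
            n = int(rng.integers(0, 4))
            boxes = []
            for _j in range(n):
                w, h = rng.uniform(0.1, 0.5, 2)
                cx = rng.uniform(w / 2, 1 - w / 2)
                cy = rng.uniform(h / 2, 1 - h / 2)
                boxes.append(BoundingBox(0, cx, cy, w, h))
            recs.append(AnnotationRecord("x", boxes))
        loss = total_loss(_head_outputs(cls, dist), recs, cfg, state)
        for v in (float(loss.total.data), loss.cls, loss.box, loss.dfl):
            assert np.isfinite(v) and v >= 0


def test_loss_without_ground_truth_is_classification_only(rng):
    cfg = ModelConfig(num_classes=2, reg_max=8)
    cls = rng.standard_normal((1, 16, 2))
    dist = rng.standard_normal((1, 16, 4, 9))
    loss = total_loss(_head_outputs(cls, dist), [AnnotationRecord("e", [])],
                      cfg, AssignmentState())
    assert loss.box == 0.0 and loss.dfl == 0.0 and loss.cls > 0
    assert loss.num_pos == 0


def test_loss_components_match_straight_line_reference():
    """Single gt, alpha = 0, beta = 1: every quantity is hand-computable and
    the classification term matches an independent BCE transcription."""
    cfg = ModelConfig(num_classes=1, reg_max=8, topk=1, loss_weights=(1.0, 1.0, 1.0))
    grid = 2
    rec = AnnotationRecord("img", [BoundingBox(0, 0.5, 0.5, 0.9, 0.9)])
    a = grid * grid
    rng = np.random.default_rng(0)
    cls_logits = rng.standard_normal((1, a, 1))
    box_dist = rng.standard_normal((1, a, 4, 9))
    state = AssignmentState(default_alpha=0.5, beta=1.0, topk=1,
                            current_epoch=100, max_epochs=100)  # alpha = 0
    out = _head_outputs(cls_logits, box_dist, grid)
    loss = total_loss(out, [rec], cfg, state)

    # independent transcription -------------------------------------------
    from pigletdet.head import decode_pred_boxes
    from pigletdet.assign import ciou_matrix, _safe_boxes
    gt = np.array([[0.05 * grid, 0.05 * grid, 0.95 * grid, 0.95 * grid]])
    pred = decode_pred_boxes(out).data[0]
    u = ciou_matrix(gt, _safe_boxes(pred))[0]
    t = np.clip(u, 0, None) ** 1.0  # alpha = 0, beta = 1, all anchors inside
    best = int(np.argmax(t))
    target = np.zeros((a, 1))
    target[best, 0] = t[best] * (max(u[best], 0.0) / t[best])
    z = cls_logits[0]
    bce = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    want_cls = bce.sum() / max(target.sum(), 1.0)
    assert loss.cls == pytest.approx(want_cls, rel=1e-6)
    want_box = (1 - u[best]) * target[best, 0] / max(target.sum(), 1.0)
    assert loss.box == pytest.approx(want_box, rel=1e-5)
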