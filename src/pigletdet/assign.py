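"""Task-aligned sample assignment with a dynamic alpha schedule, and the
composite detection loss.

Anchors are scored by the alignment metric t = s^alpha * u+^beta, where s is
the predicted classification score for the ground-truth class and u the
(non-negative part of the) complete IoU between the predicted box and the
ground truth.  The classification exponent decays linearly over training,

    alpha(epoch) = default_alpha * (max_epochs - epoch) / max_epochs,

so early assignment is dominated by localisation quality (classification
scores are unreliable at the start) and the classification contribution
fades in as training progresses; at the final epoch alpha reaches exactly 0
and t depends on u alone.

The loss keeps the baseline composite form — binary cross-entropy with
t-scaled soft targets, complete-IoU box loss, and a distribution-focal term
on the two bins bracketing each true side distance — since the assignment
strategy, not the loss form, is what changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .config import BoundingBox, ModelConfig
from .head import HeadOutputs, decode_pred_boxes


@dataclass
class AssignmentState:
    """Knobs and counters of the task-aligned assigner."""

    default_alpha: float = 0.5
    beta: float = 6.0
    topk: int = 10
    current_epoch: int = 0
    max_epochs: int = 100

    @property
    def alpha(self) -> float:
        return dynamic_alpha(self.current_epoch, self.max_epochs, self.default_alpha)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _to_xyxy(box) -> np.ndarray:
    if isinstance(box, BoundingBox):
        return np.asarray(box.as_xyxy(), dtype=np.float64)
    b = np.asarray(box, dtype=np.float64)
    return b


def ciou(a, b) -> float:
    """Complete IoU of two boxes given as BoundingBox or (x1,y1,x2,y2).

    IoU penalised by the normalised centre distance and the aspect-ratio
    divergence; 1 iff the boxes are identical, always <= IoU, and negative
    for sufficiently separated boxes.
    """
    a, b = _to_xyxy(a), _to_xyxy(b)
    return float(ciou_matrix(a[None, :], b[None, :])[0, 0])


def ciou_matrix(a: np.ndarray, b: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Pairwise CIoU between (M,4) and (N,4) xyxy boxes."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    wa = a[:, 2] - a[:, 0]
    ha = a[:, 3] - a[:, 1]
    wb = b[:, 2] - b[:, 0]
    hb = b[:, 3] - b[:, 1]
    if np.any(wa <= 0) or np.any(ha <= 0) or np.any(wb <= 0) or np.any(hb <= 0):
        raise ValueError("degenerate zero-area box")
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    union = wa[:, None] * ha[:, None] + wb[None, :] * hb[None, :] - inter
    iou = inter / (union + eps)
    # enclosing-box diagonal
    cx1 = np.minimum(a[:, None, 0], b[None, :, 0])
    cy1 = np.minimum(a[:, None, 1], b[None, :, 1])
    cx2 = np.maximum(a[:, None, 2], b[None, :, 2])
    cy2 = np.maximum(a[:, None, 3], b[None, :, 3])
    diag2 = (cx2 - cx1) ** 2 + (cy2 - cy1) ** 2 + eps
    # centre distance
    dax = (a[:, 0] + a[:, 2]) / 2
    day = (a[:, 1] + a[:, 3]) / 2
    dbx = (b[:, 0] + b[:, 2]) / 2
    dby = (b[:, 1] + b[:, 3]) / 2
    rho2 = (dax[:, None] - dbx[None, :]) ** 2 + (day[:, None] - dby[None, :]) ** 2
    v = (4 / np.pi**2) * (np.arctan(wa / ha)[:, None] - np.arctan(wb / hb)[None, :]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = v / (1 - iou + v + eps)
    return iou - rho2 / diag2 - alpha * v


# ---------------------------------------------------------------------------
# alignment metric and alpha schedule
# ---------------------------------------------------------------------------

def alignment_metric(s, u, alpha: float, beta: float):
    """t = s^alpha * max(u, 0)^beta, elementwise on arrays or scalars."""
    s = np.asarray(s, dtype=np.float64)
    u = np.clip(np.asarray(u, dtype=np.float64), 0.0, None)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("classification score s must lie in [0,1]")
    if alpha < 0 or beta < 0:
        raise ValueError("exponents must be non-negative")
    t = s**alpha * u**beta
    return float(t) if t.ndim == 0 else t


def dynamic_alpha(current_epoch: int, max_epochs: int, default_alpha: float = 0.5) -> float:
    """Linear decay from default_alpha at epoch 0 to exactly 0 at max_epochs."""
    if max_epochs < 1:
        raise ValueError("max_epochs must be >= 1")
    if not (0 <= current_epoch <= max_epochs):
        raise ValueError(f"current_epoch {current_epoch} outside [0, {max_epochs}]")
    return default_alpha * (max_epochs - current_epoch) / max_epochs


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def assign(anchor_points: np.ndarray, gt_boxes: np.ndarray, gt_classes: np.ndarray,
           cls_scores: np.ndarray, overlaps: np.ndarray, state: AssignmentState):
    """Task-aligned top-k positive-sample selection for one image.

    Parameters
    ----------
    anchor_points : (A, 2) anchor centres, same units as the boxes.
    gt_boxes : (M, 4) xyxy ground-truth boxes.
    gt_classes : (M,) int class ids.
    cls_scores : (A, num_classes) predicted scores in [0, 1].
    overlaps : (M, A) CIoU between each ground truth and each anchor's
        predicted box (precomputed).
    state : assigner configuration; ``state.alpha`` is the current exponent.

    Returns
    -------
    positives : list of M int arrays — the anchors assigned to each ground
        truth (each of size <= topk, conflicts resolved to the ground truth
        with the larger alignment metric, ties to the lower index).
    t : (M, A) alignment-metric matrix (0 outside candidate anchors).
    """
    m = len(gt_boxes)
    a = len(anchor_points)
    if m == 0:
        return [], np.zeros((0, a))
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64)
    inside = ((anchor_points[None, :, 0] > gt_boxes[:, 0, None])
              & (anchor_points[None, :, 0] < gt_boxes[:, 2, None])
              & (anchor_points[None, :, 1] > gt_boxes[:, 1, None])
              & (anchor_points[None, :, 1] < gt_boxes[:, 3, None]))
    s = cls_scores[:, gt_classes].T  # (M, A)
    t = alignment_metric(s, overlaps, state.alpha, state.beta)
    t = np.where(inside, t, 0.0)
    # per-gt top-k among candidates, by t descending (stable: lower anchor
    # index wins ties)
    claimed = {}
    for gi in range(m):
        cand = np.flatnonzero(inside[gi])
        if len(cand) == 0:
            continue
        order = cand[np.argsort(-t[gi, cand], kind="stable")]
        for ai in order[:state.topk]:
            prev = claimed.get(ai)
            if prev is None or t[gi, ai] > t[prev, ai]:
                claimed[ai] = gi
    positives = [np.array(sorted(ai for ai, gi in claimed.items() if gi == g), dtype=int)
                 for g in range(m)]
    return positives, t


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _ciou_tensor(pred: Tensor, gt: np.ndarray, eps: float = 1e-9) -> Tensor:
    """Differentiable CIoU of predicted (P,4) xyxy boxes against fixed gts."""
    gx1, gy1, gx2, gy2 = (Tensor(gt[:, i].astype(pred.data.dtype)) for i in range(4))
    px1, py1, px2, py2 = (pred[:, i] for i in range(4))
    pw = ag.clamp_min(px2 - px1, eps)
    ph = ag.clamp_min(py2 - py1, eps)
    gw = gx2 - gx1
    gh = gy2 - gy1
    ix = ag.clamp_min(ag.maximum(px1, gx1) * -1.0 + ag.minimum(px2, gx2), 0.0)
    iy = ag.clamp_min(ag.maximum(py1, gy1) * -1.0 + ag.minimum(py2, gy2), 0.0)
    inter = ix * iy
    union = pw * ph + gw * gh - inter
    iou = inter / (union + eps)
    cw = ag.maximum(px2, gx2) - ag.minimum(px1, gx1)
    ch = ag.maximum(py2, gy2) - ag.minimum(py1, gy1)
    diag2 = cw * cw + ch * ch + eps
    rho2 = ((px1 + px2 - gx1 - gx2) * 0.5) ** 2 + ((py1 + py2 - gy1 - gy2) * 0.5) ** 2
    v = (ag.atan(pw / ph) - ag.atan(gw / gh)) ** 2 * (4 / np.pi**2)
    alpha = Tensor(v.data / (1 - iou.data + v.data + eps))  # detached, standard practice
    return iou - rho2 / diag2 - alpha * v


@dataclass
class LossBreakdown:
    total: Tensor
    cls: float
    box: float
    dfl: float
    num_pos: int


def total_loss(outputs: HeadOutputs, targets: list, config: ModelConfig,
               state: AssignmentState) -> LossBreakdown:
    """Composite loss for a batch.

    ``targets`` is a list (length N) of AnnotationRecord-like objects with a
    ``boxes`` attribute of normalised BoundingBox items.  Boxes are converted
    to stride units to match the anchor grid.
    """
    n, a, nc = outputs.cls_logits.shape
    reg_max = outputs.box_dist.shape[-1] - 1
    gh, gw = outputs.grid_hw
    pred_boxes = decode_pred_boxes(outputs)  # (N, A, 4) stride units
    cls_prob = 1.0 / (1.0 + np.exp(-outputs.cls_logits.data))

    target_scores = np.zeros((n, a, nc))
    pos_img, pos_anchor, pos_gtbox, pos_weight = [], [], [], []
    for i in range(n):
        boxes = [b for b in targets[i].boxes]
        if not boxes:
            continue
        gt = np.array([[ (b.cx - b.w / 2) * gw, (b.cy - b.h / 2) * gh,
                         (b.cx + b.w / 2) * gw, (b.cy + b.h / 2) * gh ]
                       for b in boxes])
        gt_cls = np.array([b.class_id for b in boxes], dtype=int)
        overlaps = ciou_matrix(gt, _safe_boxes(pred_boxes.data[i]))
        positives, t = assign(outputs.anchor_points, gt, gt_cls, cls_prob[i],
                              overlaps, state)
        u_pos = np.clip(overlaps, 0.0, None)
        for gi, anchors in enumerate(positives):
            if len(anchors) == 0:
                continue
            t_g = t[gi, anchors]
            norm = t_g * (u_pos[gi, anchors].max() / (t_g.max() + 1e-9))
            target_scores[i, anchors, gt_cls[gi]] = norm
            pos_img.extend([i] * len(anchors))
            pos_anchor.extend(anchors)
            pos_gtbox.extend([gt[gi]] * len(anchors))
            pos_weight.extend(norm)

    w_cls, w_box, w_dfl = config.loss_weights
    ts = Tensor(target_scores.astype(outputs.cls_logits.data.dtype))
    logits = outputs.cls_logits
    # numerically stable BCE-with-logits: max(z,0) - z*y + log(1+exp(-|z|))
    zabs = ag.maximum(logits, logits * -1.0)
    bce = ag.clamp_min(logits, 0.0) - logits * ts + ag.log(ag.exp(zabs * -1.0) + 1.0)
    denom = max(target_scores.sum(), 1.0)
    cls_loss = bce.sum() / denom

    if pos_img:
        pos_img = np.array(pos_img)
        pos_anchor = np.array(pos_anchor)
        gtb = np.array(pos_gtbox)
        wts = Tensor(np.array(pos_weight, dtype=outputs.cls_logits.data.dtype))
        pb = pred_boxes[pos_img, pos_anchor]  # (P, 4)
        ciou_vals = _ciou_tensor(pb, gtb)
        box_loss = ((1.0 - ciou_vals) * wts).sum() / denom
        # distribution focal: cross-entropy on the two bins bracketing the
        # true side distance, linearly weighted
        anchors_xy = outputs.anchor_points[pos_anchor]
        dists = np.stack([
            anchors_xy[:, 0] - gtb[:, 0], anchors_xy[:, 1] - gtb[:, 1],
            gtb[:, 2] - anchors_xy[:, 0], gtb[:, 3] - anchors_xy[:, 1],
        ], axis=1)
        dists = np.clip(dists, 0.0, reg_max - 0.01)
        lo = np.floor(dists).astype(int)
        hi = lo + 1
        w_hi = dists - lo
        w_lo = 1.0 - w_hi
        logp = ag.log_softmax(outputs.box_dist[pos_img, pos_anchor], axis=-1)  # (P,4,R+1)
        pi = np.arange(len(pos_img))[:, None]
        si = np.arange(4)[None, :]
        dfl = -(logp[pi, si, lo] * Tensor(w_lo) + logp[pi, si, hi] * Tensor(w_hi))
        dfl_loss = (dfl.mean(axis=1) * wts).sum() / denom
    else:
        box_loss = Tensor(np.float64(0.0))
        dfl_loss = Tensor(np.float64(0.0))

    total = cls_loss * w_cls + box_loss * w_box + dfl_loss * w_dfl
    return LossBreakdown(total, float(cls_loss.data), float(box_loss.data),
                         float(dfl_loss.data), len(pos_img) if isinstance(pos_img, np.ndarray) else 0)


def _safe_boxes(b: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Clamp decoded boxes to strictly positive extent for CIoU."""
    out = b.copy()
    out[:, 2] = np.maximum(out[:, 2], out[:, 0] + eps)
    out[:, 3] = np.maximum(out[:, 3], out[:, 1] + eps)
    return out
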