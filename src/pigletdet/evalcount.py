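"""Inference post-processing and evaluation: NMS, detection metrics
(precision / recall / AP / mAP) and the per-class counting statistics
MAE, MSE and MAR.

Counting metrics, per class j over N test images with ground-truth counts
y_ij and predicted counts ŷ_ij:

    MAE = (1/N) Σ |ŷ_ij − y_ij|
    MSE = (1/N) Σ (ŷ_ij − y_ij)²
    MAR = (1/N) Σ (ŷ_ij / y_ij) · 100%

MAR is undefined for images with y_ij = 0; those images are excluded from
the MAR average for that class (MAE and MSE keep them), and passing them
explicitly raises an error instructing the exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Detection


@dataclass
class CountReport:
    class_id: int
    n_images: int
    y: list
    y_hat: list
    mae: float
    mse: float
    mar: float  # percentage; may exceed 100 under overcounting


# ---------------------------------------------------------------------------
# NMS
# ---------------------------------------------------------------------------

def _iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ix1 = np.maximum(a[0], b[:, 0])
    iy1 = np.maximum(a[1], b[:, 1])
    ix2 = np.minimum(a[2], b[:, 2])
    iy2 = np.minimum(a[3], b[:, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / np.maximum(area_a + area_b - inter, 1e-12)


def nms(detections: list, iou_threshold: float = 0.5) -> list:
    """Greedy per-class non-maximum suppression.

    Detections are processed in descending score order (ties broken by the
    original list position, earlier wins); the kept list is score-sorted.
    """
    kept = []
    by_class = {}
    for i, d in enumerate(detections):
        by_class.setdefault(d.box.class_id, []).append((d.score, i, d))
    for cls in sorted(by_class):
        items = sorted(by_class[cls], key=lambda x: (-x[0], x[1]))
        boxes = np.array([d.box.as_xyxy() for _, _, d in items]) if items else np.empty((0, 4))
        suppressed = np.zeros(len(items), dtype=bool)
        for i in range(len(items)):
            if suppressed[i]:
                continue
            kept.append(items[i])
            if i + 1 < len(items):
                ious = _iou_xyxy(boxes[i], boxes[i + 1:])
                suppressed[i + 1:] |= ious > iou_threshold
    kept.sort(key=lambda x: (-x[0], x[1]))
    return [d for _, _, d in kept]


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_from_detections(detections: list, class_id: int,
                          conf_threshold: float = 0.0) -> int:
    return sum(1 for d in detections
               if d.box.class_id == class_id and d.score >= conf_threshold)


def counting_metrics(y, y_hat, class_id: int = 0) -> CountReport:
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("count vectors must have equal length")
    if np.any(y == 0):
        raise ValueError(
            "MAR is undefined for images with zero ground-truth count; "
            "exclude those images from the MAR average for this class")
    err = y_hat - y
    mae = float(np.abs(err).mean())
    mse = float((err**2).mean())
    mar = float((y_hat / y).mean() * 100.0)
    return CountReport(class_id, len(y), y.tolist(), y_hat.tolist(), mae, mse, mar)


def counting_report(records_gt, records_pred, class_id: int) -> CountReport:
    """Counting metrics from paired annotation/prediction count lists, with
    zero-ground-truth images excluded from MAR (kept in MAE/MSE)."""
    y = np.array([r for r in records_gt], dtype=np.float64)
    yh = np.array([r for r in records_pred], dtype=np.float64)
    err = yh - y
    mae = float(np.abs(err).mean())
    mse = float((err**2).mean())
    nz = y > 0
    mar = float((yh[nz] / y[nz]).mean() * 100.0) if nz.any() else float("nan")
    return CountReport(class_id, len(y), y.tolist(), yh.tolist(), mae, mse, mar)


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------

def _match_image(dets: list, gts: list, iou_thr: float):
    """Greedy matching by descending score; each gt matched at most once.

    Ties on IoU go to the higher IoU then the earlier gt index.  Returns a
    list of (score, is_tp) and the number of ground truths.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    gt_boxes = np.array([g.as_xyxy() for g in gts]) if gts else np.empty((0, 4))
    used = np.zeros(len(gts), dtype=bool)
    out = []
    for i in order:
        d = dets[i]
        best_iou, best_j = 0.0, -1
        if len(gts):
            ious = _iou_xyxy(np.array(d.box.as_xyxy()), gt_boxes)
            for j in np.argsort(-ious, kind="stable"):
                if used[j] or ious[j] < iou_thr:
                    continue
                best_iou, best_j = ious[j], j
                break
        if best_j >= 0:
            used[best_j] = True
            out.append((d.score, True))
        else:
            out.append((d.score, False))
    return out


def average_precision(scored: list, n_gt: int) -> float:
    """AP by 101-point interpolation of the precision-recall curve."""
    if n_gt == 0:
        return float("nan")
    scored = sorted(scored, key=lambda x: -x[0])
    tp = np.cumsum([1.0 if t else 0.0 for _, t in scored])
    fp = np.cumsum([0.0 if t else 1.0 for _, t in scored])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1e-12)
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        mask = recall >= r
        ap += precision[mask].max() if mask.any() else 0.0
    return ap / 101.0


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    map50: float
    map50_95: float
    per_class_ap50: dict = field(default_factory=dict)
    pr_points: dict = field(default_factory=dict)  # class -> (recalls, precisions)


def detection_metrics(all_dets: list, all_gts: list, conf_threshold: float = 0.25,
                      iou_threshold: float = 0.5) -> DetectionMetrics:
    """COCO-style metrics over a list of images.

    ``all_dets[i]`` is the detection list of image i (post-NMS);
    ``all_gts[i]`` the list of ground-truth BoundingBox.  Precision/recall
    are computed at the operating confidence; AP uses all detections.
    Classes with no ground truth anywhere are excluded from the mAP means.
    """
    classes = sorted({b.class_id for gts in all_gts for b in gts})
    ap50, ap_all, pr_points = {}, {}, {}
    tp_op = fp_op = fn_op = 0
    for cls in classes:
        n_gt = sum(sum(1 for b in gts if b.class_id == cls) for gts in all_gts)
        scored_50 = []
        ap_sum = 0.0
        for thr_i, thr in enumerate(np.arange(0.5, 0.96, 0.05)):
            scored = []
            for dets, gts in zip(all_dets, all_gts):
                d_c = [d for d in dets if d.box.class_id == cls]
                g_c = [b for b in gts if b.class_id == cls]
                scored.extend(_match_image(d_c, g_c, thr))
            if thr_i == 0:
                scored_50 = scored
            ap_sum += average_precision(scored, n_gt)
        ap50[cls] = average_precision(scored_50, n_gt)
        ap_all[cls] = ap_sum / 10.0
        # operating-point counts at IoU 0.5
        op = [(s, t) for s, t in scored_50 if s >= conf_threshold]
        tp = sum(1 for _, t in op if t)
        tp_op += tp
        fp_op += len(op) - tp
        fn_op += n_gt - tp
        sc = sorted(scored_50, key=lambda x: -x[0])
        tpc = np.cumsum([1.0 if t else 0.0 for _, t in sc])
        fpc = np.cumsum([0.0 if t else 1.0 for _, t in sc])
        pr_points[cls] = ((tpc / max(n_gt, 1)).tolist(),
                          (tpc / np.maximum(tpc + fpc, 1e-12)).tolist())
    valid = [c for c in classes if not np.isnan(ap50[c])]
    precision = tp_op / max(tp_op + fp_op, 1) if (tp_op + fp_op) else 1.0
    recall = tp_op / max(tp_op + fn_op, 1) if (tp_op + fn_op) else 1.0
    map50 = float(np.mean([ap50[c] for c in valid])) if valid else float("nan")
    map_all = float(np.mean([ap_all[c] for c in valid])) if valid else float("nan")
    return DetectionMetrics(precision, recall, map50, map_all, ap50, pr_points)


def export_pr_curves(metrics: DetectionMetrics, png_path, table_path):
    """Write the PR curves as a plotted image plus a raw points table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    lines = ["class\trecall\tprecision"]
    for cls, (rec, prec) in metrics.pr_points.items():
        ax.plot(rec, prec, label=f"class_{cls} (AP50={metrics.per_class_ap50[cls]:.3f})")
        for r, p in zip(rec, prec):
            lines.append(f"{cls}\t{r:.6f}\t{p:.6f}")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower left")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    from pathlib import Path

    Path(table_path).write_text("\n".join(lines) + "\n")
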