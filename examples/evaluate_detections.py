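"""Post-processing and metrics on a hand-built toy image set.

Demonstrates greedy NMS, precision/recall at an operating confidence, AP by
101-point interpolation, and the counting metrics on a mismatch case.
"""

from pigletdet.config import BoundingBox, Detection
from pigletdet.evalcount import counting_metrics, detection_metrics, nms

# one image, one piglet, three raw detections: two duplicates + one miss
gt = [BoundingBox(0, 0.5, 0.5, 0.2, 0.2)]
raw = [Detection(BoundingBox(0, 0.5, 0.5, 0.2, 0.2), 0.92),
       Detection(BoundingBox(0, 0.51, 0.5, 0.2, 0.2), 0.85),   # duplicate
       Detection(BoundingBox(0, 0.1, 0.1, 0.1, 0.1), 0.40)]    # false positive
kept = nms(raw, iou_threshold=0.5)
print(f"NMS kept {len(kept)} of {len(raw)} detections "
      f"(scores {[d.score for d in kept]})")

m = detection_metrics([kept], [gt], conf_threshold=0.25)
print(f"precision {m.precision:.2f}  recall {m.recall:.2f}  "
      f"mAP0.5 {m.map50:.3f}  mAP {m.map50_95:.3f}")

# counting: two test images with ground-truth counts (5, 4), predictions (4, 6)
r = counting_metrics([5, 4], [4, 6])
print(f"counting: MAE {r.mae}  MSE {r.mse}  MAR {r.mar}%")
# |4-5| and |6-4| average to MAE 1.5; the squared errors to MSE 2.5; the
# ratios 80% and 150% average to MAR 115% — an over-count on balance.
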