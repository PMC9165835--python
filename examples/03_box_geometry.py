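"""Detector box geometry: grid-cell decoding, IoU, CIoU loss, NMS.

The detection stage predicts per-grid-cell box parameters; training
regresses them with the complete-IoU (CIoU) loss, which adds a center
distance and an aspect-ratio penalty to 1 - IoU, and inference prunes
duplicates with non-maximum suppression.
"""

from cowpose import BoundingBox, GridCellPrediction, ciou_loss, decode_box, iou, nms

pred = GridCellPrediction(Cx=0, Cy=0, tx=0.5, ty=0.5, tw=1.0, th=1.0)
b = decode_box(pred)
print(f"decoded box: ({b.xmin:.4f}, {b.ymin:.4f}, {b.xmax:.4f}, {b.ymax:.4f})")

a = BoundingBox(0, 0, 2, 2)
c = BoundingBox(1, 0, 3, 2)
print(f"IoU of half-overlapping unit boxes: {iou(a, c):.4f}")  # 2/6

d = BoundingBox(4, 0, 6, 2)
print(f"CIoU loss, disjoint equal-aspect boxes: {ciou_loss(a, d):.4f}")
# 1 - 0 (IoU) + 16/40 (center term) + 0 (equal aspects) = 1.4

boxes = [
    BoundingBox(0, 0, 10, 10, confidence=0.9),
    BoundingBox(1, 1, 11, 11, confidence=0.6),  # duplicate of the first
    BoundingBox(50, 50, 55, 55, confidence=0.8),
]
kept = nms(boxes, iou_threshold=0.5)
print(f"NMS kept {len(kept)} of {len(boxes)} boxes "
      f"(confidences {[b.confidence for b in kept]})")
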