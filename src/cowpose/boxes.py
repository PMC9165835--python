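"""Bounding-box geometry: grid-cell decoding, IoU, CIoU loss, BCE, NMS.

Boxes are axis-aligned ``(xmin, ymin, xmax, ymax)`` with an attached
confidence.  Coordinates may be normalized image fractions in [0, 1] or
raw pixels; a unit flag records which, and all geometric operations are
unit-agnostic as long as the two operands agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BoundingBox",
    "GridCellPrediction",
    "decode_box",
    "iou",
    "ciou_loss",
    "confidence_bce",
    "nms",
]

_EPS = 1e-7


@dataclass(frozen=True)
class BoundingBox:
    xmin: float
    ymin: float
    xmax: float
    ymax: float
    confidence: float = 1.0
    unit: str = "pixel"  # "pixel" or "fraction"
    label: str = "cow"

    def __post_init__(self) -> None:
        if self.xmin > self.xmax or self.ymin > self.ymax:
            raise ValueError(f"inverted box {self}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence outside [0,1]: {self.confidence}")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)


@dataclass(frozen=True)
class GridCellPrediction:
    """Raw per-cell detector output on an S x S grid (S in {52, 26, 13}).

    ``(Cx, Cy)`` are the cell coordinates, ``(tx, ty)`` the center offsets
    and ``(tw, th)`` the box width and height.
    """

    Cx: float
    Cy: float
    tx: float
    ty: float
    tw: float
    th: float
    confidence: float = 0.0
    S: int = 13

    def __post_init__(self) -> None:
        if not (0 <= self.Cx < self.S and 0 <= self.Cy < self.S):
            raise ValueError(f"cell ({self.Cx},{self.Cy}) outside grid S={self.S}")


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def decode_box(pred: GridCellPrediction, mode: str = "literal") -> BoundingBox:
    """Decode a grid-cell prediction into a bounding box.

    ``mode="literal"`` applies the logistic function to the whole corner
    expression::

        xmin = sigma(tx + Cx - tw/2)   xmax = sigma(tx + Cx + tw/2)
        ymin = sigma(ty + Cy - th/2)   ymax = sigma(ty + Cy + th/2)

    which always yields fractional coordinates in (0, 1) with
    ``xmin <= xmax`` by monotonicity.  ``mode="canonical"`` is the
    conventional YOLO decoding instead: the cell offset passes through the
    logistic, the center is shifted by the cell index and divided by the
    grid size, and width/height are exponentiated::

        cx = (sigma(tx) + Cx) / S      w = exp(tw) / S
        cy = (sigma(ty) + Cy) / S      h = exp(th) / S
    """
    conf = _sigmoid(pred.confidence)
    if mode == "literal":
        return BoundingBox(
            xmin=_sigmoid(pred.tx + pred.Cx - pred.tw / 2.0),
            ymin=_sigmoid(pred.ty + pred.Cy - pred.th / 2.0),
            xmax=_sigmoid(pred.tx + pred.Cx + pred.tw / 2.0),
            ymax=_sigmoid(pred.ty + pred.Cy + pred.th / 2.0),
            confidence=conf,
            unit="fraction",
        )
    if mode == "canonical":
        cx = (_sigmoid(pred.tx) + pred.Cx) / pred.S
        cy = (_sigmoid(pred.ty) + pred.Cy) / pred.S
        w = math.exp(pred.tw) / pred.S
        h = math.exp(pred.th) / pred.S
        return BoundingBox(
            xmin=cx - w / 2.0,
            ymin=cy - h / 2.0,
            xmax=cx + w / 2.0,
            ymax=cy + h / 2.0,
            confidence=conf,
            unit="fraction",
        )
    raise ValueError(f"unknown decode mode {mode!r}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 for a zero-area union."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def ciou_loss(pred: BoundingBox, gt: BoundingBox) -> float:
    """Complete-IoU regression loss.

    ``L = 1 - IoU + d^2/c^2 + alpha * v`` where ``d`` is the distance
    between box centers, ``c`` the diagonal of the smallest enclosing box,
    ``v = (4/pi^2) * (arctan(w_gt/h_gt) - arctan(w/h))^2`` the
    aspect-ratio consistency term, and ``alpha = v / ((1 - IoU) + v)``
    (0 when ``v`` is 0).

    Requires positive heights (the aspect term divides by them).
    """
    if pred.height <= 0 or gt.height <= 0:
        raise ValueError("zero height: aspect-ratio term w/h undefined")
    u = iou(pred, gt)
    pcx, pcy = pred.center
    gcx, gcy = gt.center
    d2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    cw = max(pred.xmax, gt.xmax) - min(pred.xmin, gt.xmin)
    ch = max(pred.ymax, gt.ymax) - min(pred.ymin, gt.ymin)
    c2 = cw * cw + ch * ch
    dist_term = d2 / c2 if c2 > 0 else 0.0
    v = (4.0 / math.pi**2) * (
        math.atan(gt.width / gt.height) - math.atan(pred.width / pred.height)
    ) ** 2
    alpha = 0.0 if v == 0.0 else v / ((1.0 - u) + v)
    return 1.0 - u + dist_term + alpha * v


def confidence_bce(pred_conf: float, target: int) -> float:
    """Binary cross-entropy of an objectness score against a 0/1 target."""
    p = min(max(float(pred_conf), _EPS), 1.0 - _EPS)
    t = float(target)
    return -(t * math.log(p) + (1.0 - t) * math.log(1.0 - p))


def nms(boxes: list[BoundingBox], iou_threshold: float = 0.5) -> list[BoundingBox]:
    """Greedy non-maximum suppression.

    Keeps the highest-confidence box, drops every box whose IoU with any
    kept box is >= ``iou_threshold``, and repeats.  Order is stable:
    descending confidence, ties broken by input position.
    """
    order = sorted(range(len(boxes)), key=lambda i: (-boxes[i].confidence, i))
    kept: list[BoundingBox] = []
    for i in order:
        if all(iou(boxes[i], k) < iou_threshold for k in kept):
            kept.append(boxes[i])
    return kept
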