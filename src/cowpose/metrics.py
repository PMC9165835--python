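"""Detection, keypoint, and pose-classification metrics.

Detection follows IoU-based true/false positive rules with two modes:

* ``"literal"`` (default) — a matched prediction with IoU at or above the
  threshold is a true positive; a prediction whose best IoU falls below
  the threshold is a false positive; a ground-truth box counts as a
  false negative only when **no** prediction overlaps it at all (IoU
  exactly 0).  This is deliberately nonstandard; it mirrors a common
  informal reading of the TP/FP/FN definitions in livestock-vision work.
* ``"coco"`` — every unmatched ground-truth box is a false negative,
  the conventional rule.

Keypoint quality uses object keypoint similarity (OKS), the keypoint
analogue of IoU:

    OKS = mean over labeled GT keypoints i of exp(-d_i^2 / (2 s^2 k_i^2))

with ``d_i`` the Euclidean prediction error, ``s`` the object scale
(default: sqrt of the GT skeleton bounding-box area) and ``k_i`` a
per-part normalization constant (default 0.1 for all parts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .boxes import BoundingBox, iou
from .skeleton import N_PARTS, CowSkeleton, skeleton_bbox

__all__ = [
    "DetectionOutcome",
    "OksScore",
    "ConfusionMatrix3",
    "ConfusionMetrics",
    "classify_detections",
    "average_precision",
    "compute_oks",
    "oks_ap",
    "confusion_metrics",
]

POSE_CLASSES = ("standing", "walking", "lying")


@dataclass
class DetectionOutcome:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")


def classify_detections(
    preds: list[BoundingBox],
    gts: list[BoundingBox],
    iou_threshold: float = 0.5,
    mode: str = "literal",
) -> DetectionOutcome:
    """Count TP/FP/FN by greedy confidence-ordered box matching."""
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    if mode not in ("literal", "coco"):
        raise ValueError(f"unknown mode {mode!r}")
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))
    matched_gt: set[int] = set()
    tp = fp = 0
    for i in order:
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if j in matched_gt:
                continue
            v = iou(preds[i], g)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_iou >= iou_threshold:
            tp += 1
            matched_gt.add(best_j)
        else:
            fp += 1
    if mode == "coco":
        fn = len(gts) - len(matched_gt)
    else:
        fn = 0
        for j, g in enumerate(gts):
            if j in matched_gt:
                continue
            if all(iou(p, g) == 0.0 for p in preds):
                fn += 1
    return DetectionOutcome(tp, fp, fn)


def average_precision(pr_points: list[tuple[float, float]]) -> float:
    """All-point interpolated AP from (precision, recall) pairs.

    Integrates the precision envelope over recall: at each distinct recall
    step the precision is the maximum over all points with recall >= that
    step (monotone envelope), and AP sums step width times that envelope.
    """
    if not pr_points:
        return 0.0
    pts = sorted(pr_points, key=lambda pr: pr[1])
    recalls = np.array([r for _, r in pts])
    precisions = np.array([p for p, _ in pts])
    ap = 0.0
    prev_r = 0.0
    for r in np.unique(recalls):
        env = precisions[recalls >= r].max()
        ap += (r - prev_r) * env
        prev_r = r
    return float(ap)


@dataclass
class OksScore:
    value: float
    per_keypoint: list[float]


def compute_oks(
    pred: CowSkeleton,
    gt: CowSkeleton,
    s: float | None = None,
    k: float | np.ndarray = 0.1,
) -> OksScore:
    """Object keypoint similarity between a predicted and a GT skeleton.

    ``s`` defaults to sqrt(GT skeleton bounding-box area); degenerate
    zero-area boxes fall back to scale 1.  ``k`` may be a scalar or a
    16-vector of per-part constants.  GT keypoints with visibility 0 are
    excluded; a labeled GT part missing from the prediction contributes a
    zero term (infinite distance).
    """
    labeled = gt.labeled_keypoints
    if not labeled:
        raise ValueError("ground-truth skeleton has no labeled keypoints")
    if s is None:
        box = skeleton_bbox(gt)
        s = math.sqrt(box.area) if box.area > 0 else 1.0
    if s <= 0:
        raise ValueError("object scale s must be positive")
    kvec = np.broadcast_to(np.asarray(k, dtype=float), (N_PARTS,))
    if (kvec <= 0).any():
        raise ValueError("per-part constants k must be positive")
    terms: list[float] = []
    for g in labeled:
        p = pred[g.part_id]
        if p.visibility == 0:
            terms.append(0.0)
            continue
        d2 = (p.x - g.x) ** 2 + (p.y - g.y) ** 2
        ki = kvec[g.part_id - 1]
        terms.append(math.exp(-d2 / (2.0 * s * s * ki * ki)))
    return OksScore(float(np.mean(terms)), terms)


def oks_ap(
    preds: list[CowSkeleton],
    gts: list[CowSkeleton],
    threshold: float = 0.5,
    s: float | None = None,
    k: float | np.ndarray = 0.1,
) -> float:
    """Fraction of GT objects recovered with OKS above ``threshold``.

    Predictions are matched one-to-one to ground truths greedily by
    descending OKS, then AP = (# matched pairs with OKS > threshold) /
    (# GT objects).
    """
    if not gts:
        return 0.0
    if not preds:
        return 0.0
    scores = np.zeros((len(preds), len(gts)))
    for i, p in enumerate(preds):
        for j, g in enumerate(gts):
            scores[i, j] = compute_oks(p, g, s=s, k=k).value
    used_p: set[int] = set()
    used_g: set[int] = set()
    hits = 0
    for _ in range(min(len(preds), len(gts))):
        best = -1.0
        bi = bj = -1
        for i in range(len(preds)):
            if i in used_p:
                continue
            for j in range(len(gts)):
                if j in used_g:
                    continue
                if scores[i, j] > best:
                    best, bi, bj = scores[i, j], i, j
        if bi < 0:
            break
        used_p.add(bi)
        used_g.add(bj)
        if best > threshold:
            hits += 1
    return hits / len(gts)


@dataclass
class ConfusionMatrix3:
    """3x3 pose confusion counts: rows actual, columns predicted.

    Class order is (standing, walking, lying).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError(f"expected a 3x3 matrix, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")


@dataclass
class ConfusionMetrics:
    precision: np.ndarray  # per class; nan where the column total is 0
    recall: np.ndarray  # per class; nan where the row total is 0
    accuracy: float
    n_correct: int
    n_total: int
    column_share: np.ndarray  # counts[i, j] / column total j


def confusion_metrics(cm: ConfusionMatrix3) -> ConfusionMetrics:
    """Per-class precision/recall, overall accuracy, and column shares.

    Precision is column-wise (among everything predicted as class j, the
    fraction truly j), recall row-wise, accuracy the trace over the total.
    Columns or rows with zero total report ``nan`` rather than 0.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    col = c.sum(axis=0)
    row = c.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, np.diag(c) / col, np.nan)
        recall = np.where(row > 0, np.diag(c) / row, np.nan)
        column_share = np.where(col[None, :] > 0, c / col[None, :], np.nan)
    n_correct = int(np.trace(cm.counts))
    return ConfusionMetrics(
        precision=precision,
        recall=recall,
        accuracy=n_correct / total,
        n_correct=n_correct,
        n_total=int(total),
        column_share=column_share,
    )
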