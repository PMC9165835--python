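"""Annotation readers/writers.

Supported dialects:

* **Labelme JSON** (read) — point-type shapes for keypoints.  Labels use
  the convention ``"part-name:visibility"`` (e.g. ``"neck:2"``); a bare
  part name defaults to visibility 2.  Shapes sharing a ``group_id``
  belong to one animal instance; shapes without a group id go to
  instance 0.  Parts never labeled get visibility 0.
* **PascalVOC XML** (read) — LabelImg-style bounding boxes.
* **COCO-keypoints JSON** (read/write) — the portable interchange format;
  keypoints are flattened ``(x, y, v) x 16`` and the category skeleton
  lists the limb-graph edges.  Round-trips losslessly.

Out-of-bounds coordinates are clipped (not dropped) with a warning, so
annotation counts stay stable.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .boxes import BoundingBox
from .skeleton import (
    N_PARTS,
    PART_NAMES,
    CowSkeleton,
    Keypoint,
    LimbGraph,
    default_limb_graph,
)

__all__ = [
    "AnnotatedImage",
    "read_labelme_keypoints",
    "read_voc_boxes",
    "write_coco_keypoints",
    "read_coco_keypoints",
]


@dataclass
class AnnotatedImage:
    """An image together with its skeleton and box annotations."""

    image_path: str
    width: int
    height: int
    skeletons: list[CowSkeleton] = field(default_factory=list)
    boxes: list[BoundingBox] = field(default_factory=list)
    image: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"image size must be positive, got {self.width}x{self.height}")


def _clip_point(x: float, y: float, width: int, height: int, context: str):
    cx = min(max(x, 0.0), float(width))
    cy = min(max(y, 0.0), float(height))
    if (cx, cy) != (x, y):
        warnings.warn(
            f"{context}: point ({x}, {y}) outside image {width}x{height}; clipped",
            stacklevel=3,
        )
    return cx, cy


def read_labelme_keypoints(path) -> AnnotatedImage:
    """Read a Labelme JSON file of point annotations into skeletons."""
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed Labelme JSON in {path}: {exc}") from exc
    width = int(data["imageWidth"])
    height = int(data["imageHeight"])
    instances: dict[int, dict[int, Keypoint]] = {}
    for shape in data.get("shapes", []):
        if shape.get("shape_type", "point") != "point":
            continue
        label = shape["label"]
        name, _, vis_str = label.partition(":")
        if name not in PART_NAMES:
            raise ValueError(
                f"{path}: unknown part label {name!r}; valid labels: "
                + ", ".join(PART_NAMES)
            )
        visibility = int(vis_str) if vis_str else 2
        if visibility not in (1, 2):
            raise ValueError(f"{path}: labeled point must have visibility 1 or 2, got {label!r}")
        x, y = shape["points"][0]
        x, y = _clip_point(float(x), float(y), width, height, str(path))
        gid = shape.get("group_id")
        inst = instances.setdefault(0 if gid is None else int(gid), {})
        pid = PART_NAMES.index(name) + 1
        inst[pid] = Keypoint(pid, x, y, visibility)
    skeletons = []
    for gid in sorted(instances):
        kps = [
            instances[gid].get(pid, Keypoint(pid, 0.0, 0.0, 0))
            for pid in range(1, N_PARTS + 1)
        ]
        skeletons.append(CowSkeleton(kps, instance_id=gid))
    return AnnotatedImage(
        image_path=data.get("imagePath", str(path)),
        width=width,
        height=height,
        skeletons=skeletons,
    )


def read_voc_boxes(path) -> AnnotatedImage:
    """Read a PascalVOC XML file of bounding boxes (LabelImg dialect)."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML in {path}: {exc}") from exc
    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise ValueError(f"{path}: missing <size> element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    boxes: list[BoundingBox] = []
    for obj in root.iter("object"):
        label = obj.findtext("name", default="cow")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"{path}: object without <bndbox>")
        x0 = float(bnd.findtext("xmin"))
        y0 = float(bnd.findtext("ymin"))
        x1 = float(bnd.findtext("xmax"))
        y1 = float(bnd.findtext("ymax"))
        if x0 > x1 or y0 > y1:
            warnings.warn(f"{path}: inverted box ({x0},{y0},{x1},{y1}); normalized", stacklevel=2)
            x0, x1 = min(x0, x1), max(x0, x1)
            y0, y1 = min(y0, y1), max(y0, y1)
        x0, y0 = _clip_point(x0, y0, width, height, str(path))
        x1, y1 = _clip_point(x1, y1, width, height, str(path))
        boxes.append(BoundingBox(x0, y0, x1, y1, confidence=1.0, label=label))
    return AnnotatedImage(
        image_path=root.findtext("filename", default=str(path)),
        width=width,
        height=height,
        boxes=boxes,
    )


def write_coco_keypoints(
    images: list[AnnotatedImage], path, limb_graph: LimbGraph | None = None
) -> None:
    """Write annotated images as a COCO-keypoints JSON file."""
    graph = limb_graph or default_limb_graph()
    doc: dict = {
        "images": [],
        "annotations": [],
        "categories": [
            {
                "id": 1,
                "name": "cow",
                "supercategory": "animal",
                "keypoints": list(PART_NAMES),
                "skeleton": [list(limb) for limb in graph],
            }
        ],
    }
    ann_id = 1
    for img_id, ann in enumerate(images, start=1):
        doc["images"].append(
            {
                "id": img_id,
                "file_name": ann.image_path,
                "width": ann.width,
                "height": ann.height,
            }
        )
        for skel in ann.skeletons:
            flat: list[float] = []
            for kp in skel.keypoints:
                flat.extend((kp.x, kp.y, kp.visibility))
            labeled = skel.labeled_keypoints
            if labeled:
                xs = [kp.x for kp in labeled]
                ys = [kp.y for kp in labeled]
                bbox = [min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys)]
            else:
                bbox = [0.0, 0.0, 0.0, 0.0]
            doc["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": 1,
                    "keypoints": flat,
                    "num_keypoints": len(labeled),
                    "bbox": bbox,
                    "iscrowd": 0,
                    "attributes": {
                        "pose": skel.pose_label,
                        "instance_id": skel.instance_id,
                    },
                }
            )
            ann_id += 1
        for box in ann.boxes:
            doc["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": img_id,
                    "category_id": 1,
                    "bbox": [box.xmin, box.ymin, box.width, box.height],
                    "score": box.confidence,
                    "iscrowd": 0,
                    "attributes": {"label": box.label, "unit": box.unit},
                }
            )
            ann_id += 1
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_coco_keypoints(path) -> list[AnnotatedImage]:
    """Read a COCO-keypoints JSON file written by :func:`write_coco_keypoints`."""
    with open(path) as fh:
        doc = json.load(fh)
    by_image: dict[int, AnnotatedImage] = {}
    order: list[int] = []
    for entry in doc["images"]:
        by_image[entry["id"]] = AnnotatedImage(
            image_path=entry["file_name"],
            width=entry["width"],
            height=entry["height"],
        )
        order.append(entry["id"])
    for ann in doc.get("annotations", []):
        target = by_image[ann["image_id"]]
        if "keypoints" in ann:
            flat = ann["keypoints"]
            kps = [
                Keypoint(i + 1, float(flat[3 * i]), float(flat[3 * i + 1]), int(flat[3 * i + 2]))
                for i in range(N_PARTS)
            ]
            attrs = ann.get("attributes", {})
            target.skeletons.append(
                CowSkeleton(
                    kps,
                    pose_label=attrs.get("pose", "unknown"),
                    instance_id=attrs.get("instance_id"),
                )
            )
        else:
            x, y, w, h = ann["bbox"]
            attrs = ann.get("attributes", {})
            target.boxes.append(
                BoundingBox(
                    x,
                    y,
                    x + w,
                    y + h,
                    confidence=ann.get("score", 1.0),
                    unit=attrs.get("unit", "pixel"),
                    label=attrs.get("label", "cow"),
                )
            )
    return [by_image[i] for i in order]
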