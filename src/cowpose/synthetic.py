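"""Synthetic cow scenes: pose-conditioned skeletons, multi-animal scenes
with occlusion, mosaic composites, and brightness perturbation.

The generator draws stick-figure cows from a parametric side-view model:
a horizontal axial chain (coccyx - spine - neck - head) with four
three-joint legs (root, knee, hoof).  The three pose classes differ in
geometry the way they do in the barn:

* ``standing`` — straight vertical legs, all hooves on a common ground
  line;
* ``walking`` — standing geometry with knees and hooves displaced by
  sinusoids of a gait phase, with per-leg phase offsets; the swing
  amplitude varies between animals, so a barely-moving walker is
  genuinely ambiguous with a standing one (the confusion observed in
  real footage);
* ``lying`` — the body axis lowered to the ground and the leg segments
  folded under the body (knee and hoof within 0.3 leg lengths of the
  root), giving an overall height below half the standing height.

Keypoint coordinates are rounded to integer pixels, matching the output
of point-annotation tools.  All sampling is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, line

from .annotations import AnnotatedImage
from .boxes import BoundingBox, iou
from .skeleton import (
    N_PARTS,
    CowSkeleton,
    Keypoint,
    skeleton_bbox,
    skeleton_from_arrays,
    part_id_of,
)

__all__ = [
    "PoseParams",
    "Scene",
    "sample_skeleton",
    "compose_scene",
    "mosaic_augment",
    "adjust_brightness",
    "make_pose_dataset",
    "render_scene",
]

_LEG_ROOTS = {
    "left_front_leg_root": (-4.0, "front"),
    "right_front_leg_root": (4.0, "front"),
    "left_hind_leg_root": (-4.0, "hind"),
    "right_hind_leg_root": (4.0, "hind"),
}
_LEG_CHAINS = (
    ("left_front_leg_root", "left_front_knee", "left_front_hoof", 0.0),
    ("right_front_leg_root", "right_front_knee", "right_front_hoof", math.pi),
    ("left_hind_leg_root", "left_hind_knee", "left_hind_hoof", math.pi / 2),
    ("right_hind_leg_root", "right_hind_knee", "right_hind_hoof", 3 * math.pi / 2),
)


@dataclass
class PoseParams:
    """Geometry and randomness controls for one sampled skeleton."""

    pose: str = "standing"
    body_length: float = 120.0
    leg_length: float = 60.0
    gait_phase: float = 0.0
    gait_amplitude: float = 1.0  # fraction of the maximum swing (walking only)
    jitter_sd: float = 0.0
    flip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pose not in ("standing", "walking", "lying"):
            raise ValueError(f"pose must be standing/walking/lying, got {self.pose!r}")
        if self.body_length <= 0 or self.leg_length <= 0:
            raise ValueError("body_length and leg_length must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")


def sample_skeleton(params: PoseParams) -> CowSkeleton:
    """Draw one pose-conditioned skeleton, deterministic given the seed.

    Coordinates are returned shifted into the positive quadrant (bounding
    box touching (0, 0)) and rounded to integer pixels.
    """
    L, leg = params.body_length, params.leg_length
    rng = np.random.default_rng(params.seed)
    coords = np.zeros((N_PARTS, 2))

    def put(name: str, x: float, y: float) -> None:
        coords[part_id_of(name) - 1] = (x, y)

    if params.pose in ("standing", "walking"):
        y_body = -leg
        put("coccyx", 0.0, y_body)
        put("spine", 0.5 * L, y_body)
        put("neck", L, y_body)
        put("head", 1.2 * L, y_body - 0.25 * leg)
        for root_name, knee_name, hoof_name, phase_off in _LEG_CHAINS:
            dx_side, end = _LEG_ROOTS[root_name][0], _LEG_ROOTS[root_name][1]
            rx = (0.9 * L if end == "front" else 0.05 * L) + dx_side
            swing = lift = 0.0
            if params.pose == "walking":
                amp = params.gait_amplitude * 0.3 * leg
                theta = params.gait_phase + phase_off
                swing = amp * math.sin(theta)
                lift = 0.5 * amp * max(0.0, math.cos(theta))
            put(root_name, rx, y_body)
            put(knee_name, rx + 0.5 * swing, y_body + 0.5 * leg - 0.5 * lift)
            put(hoof_name, rx + swing, -lift)
    else:  # lying
        y_body = -0.3 * leg
        put("coccyx", 0.0, y_body)
        put("spine", 0.5 * L, y_body)
        put("neck", L, y_body)
        put("head", 1.2 * L, y_body - 0.2 * leg)
        for root_name, knee_name, hoof_name, _ in _LEG_CHAINS:
            dx_side, end = _LEG_ROOTS[root_name]
            rx = (0.9 * L if end == "front" else 0.05 * L) + dx_side
            ry = -0.15 * leg
            put(root_name, rx, ry)
            # folded: knee and hoof stay within 0.3*leg of the root
            put(knee_name, rx + 0.15 * leg, ry + 0.1 * leg)
            put(hoof_name, rx + 0.2 * leg, ry + 0.12 * leg)

    if params.flip:
        coords[:, 0] = -coords[:, 0]
    if params.jitter_sd > 0:
        coords += rng.normal(0.0, params.jitter_sd, size=coords.shape)
    coords -= coords.min(axis=0)
    coords = np.rint(coords)
    return skeleton_from_arrays(coords, pose_label=params.pose)


@dataclass
class Scene:
    """A multi-cow canvas with ground-truth skeletons."""

    height: int
    width: int
    skeletons: list[CowSkeleton]
    occlusion_fraction: list[float] = field(default_factory=list)


def _occlusion_fraction(skel: CowSkeleton) -> float:
    return sum(1 for kp in skel.keypoints if kp.visibility < 2) / N_PARTS


def compose_scene(
    n_cows: int,
    overlap: str = "none",
    lighting: str = "day",
    seed: int = 0,
    height: int = 480,
    width: int = 768,
    body_length: float = 120.0,
    leg_length: float = 60.0,
    jitter_sd: float = 0.0,
) -> tuple[Scene, np.ndarray]:
    """Place ``n_cows`` skeletons on a canvas and render a raster image.

    ``overlap="none"`` gives pairwise-disjoint bounding boxes;
    ``overlap="partial"`` forces bounding-box IoU in [0.1, 0.4] for one
    pair and marks the occluded cow's covered keypoints visibility 1
    (with a random subset dropped to 0).  ``lighting="night"`` darkens
    the render and adds sensor noise.  Raises ``ValueError`` when the
    canvas cannot hold ``n_cows`` disjoint animals.
    """
    if n_cows < 1:
        raise ValueError("n_cows must be >= 1")
    if overlap not in ("none", "partial"):
        raise ValueError(f"overlap must be 'none' or 'partial', got {overlap!r}")
    if overlap == "partial" and n_cows < 2:
        raise ValueError("partial overlap needs at least 2 cows")
    rng = np.random.default_rng(seed)
    poses = ("standing", "walking", "lying")
    skels: list[CowSkeleton] = []
    for i in range(n_cows):
        params = PoseParams(
            pose=poses[int(rng.integers(3))],
            body_length=body_length,
            leg_length=leg_length,
            gait_phase=float(rng.uniform(0, 2 * math.pi)),
            gait_amplitude=float(rng.uniform(0.0, 1.0)),
            jitter_sd=jitter_sd,
            flip=bool(rng.integers(2)),
            seed=int(rng.integers(2**31 - 1)),
        )
        skels.append(sample_skeleton(params))

    boxes = [skeleton_bbox(s) for s in skels]
    margin = 10
    cell_w = int(max(b.width for b in boxes)) + margin
    cell_h = int(max(b.height for b in boxes)) + margin
    cols, rows = width // cell_w, height // cell_h
    if cols * rows < n_cows:
        raise ValueError(
            f"canvas {width}x{height} too small for {n_cows} disjoint cows "
            f"(cells of {cell_w}x{cell_h})"
        )
    cells = rng.choice(cols * rows, size=n_cows, replace=False)
    placed: list[CowSkeleton] = []
    for i, (skel, cell) in enumerate(zip(skels, cells)):
        cx, cy = (int(cell) % cols) * cell_w, (int(cell) // cols) * cell_h
        b = boxes[i]
        jx = int(rng.integers(0, max(1, cell_w - int(b.width) - 1)))
        jy = int(rng.integers(0, max(1, cell_h - int(b.height) - 1)))
        s = skel.translated(cx + jx, cy + jy)
        s.instance_id = i
        placed.append(s)

    if overlap == "partial":
        # slide cow 1 toward cow 0 until their boxes overlap with IoU in [0.1, 0.4]
        b0 = skeleton_bbox(placed[0])
        base = placed[1]
        bb = skeleton_bbox(base)
        best = None
        for frac in np.linspace(0.0, 1.0, 201):
            dx = (b0.xmin - bb.xmin) + frac * b0.width
            dy = b0.ymin - bb.ymin
            cand_box = BoundingBox(
                bb.xmin + dx, bb.ymin + dy, bb.xmax + dx, bb.ymax + dy
            )
            v = iou(cand_box, b0)
            if 0.1 <= v <= 0.4:
                best = (dx, dy)
                break
        if best is None:  # pragma: no cover - geometry always admits a solution
            raise RuntimeError("could not achieve partial overlap")
        moved = base.translated(*best)
        inter = _intersection(skeleton_bbox(moved), b0)
        kps = []
        for kp in moved.keypoints:
            if kp.visibility > 0 and _inside(kp, inter):
                vis = 0 if rng.random() < 0.3 else 1
                kps.append(Keypoint(kp.part_id, kp.x, kp.y, vis))
            else:
                kps.append(kp)
        placed[1] = CowSkeleton(kps, moved.pose_label, moved.instance_id)
        # re-clip into canvas if the slide pushed it out
        bb2 = skeleton_bbox(placed[1])
        shift_x = min(0.0, width - 1 - bb2.xmax) or max(0.0, -bb2.xmin)
        shift_y = min(0.0, height - 1 - bb2.ymax) or max(0.0, -bb2.ymin)
        if shift_x or shift_y:
            placed[1] = placed[1].translated(shift_x, shift_y)

    scene = Scene(height, width, placed, [_occlusion_fraction(s) for s in placed])
    image = render_scene(scene, lighting=lighting, seed=seed)
    return scene, image


def _intersection(a: BoundingBox, b: BoundingBox) -> tuple[float, float, float, float]:
    return (
        max(a.xmin, b.xmin),
        max(a.ymin, b.ymin),
        min(a.xmax, b.xmax),
        min(a.ymax, b.ymax),
    )


def _inside(kp: Keypoint, rect: tuple[float, float, float, float]) -> bool:
    x0, y0, x1, y1 = rect
    return x0 <= kp.x <= x1 and y0 <= kp.y <= y1


def render_scene(scene: Scene, lighting: str = "day", seed: int = 0) -> np.ndarray:
    """Draw stick-figure cows on a gray canvas; uint8 grayscale."""
    from .skeleton import default_limb_graph

    if lighting not in ("day", "night"):
        raise ValueError(f"lighting must be 'day' or 'night', got {lighting!r}")
    rng = np.random.default_rng(seed + 7)
    img = np.full((scene.height, scene.width), 185.0)
    graph = default_limb_graph()
    for idx, skel in enumerate(scene.skeletons):
        shade = 40.0 + 25.0 * (idx % 5)
        for pa, pb in graph:
            a, b = skel[pa], skel[pb]
            if a.visibility == 0 or b.visibility == 0:
                continue
            rr, cc = line(int(a.y), int(a.x), int(b.y), int(b.x))
            ok = (rr >= 0) & (rr < scene.height) & (cc >= 0) & (cc < scene.width)
            img[rr[ok], cc[ok]] = shade
        for kp in skel.keypoints:
            if kp.visibility != 2:
                continue
            rr, cc = disk((kp.y, kp.x), 2, shape=img.shape)
            img[rr, cc] = shade * 0.5
    if lighting == "night":
        img = img * 0.4 + rng.normal(0.0, 6.0, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Per-pixel multiplicative brightness change with clipping.

    Emulates front-light/back-light conditions (e.g. factors 0.5, 0.75,
    1.25, 1.5). Annotations are unaffected by construction.
    """
    if factor <= 0:
        raise ValueError("brightness factor must be positive")
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(image.astype(np.float64) * factor, 0, 255).astype(image.dtype)
    return np.clip(image * factor, 0.0, 1.0)


def mosaic_augment(
    images: list[AnnotatedImage],
    out_size: tuple[int, int] = (480, 768),
    seed: int = 0,
) -> AnnotatedImage:
    """Stitch four annotated images into one mosaic composite.

    Each input is independently mirrored/flipped/rotated (90-degree
    multiples) and randomly cropped to one quadrant of the output canvas,
    with keypoints and boxes transformed consistently.  Keypoints falling
    outside their crop become visibility 0; boxes are clipped and any
    annotation whose clipped box area drops below 20% of its original is
    dropped.
    """
    if len(images) != 4:
        raise ValueError("mosaic_augment needs exactly 4 annotated images")
    H, W = out_size
    rng = np.random.default_rng(seed)
    sy = int(rng.integers(int(0.3 * H), int(0.7 * H)))
    sx = int(rng.integers(int(0.3 * W), int(0.7 * W)))
    quads = (
        (0, 0, sy, sx),
        (0, sx, sy, W - sx),
        (sy, 0, H - sy, sx),
        (sy, sx, H - sy, W - sx),
    )
    canvas = np.zeros((H, W), dtype=np.uint8)
    out_skels: list[CowSkeleton] = []
    out_boxes: list[BoundingBox] = []
    for ann, (qy, qx, qh, qw) in zip(images, quads):
        img = ann.image if ann.image is not None else np.zeros(
            (ann.height, ann.width), dtype=np.uint8
        )
        skels = [CowSkeleton(list(s.keypoints), s.pose_label, s.instance_id) for s in ann.skeletons]
        bxs = list(ann.boxes)
        h, w = img.shape[:2]
        if rng.integers(2):
            img = img[:, ::-1]
            skels = [_flip_skel(s, w, axis="x") for s in skels]
            bxs = [_flip_box(b, w, axis="x") for b in bxs]
        if rng.integers(2):
            img = img[::-1]
            skels = [_flip_skel(s, h, axis="y") for s in skels]
            bxs = [_flip_box(b, h, axis="y") for b in bxs]
        k = int(rng.integers(4))
        for _ in range(k):
            img = np.rot90(img)  # (x, y) -> (y, h-1-x) with h the pre-rotation height
            h, w = img.shape[:2]
            skels = [_rot_skel(s, w) for s in skels]
            bxs = [_rot_box(b, w) for b in bxs]
        h, w = img.shape[:2]
        if h < qh or w < qw:  # pad to quadrant size
            pad = np.zeros((max(h, qh), max(w, qw)), dtype=img.dtype)
            pad[:h, :w] = img
            img = pad
            h, w = img.shape[:2]
        cy = int(rng.integers(0, h - qh + 1))
        cx = int(rng.integers(0, w - qw + 1))
        canvas[qy : qy + qh, qx : qx + qw] = img[cy : cy + qh, cx : cx + qw]
        crop = (cx, cy, cx + qw, cy + qh)
        for s in skels:
            kps = []
            n_vis = 0
            for kp in s.keypoints:
                if kp.visibility == 0:
                    kps.append(kp)
                    continue
                if crop[0] <= kp.x < crop[2] and crop[1] <= kp.y < crop[3]:
                    kps.append(
                        Keypoint(kp.part_id, kp.x - cx + qx, kp.y - cy + qy, kp.visibility)
                    )
                    n_vis += 1
                else:
                    kps.append(Keypoint(kp.part_id, 0.0, 0.0, 0))
            if n_vis:
                out_skels.append(CowSkeleton(kps, s.pose_label))
        for b in bxs:
            nx0 = max(b.xmin, crop[0]) - cx + qx
            ny0 = max(b.ymin, crop[1]) - cy + qy
            nx1 = min(b.xmax, crop[2]) - cx + qx
            ny1 = min(b.ymax, crop[3]) - cy + qy
            if nx1 <= nx0 or ny1 <= ny0:
                continue
            clipped = BoundingBox(nx0, ny0, nx1, ny1, b.confidence, b.unit, b.label)
            if b.area > 0 and clipped.area / b.area < 0.2:
                continue
            out_boxes.append(clipped)
    return AnnotatedImage(
        image_path="<mosaic>",
        width=W,
        height=H,
        skeletons=out_skels,
        boxes=out_boxes,
        image=canvas,
    )


def _flip_skel(s: CowSkeleton, extent: float, axis: str) -> CowSkeleton:
    kps = []
    for kp in s.keypoints:
        if kp.visibility == 0:
            kps.append(kp)
        elif axis == "x":
            kps.append(Keypoint(kp.part_id, extent - 1 - kp.x, kp.y, kp.visibility))
        else:
            kps.append(Keypoint(kp.part_id, kp.x, extent - 1 - kp.y, kp.visibility))
    return CowSkeleton(kps, s.pose_label, s.instance_id)


def _flip_box(b: BoundingBox, extent: float, axis: str) -> BoundingBox:
    if axis == "x":
        return BoundingBox(
            extent - 1 - b.xmax, b.ymin, extent - 1 - b.xmin, b.ymax, b.confidence, b.unit, b.label
        )
    return BoundingBox(
        b.xmin, extent - 1 - b.ymax, b.xmax, extent - 1 - b.ymin, b.confidence, b.unit, b.label
    )


def _rot_skel(s: CowSkeleton, new_height: float) -> CowSkeleton:
    # np.rot90 maps pixel (x, y) to (x', y') = (y, W_old - 1 - x); W_old == new_height
    kps = []
    for kp in s.keypoints:
        if kp.visibility == 0:
            kps.append(kp)
        else:
            kps.append(Keypoint(kp.part_id, kp.y, new_height - 1 - kp.x, kp.visibility))
    return CowSkeleton(kps, s.pose_label, s.instance_id)


def _rot_box(b: BoundingBox, new_height: float) -> BoundingBox:
    x0, y0 = b.ymin, new_height - 1 - b.xmax
    x1, y1 = b.ymax, new_height - 1 - b.xmin
    return BoundingBox(x0, y0, x1, y1, b.confidence, b.unit, b.label)


def make_pose_dataset(
    n_per_pose: int = 600,
    seed: int = 0,
    jitter_sd: float = 2.0,
    body_length_range: tuple[float, float] = (100.0, 140.0),
    leg_length_range: tuple[float, float] = (50.0, 70.0),
    gait_amplitude_range: tuple[float, float] = (0.25, 1.0),
) -> tuple[list[CowSkeleton], np.ndarray]:
    """A balanced labeled skeleton dataset for classifier training.

    Walking samples draw a gait phase uniform on [0, 2 pi) and a swing
    amplitude uniform on ``gait_amplitude_range``.  The lower bound is
    the slowest gait a human labeler would still annotate as walking
    rather than standing; near that bound the leg displacement is
    comparable to the labeling jitter, so a residual standing/walking
    confusion remains while the classes stay learnable.  Returns
    (skeletons, integer labels) with 0=standing, 1=walking, 2=lying.
    """
    rng = np.random.default_rng(seed)
    skels: list[CowSkeleton] = []
    labels: list[int] = []
    for label, pose in enumerate(("standing", "walking", "lying")):
        for _ in range(n_per_pose):
            params = PoseParams(
                pose=pose,
                body_length=float(rng.uniform(*body_length_range)),
                leg_length=float(rng.uniform(*leg_length_range)),
                gait_phase=float(rng.uniform(0, 2 * math.pi)),
                gait_amplitude=float(rng.uniform(*gait_amplitude_range)),
                jitter_sd=jitter_sd,
                flip=bool(rng.integers(2)),
                seed=int(rng.integers(2**31 - 1)),
            )
            skels.append(sample_skeleton(params))
            labels.append(label)
    return skels, np.asarray(labels)
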