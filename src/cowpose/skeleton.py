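"""Canonical data model for the 16-keypoint cow skeleton.

Coordinates are in pixels with the origin at the top-left corner of the
image, x increasing rightward and y increasing downward (0-based), the
convention of common image-annotation tools.

Visibility flags follow the three-state labeling convention:

* ``2`` — keypoint visible in the image,
* ``1`` — keypoint labeled but occluded (invisible),
* ``0`` — keypoint missing (not labeled; coordinates are meaningless).

All metric and encoding code treats ``{1, 2}`` as "labeled".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .boxes import BoundingBox

__all__ = [
    "PART_NAMES",
    "PART_IDS",
    "N_PARTS",
    "Keypoint",
    "CowSkeleton",
    "LimbGraph",
    "default_limb_graph",
    "skeleton_bbox",
    "part_id_of",
]

#: Part names in part-id order (ids 1..16).
PART_NAMES: tuple[str, ...] = (
    "head",
    "left_front_leg_root",
    "right_front_leg_root",
    "left_front_knee",
    "right_front_knee",
    "left_front_hoof",
    "right_front_hoof",
    "left_hind_leg_root",
    "right_hind_leg_root",
    "left_hind_knee",
    "right_hind_knee",
    "left_hind_hoof",
    "right_hind_hoof",
    "neck",
    "spine",
    "coccyx",
)

N_PARTS = len(PART_NAMES)
PART_IDS = tuple(range(1, N_PARTS + 1))
_NAME_TO_ID = {name: i + 1 for i, name in enumerate(PART_NAMES)}

POSE_LABELS = ("standing", "walking", "lying")


def part_id_of(name: str) -> int:
    """Map a part name to its 1-based part id.

    Raises ``KeyError`` listing the valid names for unknown labels.
    """
    try:
        return _NAME_TO_ID[name]
    except KeyError:
        raise KeyError(
            f"unknown part name {name!r}; valid names: {', '.join(PART_NAMES)}"
        ) from None


@dataclass(frozen=True)
class Keypoint:
    """A single body-part observation: id, pixel position, visibility."""

    part_id: int
    x: float
    y: float
    visibility: int = 2

    def __post_init__(self) -> None:
        if self.part_id not in PART_IDS:
            raise ValueError(f"part_id must be in 1..{N_PARTS}, got {self.part_id}")
        if self.visibility not in (0, 1, 2):
            raise ValueError(f"visibility must be 0, 1 or 2, got {self.visibility}")

    @property
    def labeled(self) -> bool:
        return self.visibility > 0

    @property
    def name(self) -> str:
        return PART_NAMES[self.part_id - 1]


@dataclass
class CowSkeleton:
    """One animal instance: exactly one keypoint per part id.

    ``keypoints`` is stored sorted by part id. ``pose_label`` is one of
    ``standing``/``walking``/``lying``/``unknown``; ``instance_id`` is an
    optional identifier within a scene.
    """

    keypoints: list[Keypoint]
    pose_label: str = "unknown"
    instance_id: int | None = None

    def __post_init__(self) -> None:
        ids = sorted(kp.part_id for kp in self.keypoints)
        if ids != list(PART_IDS):
            raise ValueError(
                f"a skeleton needs exactly one keypoint per part id 1..{N_PARTS}"
            )
        if self.pose_label not in POSE_LABELS + ("unknown",):
            raise ValueError(f"unknown pose label {self.pose_label!r}")
        self.keypoints = sorted(self.keypoints, key=lambda kp: kp.part_id)

    def __getitem__(self, part_id: int) -> Keypoint:
        return self.keypoints[part_id - 1]

    @property
    def labeled_keypoints(self) -> list[Keypoint]:
        return [kp for kp in self.keypoints if kp.visibility > 0]

    def translated(self, dx: float, dy: float) -> "CowSkeleton":
        """A copy shifted by (dx, dy); missing keypoints untouched."""
        kps = [
            replace(kp, x=kp.x + dx, y=kp.y + dy) if kp.visibility > 0 else kp
            for kp in self.keypoints
        ]
        return CowSkeleton(kps, self.pose_label, self.instance_id)


@dataclass(frozen=True)
class LimbGraph:
    """Ordered edge set over the 16 parts; one PAF channel per limb.

    The default graph is a 15-edge anatomical spanning tree (head-neck,
    axial chain, and four 3-joint legs), so keypoint grouping can never
    assemble two candidates of the same part into one instance.
    """

    limbs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.limbs:
            if a == b:
                raise ValueError(f"self-loop on part {a}")
            if a not in PART_IDS or b not in PART_IDS:
                raise ValueError(f"limb ({a},{b}) uses ids outside 1..{N_PARTS}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate limb ({a},{b})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.limbs)

    def __iter__(self):
        return iter(self.limbs)

    def is_connected(self) -> bool:
        adj: dict[int, set[int]] = {i: set() for i in PART_IDS}
        for a, b in self.limbs:
            adj[a].add(b)
            adj[b].add(a)
        seen = {1}
        stack = [1]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == N_PARTS


_N = _NAME_TO_ID  # brevity

_DEFAULT_LIMBS: tuple[tuple[int, int], ...] = (
    (_N["head"], _N["neck"]),
    (_N["neck"], _N["spine"]),
    (_N["spine"], _N["coccyx"]),
    (_N["neck"], _N["left_front_leg_root"]),
    (_N["neck"], _N["right_front_leg_root"]),
    (_N["left_front_leg_root"], _N["left_front_knee"]),
    (_N["left_front_knee"], _N["left_front_hoof"]),
    (_N["right_front_leg_root"], _N["right_front_knee"]),
    (_N["right_front_knee"], _N["right_front_hoof"]),
    (_N["coccyx"], _N["left_hind_leg_root"]),
    (_N["coccyx"], _N["right_hind_leg_root"]),
    (_N["left_hind_leg_root"], _N["left_hind_knee"]),
    (_N["left_hind_knee"], _N["left_hind_hoof"]),
    (_N["right_hind_leg_root"], _N["right_hind_knee"]),
    (_N["right_hind_knee"], _N["right_hind_hoof"]),
)


def default_limb_graph() -> LimbGraph:
    """The 15-edge anatomical spanning tree over the 16 parts."""
    return LimbGraph(_DEFAULT_LIMBS)


def skeleton_bbox(skel: CowSkeleton) -> BoundingBox:
    """Tight axis-aligned box over labeled keypoints, confidence 1.

    Keypoints with visibility 0 are ignored. Raises ``ValueError`` for a
    skeleton with no labeled keypoint at all.
    """
    pts = skel.labeled_keypoints
    if not pts:
        raise ValueError("empty skeleton: no keypoint with visibility > 0")
    xs = [kp.x for kp in pts]
    ys = [kp.y for kp in pts]
    return BoundingBox(min(xs), min(ys), max(xs), max(ys), confidence=1.0)


def skeleton_from_arrays(
    coords: Sequence[Sequence[float]],
    visibility: Iterable[int] | None = None,
    pose_label: str = "unknown",
    instance_id: int | None = None,
) -> CowSkeleton:
    """Build a skeleton from a (16, 2) coordinate array in part-id order."""
    if len(coords) != N_PARTS:
        raise ValueError(f"expected {N_PARTS} coordinate pairs, got {len(coords)}")
    vis = list(visibility) if visibility is not None else [2] * N_PARTS
    kps = [
        Keypoint(i + 1, float(xy[0]), float(xy[1]), int(v))
        for i, (xy, v) in enumerate(zip(coords, vis))
    ]
    return CowSkeleton(kps, pose_label, instance_id)
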