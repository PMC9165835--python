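"""Ground-truth encoding of keypoint heatmaps and part affinity fields.

A keypoint heatmap is a per-part confidence grid: at pixel ``p`` the value
for part ``j`` is ``exp(-||p - x_{j,k}||^2 / (2 sigma^2))`` for instance
``k``'s keypoint ``x_{j,k}``, and the multi-instance channel takes the
pixelwise maximum over instances.

A part affinity field (PAF) stores, for every limb (pair of connected
parts) and every pixel on that limb, the unit vector pointing from the
first part toward the second; pixels on no limb are zero, and pixels
covered by limbs of several instances hold the arithmetic mean of their
unit vectors.  "On the limb" means within a rectangular band around the
segment: along-segment projection inside [0, limb length] and
perpendicular distance at most ``limb_width`` pixels.

Stacks are computed at full image resolution.  Channel order is part id
ascending for heatmaps and limb-graph order for PAFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .skeleton import N_PARTS, CowSkeleton, LimbGraph

__all__ = [
    "HeatmapStack",
    "PafStack",
    "PeakCandidate",
    "encode_heatmaps",
    "encode_pafs",
    "extract_peaks",
    "save_stacks",
    "load_stacks",
]


@dataclass
class HeatmapStack:
    """Per-part confidence grids, shape (16, H, W), values in [0, 1]."""

    values: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[0] != N_PARTS:
            raise ValueError(f"expected ({N_PARTS}, H, W) array, got {self.values.shape}")


@dataclass
class PafStack:
    """Per-limb 2-channel vector grids, shape (C, 2, H, W)."""

    values: np.ndarray
    limb_width: float

    def __post_init__(self) -> None:
        if self.values.ndim != 4 or self.values.shape[1] != 2:
            raise ValueError(f"expected (C, 2, H, W) array, got {self.values.shape}")


@dataclass(frozen=True)
class PeakCandidate:
    """A local heatmap maximum proposed as a keypoint of some instance."""

    part_id: int
    x: int
    y: int
    score: float


def encode_heatmaps(
    skeletons: list[CowSkeleton], H: int, W: int, sigma: float = 2.0
) -> HeatmapStack:
    """Encode labeled keypoints of all instances as Gaussian heatmaps.

    Only keypoints with visibility > 0 are encoded; a part absent from
    every skeleton yields an all-zero channel.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    values = np.zeros((N_PARTS, H, W), dtype=np.float64)
    ys, xs = np.mgrid[0:H, 0:W]
    inv = 1.0 / (2.0 * sigma * sigma)
    for skel in skeletons:
        for kp in skel.keypoints:
            if kp.visibility == 0:
                continue
            g = np.exp(-((xs - kp.x) ** 2 + (ys - kp.y) ** 2) * inv)
            ch = kp.part_id - 1
            np.maximum(values[ch], g, out=values[ch])
    return HeatmapStack(values, sigma)


def encode_pafs(
    skeletons: list[CowSkeleton],
    limb_graph: LimbGraph,
    H: int,
    W: int,
    limb_width: float = 4.0,
) -> PafStack:
    """Encode part affinity fields for every limb of every instance.

    A limb is encoded only when both endpoints have visibility > 0.
    Zero-length limbs (coincident endpoints) are skipped with a warning.
    Where bands of several instances overlap, the field is the mean of
    their unit vectors.
    """
    C = len(limb_graph)
    values = np.zeros((C, 2, H, W), dtype=np.float64)
    counts = np.zeros((C, H, W), dtype=np.int64)
    ys, xs = np.mgrid[0:H, 0:W]
    for skel in skeletons:
        for c, (pa, pb) in enumerate(limb_graph):
            a, b = skel[pa], skel[pb]
            if a.visibility == 0 or b.visibility == 0:
                continue
            dx, dy = b.x - a.x, b.y - a.y
            length = float(np.hypot(dx, dy))
            if length == 0.0:
                warnings.warn(
                    f"zero-length limb ({pa},{pb}) at ({a.x},{a.y}); skipped",
                    stacklevel=2,
                )
                continue
            ux, uy = dx / length, dy / length
            rx, ry = xs - a.x, ys - a.y
            along = rx * ux + ry * uy
            perp = np.abs(rx * uy - ry * ux)
            # tiny slack so the exact endpoints stay inside despite fp rounding
            band = (along >= -1e-9) & (along <= length + 1e-9) & (perp <= limb_width)
            values[c, 0][band] += ux
            values[c, 1][band] += uy
            counts[c][band] += 1
    multi = counts > 1
    if multi.any():
        for ch in range(2):
            values[:, ch][multi] /= counts[multi]
    return PafStack(values, limb_width)


def extract_peaks(
    hm: HeatmapStack, peak_threshold: float = 0.1
) -> list[PeakCandidate]:
    """Extract keypoint candidates as thresholded 3x3 local maxima.

    A pixel qualifies when its value is >= every 3x3 neighbor and >= the
    threshold.  A plateau of equal-valued adjacent maxima yields a single
    candidate at its smallest (y, x) pixel.  Candidates are sorted per
    part by descending score, ties by (y, x).
    """
    if not 0.0 < peak_threshold < 1.0:
        raise ValueError(f"peak_threshold must lie in (0, 1), got {peak_threshold}")
    out: list[PeakCandidate] = []
    for ch in range(N_PARTS):
        grid = hm.values[ch]
        local_max = grid >= ndimage.maximum_filter(grid, size=3, mode="constant")
        mask = local_max & (grid >= peak_threshold)
        if not mask.any():
            continue
        # adjacent qualifying maxima are necessarily equal-valued plateaus;
        # keep the lexicographically smallest (y, x) pixel of each
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        cands = []
        for lab in range(1, n + 1):
            yy, xx = np.nonzero(labels == lab)
            i = np.lexsort((xx, yy))[0]
            y, x = int(yy[i]), int(xx[i])
            cands.append(PeakCandidate(ch + 1, x, y, float(grid[y, x])))
        cands.sort(key=lambda c: (-c.score, c.y, c.x))
        out.extend(cands)
    return out


def save_stacks(path, hm: HeatmapStack | None = None, paf: PafStack | None = None) -> None:
    """Save stacks to a ``.npz`` archive (portable numpy array format)."""
    arrays: dict[str, np.ndarray] = {}
    if hm is not None:
        arrays["heatmaps"] = hm.values
        arrays["sigma"] = np.asarray(hm.sigma)
    if paf is not None:
        arrays["pafs"] = paf.values
        arrays["limb_width"] = np.asarray(paf.limb_width)
    np.savez_compressed(path, **arrays)


def load_stacks(path) -> tuple[HeatmapStack | None, PafStack | None]:
    with np.load(path) as data:
        hm = (
            HeatmapStack(data["heatmaps"], float(data["sigma"]))
            if "heatmaps" in data
            else None
        )
        paf = (
            PafStack(data["pafs"], float(data["limb_width"]))
            if "pafs" in data
            else None
        )
    return hm, paf
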