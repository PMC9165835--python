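"""Bottom-up grouping of keypoint candidates into animal instances.

Each limb hypothesis (a pair of candidates for the two parts a limb
connects) is scored by the line integral of the part affinity field along
the candidate segment; per limb type, candidates on the two sides are put
in one-to-one correspondence by maximizing the total score with the
Hungarian algorithm; matched limbs sharing a candidate are then merged
into instances with union-find.  Because the default limb graph is a
tree, a merge can never claim two different candidates for one part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .codec import PafStack, PeakCandidate
from .skeleton import N_PARTS, CowSkeleton, Keypoint, LimbGraph

__all__ = [
    "LimbCandidate",
    "AssemblyResult",
    "paf_line_integral",
    "match_limb",
    "assemble_skeletons",
    "group_candidates",
]


@dataclass(frozen=True)
class LimbCandidate:
    """A scored hypothesis that two peak candidates form one limb."""

    limb_index: int
    cand_a: PeakCandidate
    cand_b: PeakCandidate
    score: float


@dataclass
class AssemblyResult:
    skeletons: list[CowSkeleton]
    unassigned: list[PeakCandidate]


def paf_line_integral(
    paf: PafStack,
    limb_index: int,
    a: tuple[float, float],
    b: tuple[float, float],
    n_samples: int = 10,
) -> float:
    """Average alignment of the PAF with the segment from ``a`` to ``b``.

    Samples ``n_samples`` points uniformly on the segment (endpoints
    included), looks the field up at the nearest pixel, and averages the
    dot product with the segment's unit direction.  Result lies in
    [-1, 1]; a perfectly aligned unit field gives 1.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    norm = float(np.hypot(dx, dy))
    if norm == 0.0:
        raise ValueError("degenerate limb: endpoints coincide")
    ux, uy = dx / norm, dy / norm
    _, _, H, W = paf.values.shape
    u = np.linspace(0.0, 1.0, n_samples)
    px = np.clip(np.rint(ax + u * dx).astype(int), 0, W - 1)
    py = np.clip(np.rint(ay + u * dy).astype(int), 0, H - 1)
    fx = paf.values[limb_index, 0, py, px]
    fy = paf.values[limb_index, 1, py, px]
    return float(np.mean(fx * ux + fy * uy))


def match_limb(
    candidates_a: list[PeakCandidate],
    candidates_b: list[PeakCandidate],
    paf: PafStack,
    limb_index: int,
    score_threshold: float = 0.05,
    n_samples: int = 10,
) -> list[LimbCandidate]:
    """One-to-one limb assignment maximizing the total line-integral score.

    Solves the bipartite assignment with the Hungarian algorithm, then
    removes pairs scoring below ``score_threshold``.  Output is sorted by
    descending score (ties by candidate coordinates, for determinism).
    """
    if not candidates_a or not candidates_b:
        return []
    scores = np.empty((len(candidates_a), len(candidates_b)))
    for i, ca in enumerate(candidates_a):
        for j, cb in enumerate(candidates_b):
            if (ca.x, ca.y) == (cb.x, cb.y):
                scores[i, j] = -np.inf  # degenerate pairing, never chosen
            else:
                scores[i, j] = paf_line_integral(
                    paf, limb_index, (ca.x, ca.y), (cb.x, cb.y), n_samples
                )
    finite = np.where(np.isfinite(scores), scores, -1e9)
    rows, cols = linear_sum_assignment(finite, maximize=True)
    out = [
        LimbCandidate(limb_index, candidates_a[i], candidates_b[j], float(scores[i, j]))
        for i, j in zip(rows, cols)
        if np.isfinite(scores[i, j]) and scores[i, j] >= score_threshold
    ]
    out.sort(key=lambda lc: (-lc.score, lc.cand_a.y, lc.cand_a.x))
    return out


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        root = x
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def assemble_skeletons(
    matches: list[LimbCandidate],
    limb_graph: LimbGraph,
    min_parts: int = 4,
) -> AssemblyResult:
    """Merge matched limbs that share candidates into skeleton instances.

    Instances with fewer than ``min_parts`` assigned keypoints are
    discarded to ``unassigned``.  Assigned parts get visibility 2 at the
    candidate's pixel; the rest get visibility 0.
    """
    # candidates are identified by object id; register each exactly once
    registry: dict[int, PeakCandidate] = {}
    uf = _UnionFind()
    matched_ids: set[int] = set()
    key_order: list[int] = []

    def _key(c: PeakCandidate) -> int:
        k = id(c)
        if k not in registry:
            registry[k] = c
            key_order.append(k)
        return k

    stable: dict[int, int] = {}  # first match index touching a key, for stable output order
    for idx, m in enumerate(matches):
        ka, kb = _key(m.cand_a), _key(m.cand_b)
        stable.setdefault(ka, idx)
        stable.setdefault(kb, idx)
        uf.union(ka, kb)
        matched_ids.update((ka, kb))

    groups: dict[int, list[PeakCandidate]] = {}
    for k in key_order:
        if k in matched_ids:
            groups.setdefault(uf.find(k), []).append(registry[k])

    skeletons: list[CowSkeleton] = []
    unassigned: list[PeakCandidate] = []
    ordered = sorted(groups.items(), key=lambda kv: stable[kv[0]])
    for inst_id, (_, cands) in enumerate(ordered):
        by_part: dict[int, PeakCandidate] = {}
        for c in cands:
            if c.part_id in by_part and by_part[c.part_id] is not c:
                raise AssertionError(
                    f"part {c.part_id} claimed by two candidates in one instance; "
                    "limb graph must be acyclic for consistent assembly"
                )
            by_part[c.part_id] = c
        if len(by_part) < min_parts:
            unassigned.extend(cands)
            continue
        kps = []
        for pid in range(1, N_PARTS + 1):
            if pid in by_part:
                c = by_part[pid]
                kps.append(Keypoint(pid, float(c.x), float(c.y), 2))
            else:
                kps.append(Keypoint(pid, 0.0, 0.0, 0))
        skeletons.append(CowSkeleton(kps, instance_id=inst_id))
    return AssemblyResult(skeletons, unassigned)


def group_candidates(
    candidates: list[PeakCandidate],
    paf: PafStack,
    limb_graph: LimbGraph,
    score_threshold: float = 0.05,
    min_parts: int = 4,
    n_samples: int = 10,
) -> AssemblyResult:
    """Full grouping: per-limb Hungarian matching, then assembly.

    Convenience wrapper running :func:`match_limb` for every limb of the
    graph over the peak candidates and assembling the matches.
    """
    by_part: dict[int, list[PeakCandidate]] = {}
    for c in candidates:
        by_part.setdefault(c.part_id, []).append(c)
    matches: list[LimbCandidate] = []
    for limb_index, (pa, pb) in enumerate(limb_graph):
        matches.extend(
            match_limb(
                by_part.get(pa, []),
                by_part.get(pb, []),
                paf,
                limb_index,
                score_threshold,
                n_samples,
            )
        )
    result = assemble_skeletons(matches, limb_graph, min_parts)
    assigned = {id(c) for m in matches for c in (m.cand_a, m.cand_b)}
    leftovers = [c for c in candidates if id(c) not in assigned]
    result.unassigned.extend(leftovers)
    return result
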