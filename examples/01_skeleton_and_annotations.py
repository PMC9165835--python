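"""Build a cow skeleton, inspect its geometry, and round-trip annotations.

The 16-part skeleton (head, neck, spine, coccyx, and four 3-joint legs)
is the unit every other stage works on.  Keypoints carry a visibility
flag: 2 visible, 1 occluded-but-labeled, 0 missing.
"""

import tempfile
from pathlib import Path

from cowpose import (
    AnnotatedImage,
    PoseParams,
    default_limb_graph,
    read_coco_keypoints,
    sample_skeleton,
    skeleton_bbox,
    write_coco_keypoints,
)

skel = sample_skeleton(PoseParams(pose="standing", seed=1))
box = skeleton_bbox(skel)
print(f"standing cow bbox: {box.width:.0f} x {box.height:.0f} px")
print(f"visible keypoints: {len(skel.labeled_keypoints)} of 16")

graph = default_limb_graph()
print(f"limb graph: {len(graph)} limbs (spanning tree over 16 parts)")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "ann.json"
    ann = AnnotatedImage("frame.png", 640, 480, skeletons=[skel])
    write_coco_keypoints([ann], path)
    back = read_coco_keypoints(path)[0]
    same = all(
        (a.x, a.y, a.visibility) == (b.x, b.y, b.visibility)
        for a, b in zip(skel.keypoints, back.skeletons[0].keypoints)
    )
    print(f"COCO-keypoints round trip lossless: {same}")
# The bbox is the tight envelope of labeled keypoints; it provides the
# object scale for OKS scoring and the classifier's normalization frame.
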