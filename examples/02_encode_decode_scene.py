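"""Bottom-up decoding of a multi-cow scene.

Generates a 3-cow synthetic scene, encodes the ground-truth Gaussian
keypoint heatmaps and part affinity fields (PAFs), then runs the full
decode chain — peak extraction, PAF line-integral scoring, Hungarian
limb matching, union-find assembly — and scores the recovered skeletons
with object keypoint similarity (OKS).
"""

from cowpose import compose_scene, compute_oks, decode_scene, oks_ap

scene, image = compose_scene(n_cows=3, overlap="none", lighting="day", seed=7)
print(f"scene: {len(scene.skeletons)} cows on a {scene.width}x{scene.height} canvas")

decoded = decode_scene(scene)
print(f"decoded instances: {len(decoded)}")

for gt in scene.skeletons:
    best = max(compute_oks(d, gt).value for d in decoded)
    print(f"  cow {gt.instance_id} ({gt.pose_label:>8}): best OKS = {best:.3f}")

ap = oks_ap(decoded, scene.skeletons, threshold=0.5)
print(f"OKS-AP@0.5 = {ap:.3f}")
# OKS = 1.0 means every keypoint was recovered at its exact pixel; with
# well-separated animals and noiseless encodings the pipeline is exact.
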