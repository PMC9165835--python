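# cowpose

Bottom-up 2D pose estimation for multiple dairy cows in barn surveillance
imagery, with a skeleton-coordinate classifier for the three daily poses
(standing, walking, lying). The package is aimed at precision-livestock
researchers who need the *geometry and evaluation machinery* of a
multi-animal pose pipeline — keypoint encoding/decoding, instance
grouping, detection-box losses, and metrics — in a form that is fully
testable on synthetic scenes, without farm footage or GPU training.

## What it implements

**Skeleton model.** Each cow is 16 named keypoints (head; neck, spine,
coccyx; four legs with root, knee, hoof), each with a visibility flag
(2 visible / 1 occluded / 0 missing) and pixel coordinates (origin
top-left, y down). A 15-edge anatomical spanning tree over the parts
defines the limbs.

**Keypoint heatmaps.** The ground-truth confidence of part *j* of cow
*k* at pixel *p* is a Gaussian around the true position *x*<sub>j,k</sub>:

    S*_{j,k}(p) = exp(-||p - x_{j,k}||^2 / (2 sigma^2))

with the per-part map taken as the pixelwise **max** over animals.
Candidates are recovered as thresholded 3×3 local maxima.

**Part affinity fields.** Every limb *c* stores, at each pixel on the
limb (a band of half-width `limb_width` around the segment), the unit
vector **v** from its first joint to its second; the mean is taken where
limbs of several animals overlap. A candidate pair (d<sub>j1</sub>,
d<sub>j2</sub>) is scored by the line integral

    E = ∫_0^1 L_c(p(u)) · (d_j2 - d_j1)/||d_j2 - d_j1|| du

evaluated by nearest-pixel sampling. Per limb, candidates are matched
one-to-one by maximizing total *E* with the Hungarian algorithm, and
matched limbs sharing candidates are merged into instances with
union-find.

**Box geometry.** Grid-cell box decoding, IoU, the CIoU regression loss
`L = 1 - IoU + d²/c² + αυ` (center distance *d*, enclosing-box diagonal
*c*, aspect term υ), confidence binary cross-entropy, and greedy NMS.

**Evaluation.** Detection precision/recall/AP with IoU-thresholded
TP/FP/FN rules; object keypoint similarity

    OKS = mean_i exp(-d_i^2 / (2 s^2 k_i^2))   over labeled GT keypoints,

its AP at OKS > 0.5; and 3×3 pose confusion-matrix metrics (column-wise
precision, row-wise recall, accuracy, column shares).

**Pose classifier.** A 32→128→64→16→4 fully connected network (batch
norm + ReLU per hidden layer, softmax output) on bbox-normalized
keypoint coordinates, implemented directly on numpy with Adam and
deterministic seeding. The fourth output unit ("other") is reserved for
transitional poses and receives no training data by default.

**Synthetic scenes.** A parametric stick-figure generator produces
pose-conditioned skeletons, multi-cow scenes with controlled occlusion
and day/night rendering, mosaic augmentation, and brightness
perturbation — every pipeline stage is testable end-to-end in-repo.

## Worked example

```python
from cowpose import compose_scene, decode_scene, compute_oks, oks_ap

scene, image = compose_scene(n_cows=3, overlap="none", seed=7)
decoded = decode_scene(scene)
for gt in scene.skeletons:
    best = max(compute_oks(d, gt).value for d in decoded)
    print(f"cow {gt.instance_id} ({gt.pose_label}): best OKS = {best:.3f}")
print("OKS-AP@0.5 =", oks_ap(decoded, scene.skeletons))
```

prints

```
cow 0 (lying): best OKS = 1.000
cow 1 (standing): best OKS = 1.000
cow 2 (walking): best OKS = 1.000
OKS-AP@0.5 = 1.0
```

i.e. with well-separated animals and noiseless encodings the full
heatmap → peaks → PAF integral → Hungarian → assembly chain returns
every cow with all 16 keypoints at their exact pixels. Training the
classifier (`python examples/04_pose_classifier.py`) on the default
600-skeletons-per-pose synthetic dataset reports

```
held-out accuracy: 0.9639
confusion matrix (rows actual, cols predicted; standing/walking/lying):
[[112   6   0]
 [  7 118   0]
 [  0   0 117]]
```

— the standing↔walking pair carries essentially all the confusion, as
slow walkers are genuinely ambiguous with standing cows, while lying is
nearly error-free.

More narrative scripts live in `examples/` (one per capability); a thin
CLI (`cowpose simulate|encode|group|train-pose|classify|evaluate|nms|run`)
wraps the same library functions for shell use.

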