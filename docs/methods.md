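# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices that affect results.

## Skeleton model and coordinate conventions

A cow is represented by 16 keypoints: head; neck, spine, coccyx (the
axial chain); and for each of the four legs a root, knee and hoof.
Coordinates are pixels, 0-based, origin at the image's top-left corner,
x rightward and y downward — the convention of LabelImg/Labelme-style
annotation tools. Visibility is three-state: 2 visible, 1 labeled but
occluded, 0 missing; all consumers treat {1, 2} as "labeled" and ignore
coordinates at visibility 0.

The limb set is not intrinsic to the keypoint list; the package adopts
a 15-edge anatomical spanning tree (head–neck, neck–spine,
spine–coccyx, neck to both front-leg roots, coccyx to both hind-leg
roots, and root–knee–hoof chains). Two properties of the tree matter:
it is connected, so any two matched limbs of one animal can be merged
into the same instance, and it is acyclic, so union-find assembly can
never claim two candidates of the same part for one instance (asserted
in code). Alternative limb sets can be supplied as a `LimbGraph`.

## Heatmap and PAF encoding

Per part *j* and animal *k*, the ground-truth heatmap value at pixel *p*
is `exp(-||p - x_jk||^2 / (2 sigma^2))`; channels combine animals with a
pixelwise max. `sigma` defaults to 2 px at full image resolution; the
encoding is done at full resolution because no learned downsampling
stage exists in this package. Decoding finds pixels that are ≥ all eight
neighbors and ≥ `peak_threshold` (default 0.1); equal-valued plateau
neighbors collapse to the lexicographically smallest (y, x) pixel, which
makes extraction deterministic.

The part affinity field of limb *c* holds the segment's unit vector at
every pixel whose projection onto the segment lies within [0, length]
and whose perpendicular distance is ≤ `limb_width` (default 4 px, a
plausible half-thickness of a cow leg at the rendered scale); a 1e-9
slack on the projection interval keeps the exact endpoints inside the
band despite floating-point rounding. Overlapping bands of several
animals average their vectors, so opposing limbs cancel.

## Grouping

A candidate pair is scored by the mean over `n_samples` = 10 uniformly
spaced points (endpoints included) of the dot product between the field
at the nearest pixel and the segment's unit direction; the score lies in
[-1, 1] and is antisymmetric under endpoint swap. No quadrature rule
beyond uniform sampling is warranted at these limb lengths. Per limb
type, the bipartite assignment maximizing total score is solved exactly
(`scipy.optimize.linear_sum_assignment`); pairs under `score_threshold`
(default 0.05) are dropped after assignment, so thresholding can only
remove, never re-route, matches. Assembly unions matched limbs through
shared candidates; instances with fewer than `min_parts` (default 4)
keypoints are discarded to the unassigned pool. A global joint
optimization across limb types is deliberately not attempted — per-limb
independent assignment is the standard greedy relaxation of bottom-up
grouping.

## Box geometry

Grid-cell decoding offers two modes. The default applies the logistic
function to the whole corner expression
(`xmin = sigma(tx + Cx - tw/2)`, etc.), which guarantees ordered corners
in (0, 1) but confines boxes to a fraction of the image regardless of
grid cell; a `canonical` mode implements the conventional YOLO decode
(logistic offset within the cell, exponential width/height, divided by
the grid size). Both are exposed because the literal form is unusual
enough that downstream users should choose consciously; the default
follows the literal definition.

CIoU is `1 - IoU + d^2/c^2 + alpha*v` with
`v = (4/pi^2)(arctan(w_gt/h_gt) - arctan(w/h))^2` and
`alpha = v/((1-IoU)+v)`, defined as 0 when `v = 0`. Zero heights are
rejected rather than clamped: a degenerate aspect ratio is an upstream
bug. NMS is greedy by descending confidence with suppression at IoU ≥
threshold (default 0.5) and input-order tie-breaking, making output
order reproducible.

## Evaluation

Detection TP/FP/FN supports two rules. The default "literal" rule
counts a ground-truth box as a false negative only when **no**
prediction overlaps it at all; a prediction whose best IoU is below
threshold is a false positive even when that overlap is nonzero. This
rule inflates recall relative to the conventional definition and is kept
as the default deliberately (it matches how the counts are often
described informally in livestock-vision evaluations); `mode="coco"`
gives the standard rule (every unmatched GT is a FN). AP integrates the
precision envelope over recall with all-point interpolation.

OKS is the mean over labeled ground-truth keypoints of
`exp(-d_i^2/(2 s^2 k_i^2))`. The object scale `s` defaults to the square
root of the ground-truth skeleton's bounding-box area, and `k_i` is a
uniform 0.1 unless per-part constants are supplied — there is no
published per-part constant table for cattle, so a single moderate value
is used; the visibility condition is read as v > 0 (labeled), since
occluded-but-labeled points carry coordinates. A labeled part missing
from the prediction contributes a zero term. OKS-AP matches predictions
to ground truths greedily by descending OKS (one-to-one) and reports the
fraction of ground-truth objects with a match above the threshold
(default 0.5).

Confusion-matrix metrics are column-wise precision, row-wise recall,
trace accuracy, and the column-share matrix (each cell over its column
total, the quantity behind statements like "7.58% of detected standing
was actually walking"). Zero rows/columns report NaN rather than 0 so
degenerate classes are visible.

## Pose classifier

Features are the 32 coordinates in part-id order, translated and scaled
to the skeleton's own bounding box, so the representation is invariant
to image position and apparent size; missing parts map to (0, 0). Raw
pixel mode is available (`normalize=False`). The network is
32→128→64→16→4 with batch normalization and ReLU after each hidden
layer and a softmax output, initialized Glorot-uniform from a seed.
The fourth output unit is reserved for poses outside the three trained
classes (transitions between lying and standing); it receives no
training data by default and is reported but never predicted in
practice. Training uses mean cross-entropy with Adam (lr 1e-3, batch
32, 30 epochs by default), shuffling from a seeded generator; batch-norm
inference uses running statistics (momentum 0.9). Everything is
bit-reproducible given the seeds. The implementation is plain numpy —
forward, backward and optimizer are a few hundred lines and need no deep
learning framework.

## Synthetic generator

The generator emulates side-view stick cows with three pose classes:

* **standing** — horizontal axial chain at leg height, straight legs,
  all hooves on one ground line;
* **walking** — standing geometry plus sinusoidal knee/hoof
  displacement with per-leg phase offsets (0, π, π/2, 3π/2); the swing
  amplitude is a per-animal factor in [0.25, 1] of 0.3 leg lengths;
* **lying** — axial chain lowered to the ground, legs folded so knee
  and hoof stay within 0.3 leg lengths of the root; overall height under
  half the standing height.

Default dimensions are body length 120 px and leg length 60 px (drawn
from ±~15% ranges in the dataset generator), Gaussian labeling jitter of
2 px, random left-right flips, and final rounding to integer pixels —
the output of a point-annotation tool. The amplitude floor of 0.25 is a
design choice: a hand-labeled training set only contains walkers that a
labeler could distinguish from standing, and below the floor the leg
displacement is within labeling jitter. Near the floor the classes
still overlap, which is what produces the standing↔walking confusion
structure; lying is geometrically distinct and essentially error-free.

Scenes place animals on disjoint grid cells ("none" overlap) or slide
one animal to a bounding-box IoU in [0.1, 0.4] with another ("partial"),
marking the occluded animal's covered keypoints visibility 1 with a
random 30% dropped to 0. Rendering is a grayscale stick-figure raster;
night mode scales intensity by 0.4 and adds Gaussian sensor noise.

What the generator does **not** emulate: photographic texture and
background clutter, perspective and camera tilt, body mass (the stick
figure has no silhouette), herd poses seen from the front (the
generator is strictly side-view), and transitional postures. Passing
tests on this generator therefore demonstrate the correctness of the
geometry, grouping, training and evaluation machinery — not detection
or keypoint-localization performance on real footage, which depends on
learned networks that are outside this package's scope.

## Problem sizes and determinism

The test suite and the acceptance script run multi-cow recovery on
480×768 canvases with up to 5 animals, the matching oracle on 200
random bipartite instances up to 5×5, and classifier training on 600
skeletons per pose with an 80/20 split — sizes chosen so a full run
completes in seconds on one CPU while still exercising every code path
at realistic scale. All randomness flows from explicit seeds;
rerunning any entry point with the same seed reproduces its output
byte-for-byte.

## Known limitations

* Heatmap peaks are integer pixels; no sub-pixel refinement is applied,
  so localization error on real (non-integer) annotations is up to half
  a pixel per axis.
* The literal grid-cell decode confines boxes to image fractions in
  (0, 1); use `canonical` mode for conventional behavior.
* Per-limb independent Hungarian matching can, in principle, stitch
  parts of different animals when their limbs overlap heavily; no
  midpoint or count penalty is applied during matching.
* The "literal" detection FN rule is nonstandard (see Evaluation);
  comparisons with other toolkits should use `mode="coco"`.
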