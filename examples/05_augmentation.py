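"""Data augmentation: mosaic composites and brightness perturbation.

Mosaic stitches four transformed annotated images into one training
canvas; brightness scaling emulates front-light/back-light conditions
(+/- 25% and 50%).  Annotations are transformed consistently and
survive both operations.
"""

import numpy as np

from cowpose import AnnotatedImage, adjust_brightness, compose_scene, mosaic_augment

anns = []
for seed in range(4):
    scene, image = compose_scene(1, seed=seed, height=240, width=320)
    anns.append(AnnotatedImage("src.png", 320, 240, skeletons=scene.skeletons, image=image))

mosaic = mosaic_augment(anns, out_size=(480, 640), seed=0)
print(f"mosaic canvas: {mosaic.image.shape}, cows kept: {len(mosaic.skeletons)}")

base = anns[0].image
for factor in (0.5, 0.75, 1.25, 1.5):
    adj = adjust_brightness(base, factor)
    print(f"brightness x{factor:<5} mean intensity {base.mean():6.1f} -> {adj.mean():6.1f}")
# Values clip at the sensor range [0, 255], so x1.5 saturates bright pixels.
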