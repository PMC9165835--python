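import numpy as np
import pytest

from cowpose.skeleton import CowSkeleton, Keypoint, default_limb_graph
from cowpose.synthetic import PoseParams, sample_skeleton


@pytest.fixture
def limb_graph():
    return default_limb_graph()


@pytest.fixture
def standing_skeleton():
    return sample_skeleton(PoseParams(pose="standing", seed=0))


@pytest.fixture
def lying_skeleton():
    return sample_skeleton(PoseParams(pose="lying", seed=0))


def make_skeleton(coords, visibility=None, pose="unknown"):
    """Skeleton from an explicit (16, 2) coordinate list."""
    vis = visibility if visibility is not None else [2] * 16
    kps = [Keypoint(i + 1, float(x), float(y), int(v)) for i, ((x, y), v) in enumerate(zip(coords, vis))]
    return CowSkeleton(kps, pose_label=pose)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
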