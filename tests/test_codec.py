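import math

import numpy as np
import pytest

from cowpose.codec import encode_heatmaps, encode_pafs, extract_peaks, load_stacks, save_stacks
from cowpose.skeleton import LimbGraph, default_limb_graph

from conftest import make_skeleton


def single_point_skeleton(x, y, part=1):
    coords = [(0, 0)] * 16
    coords[part - 1] = (x, y)
    vis = [0] * 16
    vis[part - 1] = 2
    return make_skeleton(coords, vis)


class TestEncodeHeatmaps:
    def test_unit_value_at_keypoint(self):
        hm = encode_heatmaps([single_point_skeleton(7, 5)], 20, 20, sigma=2.0)
        assert hm.values[0, 5, 7] == pytest.approx(1.0)

    def test_gaussian_falloff_at_distance_sigma(self):
        hm = encode_heatmaps([single_point_skeleton(10, 10)], 30, 30, sigma=2.0)
        assert hm.values[0, 10, 12] == pytest.approx(math.exp(-0.5), abs=1e-9)

    def test_multi_instance_takes_maximum(self):
        a = single_point_skeleton(5, 10)
        b = single_point_skeleton(15, 10)
        hm = encode_heatmaps([a, b], 24, 24, sigma=3.0)
        merged = hm.values[0]
        only_a = encode_heatmaps([a], 24, 24, sigma=3.0).values[0]
        only_b = encode_heatmaps([b], 24, 24, sigma=3.0).values[0]
        assert np.allclose(merged, np.maximum(only_a, only_b))

    def test_unlabeled_part_gives_zero_channel(self):
        hm = encode_heatmaps([single_point_skeleton(5, 5, part=1)], 16, 16, 2.0)
        assert hm.values[1].max() == 0.0

    def test_values_bounded_by_one(self, rng):
        skels = [single_point_skeleton(int(rng.integers(30)), int(rng.integers(30)))
                 for _ in range(4)]
        hm = encode_heatmaps(skels, 30, 30, sigma=4.0)
        assert hm.values.max() <= 1.0

    def test_reflection_symmetry(self):
        W = 31
        hm = encode_heatmaps([single_point_skeleton(8, 12)], 31, W, 2.0)
        reflected = encode_heatmaps([single_point_skeleton(W - 1 - 8, 12)], 31, W, 2.0)
        assert np.allclose(hm.values[0][:, ::-1], reflected.values[0])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            encode_heatmaps([], 10, 10, sigma=0.0)


def two_part_skeleton(a, b):
    coords = [(0, 0)] * 16
    coords[0], coords[13] = a, b  # head and neck: limb 0 of the default graph
    vis = [0] * 16
    vis[0] = vis[13] = 2
    return make_skeleton(coords, vis)


class TestEncodePafs:
    def test_horizontal_limb_has_unit_x_vector(self, limb_graph):
        skel = two_part_skeleton((0, 5), (10, 5))
        paf = encode_pafs([skel], limb_graph, 12, 16, limb_width=2.0)
        assert paf.values[0, 0, 5, 5] == pytest.approx(1.0)
        assert paf.values[0, 1, 5, 5] == pytest.approx(0.0)

    def test_off_band_pixels_zero(self, limb_graph):
        skel = two_part_skeleton((0, 5), (10, 5))
        paf = encode_pafs([skel], limb_graph, 20, 16, limb_width=2.0)
        assert paf.values[0, :, 15, 5].tolist() == [0.0, 0.0]

    def test_opposite_overlapping_limbs_cancel(self, limb_graph):
        fwd = two_part_skeleton((0, 5), (10, 5))
        bwd = two_part_skeleton((10, 5), (0, 5))
        paf = encode_pafs([fwd, bwd], limb_graph, 12, 16, limb_width=2.0)
        assert np.allclose(paf.values[0, :, 5, 5], 0.0)

    def test_vectors_have_unit_bound(self, limb_graph, standing_skeleton):
        paf = encode_pafs([standing_skeleton], limb_graph, 100, 200, 4.0)
        mag = np.hypot(paf.values[:, 0], paf.values[:, 1])
        assert mag.max() <= 1.0 + 1e-12

    def test_zero_length_limb_skipped_with_warning(self, limb_graph):
        skel = two_part_skeleton((5, 5), (5, 5))
        with pytest.warns(UserWarning, match="zero-length"):
            paf = encode_pafs([skel], limb_graph, 12, 12, 2.0)
        assert paf.values[0].max() == 0.0

    def test_band_area_scales_with_limb_length(self, limb_graph):
        short = two_part_skeleton((2, 10), (12, 10))
        long = two_part_skeleton((2, 10), (22, 10))
        w = 3.0
        area_short = (encode_pafs([short], limb_graph, 24, 30, w).values[0, 0] != 0).sum()
        area_long = (encode_pafs([long], limb_graph, 24, 30, w).values[0, 0] != 0).sum()
        band_height = area_short / 11  # pixels per unit length column
        assert area_long == pytest.approx(band_height * 21, abs=band_height)


class TestExtractPeaks:
    def test_single_gaussian_single_peak(self):
        hm = encode_heatmaps([single_point_skeleton(7, 5)], 20, 20, 2.0)
        peaks = extract_peaks(hm)
        assert len(peaks) == 1
        assert (peaks[0].x, peaks[0].y, peaks[0].score) == (7, 5, 1.0)

    def test_two_distant_gaussians_two_peaks(self):
        skels = [single_point_skeleton(5, 10), single_point_skeleton(25, 10)]
        hm = encode_heatmaps(skels, 24, 40, sigma=2.0)
        peaks = extract_peaks(hm)
        assert sorted((p.x, p.y) for p in peaks) == [(5, 10), (25, 10)]

    def test_zero_channel_yields_nothing(self):
        hm = encode_heatmaps([single_point_skeleton(5, 5, part=2)], 16, 16, 2.0)
        assert all(p.part_id == 2 for p in extract_peaks(hm))

    def test_plateau_reports_smallest_yx(self):
        from cowpose.codec import HeatmapStack

        values = np.zeros((16, 10, 10))
        values[0, 4:6, 4:6] = 0.7  # 2x2 plateau
        peaks = extract_peaks(HeatmapStack(values, 2.0))
        assert len(peaks) == 1
        assert (peaks[0].y, peaks[0].x) == (4, 4)

    def test_threshold_validated(self):
        hm = encode_heatmaps([], 8, 8, 2.0)
        with pytest.raises(ValueError):
            extract_peaks(hm, peak_threshold=0.0)

    def test_encode_extract_recovery(self, rng):
        """Well-separated keypoints are recovered at their exact pixels."""
        sigma = 2.0
        for _ in range(5):
            n = int(rng.integers(1, 4))
            pts = []
            while len(pts) < n:
                cand = (int(rng.integers(5, 55)), int(rng.integers(5, 55)))
                if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) > 4 * sigma for p in pts):
                    pts.append(cand)
            skels = [single_point_skeleton(x, y) for x, y in pts]
            hm = encode_heatmaps(skels, 60, 60, sigma)
            peaks = extract_peaks(hm)
            assert sorted((p.x, p.y) for p in peaks) == sorted(pts)


def test_stack_roundtrip(tmp_path, limb_graph, standing_skeleton):
    hm = encode_heatmaps([standing_skeleton], 90, 160, 2.0)
    paf = encode_pafs([standing_skeleton], limb_graph, 90, 160, 4.0)
    save_stacks(tmp_path / "s.npz", hm, paf)
    hm2, paf2 = load_stacks(tmp_path / "s.npz")
    assert np.array_equal(hm.values, hm2.values) and hm2.sigma == 2.0
    assert np.array_equal(paf.values, paf2.values) and paf2.limb_width == 4.0
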