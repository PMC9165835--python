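import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cowpose.annotations import (
    AnnotatedImage,
    read_coco_keypoints,
    read_labelme_keypoints,
    read_voc_boxes,
    write_coco_keypoints,
)
from cowpose.boxes import BoundingBox
from cowpose.skeleton import N_PARTS, PART_NAMES, CowSkeleton, Keypoint


def labelme_doc(shapes, width=640, height=480):
    return {
        "imagePath": "frame.png",
        "imageWidth": width,
        "imageHeight": height,
        "shapes": shapes,
    }


def point_shape(label, x, y, group_id=None):
    return {"label": label, "points": [[x, y]], "shape_type": "point", "group_id": group_id}


class TestLabelme:
    def test_full_skeleton_read(self, tmp_path):
        shapes = [point_shape(f"{name}:2", 10 * i + 5, 20 + i) for i, name in enumerate(PART_NAMES)]
        path = tmp_path / "a.json"
        path.write_text(json.dumps(labelme_doc(shapes)))
        ann = read_labelme_keypoints(path)
        assert len(ann.skeletons) == 1
        assert sum(1 for kp in ann.skeletons[0].keypoints if kp.visibility > 0) == 16

    def test_missing_parts_get_visibility_zero(self, tmp_path):
        shapes = [point_shape(f"{name}:2", 10, 10) for name in PART_NAMES[:12]]
        path = tmp_path / "b.json"
        path.write_text(json.dumps(labelme_doc(shapes)))
        skel = read_labelme_keypoints(path).skeletons[0]
        assert sum(1 for kp in skel.keypoints if kp.visibility == 0) == 4

    def test_bare_label_defaults_visible(self, tmp_path):
        path = tmp_path / "c.json"
        path.write_text(json.dumps(labelme_doc([point_shape("neck", 5, 5)])))
        skel = read_labelme_keypoints(path).skeletons[0]
        assert skel[14].visibility == 2

    def test_out_of_bounds_point_clipped_with_warning(self, tmp_path):
        path = tmp_path / "d.json"
        path.write_text(json.dumps(labelme_doc([point_shape("head:2", 700, -3)], width=640)))
        with pytest.warns(UserWarning, match="clipped"):
            ann = read_labelme_keypoints(path)
        head = ann.skeletons[0][1]
        assert (head.x, head.y) == (640.0, 0.0)

    def test_unknown_label_lists_valid_parts(self, tmp_path):
        path = tmp_path / "e.json"
        path.write_text(json.dumps(labelme_doc([point_shape("tail:2", 5, 5)])))
        with pytest.raises(ValueError, match="neck"):
            read_labelme_keypoints(path)

    def test_malformed_json_names_file(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="broken.json"):
            read_labelme_keypoints(path)

    def test_group_ids_split_instances(self, tmp_path):
        shapes = [point_shape("neck:2", 5, 5, group_id=1), point_shape("neck:1", 50, 50, group_id=2)]
        path = tmp_path / "f.json"
        path.write_text(json.dumps(labelme_doc(shapes)))
        ann = read_labelme_keypoints(path)
        assert len(ann.skeletons) == 2


VOC_TEMPLATE = """<annotation>
  <filename>frame.png</filename>
  {size}
  {objects}
</annotation>"""


def voc_obj(x0, y0, x1, y1, name="cow"):
    return (
        f"<object><name>{name}</name><bndbox><xmin>{x0}</xmin><ymin>{y0}</ymin>"
        f"<xmax>{x1}</xmax><ymax>{y1}</ymax></bndbox></object>"
    )


class TestVoc:
    SIZE = "<size><width>640</width><height>480</height></size>"

    def test_two_objects(self, tmp_path):
        doc = VOC_TEMPLATE.format(size=self.SIZE, objects=voc_obj(1, 2, 30, 40) + voc_obj(50, 60, 70, 80))
        path = tmp_path / "a.xml"
        path.write_text(doc)
        ann = read_voc_boxes(path)
        assert len(ann.boxes) == 2
        assert ann.boxes[0].xmin == 1 and ann.boxes[1].ymax == 80

    def test_inverted_box_normalized_with_warning(self, tmp_path):
        path = tmp_path / "b.xml"
        path.write_text(VOC_TEMPLATE.format(size=self.SIZE, objects=voc_obj(10, 20, 5, 25)))
        with pytest.warns(UserWarning, match="inverted"):
            ann = read_voc_boxes(path)
        b = ann.boxes[0]
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (5, 20, 10, 25)

    def test_missing_size_rejected(self, tmp_path):
        path = tmp_path / "c.xml"
        path.write_text(VOC_TEMPLATE.format(size="", objects=voc_obj(1, 2, 3, 4)))
        with pytest.raises(ValueError, match="size"):
            read_voc_boxes(path)

    def test_empty_object_list(self, tmp_path):
        path = tmp_path / "d.xml"
        path.write_text(VOC_TEMPLATE.format(size=self.SIZE, objects=""))
        assert read_voc_boxes(path).boxes == []


class TestCocoRoundtrip:
    def test_keypoints_flattened_to_48(self, tmp_path, standing_skeleton):
        ann = AnnotatedImage("x.png", 640, 480, skeletons=[standing_skeleton])
        write_coco_keypoints([ann], tmp_path / "a.json")
        doc = json.loads((tmp_path / "a.json").read_text())
        assert len(doc["annotations"][0]["keypoints"]) == 48
        assert doc["categories"][0]["keypoints"] == list(PART_NAMES)

    def test_empty_input_valid_file(self, tmp_path):
        write_coco_keypoints([], tmp_path / "empty.json")
        doc = json.loads((tmp_path / "empty.json").read_text())
        assert doc["images"] == [] and doc["annotations"] == []

    @given(data=st.data())
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_roundtrip_preserves_everything(self, data, tmp_path_factory):
        n_skel = data.draw(st.integers(0, 3))
        skels = []
        for s in range(n_skel):
            kps = []
            for pid in range(1, N_PARTS + 1):
                v = data.draw(st.sampled_from([0, 1, 2]))
                x = data.draw(st.floats(0, 640, allow_nan=False)) if v else 0.0
                y = data.draw(st.floats(0, 480, allow_nan=False)) if v else 0.0
                kps.append(Keypoint(pid, x, y, v))
            pose = data.draw(st.sampled_from(["standing", "walking", "lying", "unknown"]))
            skels.append(CowSkeleton(kps, pose_label=pose, instance_id=s))
        boxes = [
            BoundingBox(1.5, 2.5, 100.0, 120.25, confidence=0.75),
        ] * data.draw(st.integers(0, 2))
        ann = AnnotatedImage("img.png", 640, 480, skeletons=skels, boxes=list(boxes))
        path = tmp_path_factory.mktemp("coco") / "rt.json"
        write_coco_keypoints([ann], path)
        back = read_coco_keypoints(path)
        assert len(back) == 1
        rt = back[0]
        assert (rt.image_path, rt.width, rt.height) == ("img.png", 640, 480)
        assert len(rt.skeletons) == len(skels)
        for orig, new in zip(skels, rt.skeletons):
            assert orig.pose_label == new.pose_label
            assert orig.instance_id == new.instance_id
            for ka, kb in zip(orig.keypoints, new.keypoints):
                assert (ka.x, ka.y, ka.visibility) == (kb.x, kb.y, kb.visibility)
        for orig, new in zip(boxes, rt.boxes):
            assert (orig.xmin, orig.ymin, orig.xmax, orig.ymax, orig.confidence) == (
                new.xmin, new.ymin, new.xmax, new.ymax, new.confidence,
            )
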