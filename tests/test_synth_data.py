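"""Synthetic scene generator, VOC XML round-trips and augmentations."""

import xml.etree.ElementTree as ET

import numpy as np
import pytest

from giwtnet.metrics import DetectionBox, GroundTruthBox, map_suite
from giwtnet.synth_data import (
    CLASS_NAMES,
    AnnotatedImage,
    SceneSpec,
    generate_scene,
    load_split,
    make_dataset,
    mixup,
    mosaic,
    read_voc_xml,
    write_voc_xml,
)

_SMALL_CUT = 0.08  # between the small (2-6%) and large (10-25%) regimes


class TestGenerateScene:
    def test_empty_scene(self):
        scene = generate_scene(SceneSpec(n_objects=0, seed=1))
        assert scene.boxes == []
        assert scene.pixels.shape == (256, 256, 3)

    def test_deterministic_under_seed(self):
        a = generate_scene(SceneSpec(seed=42))
        b = generate_scene(SceneSpec(seed=42))
        assert np.array_equal(a.pixels, b.pixels)
        assert [x.box for x in a.boxes] == [x.box for x in b.boxes]
        c = generate_scene(SceneSpec(seed=43))
        assert not np.array_equal(a.pixels, c.pixels)

    def test_boxes_inside_image_with_positive_area(self):
        scene = generate_scene(SceneSpec(n_objects=12, seed=5))
        H, W = scene.pixels.shape[:2]
        for b in scene.boxes:
            x1, y1, x2, y2 = b.box
            assert 0 <= x1 < x2 <= W and 0 <= y1 < y2 <= H

    def test_size_mix_fraction_matches_binomial_expectation(self):
        small = total = 0
        for seed in range(10):
            spec = SceneSpec(n_objects=20, size_mix=0.5, seed=seed)
            scene = generate_scene(spec)
            side = min(spec.image_size)
            for b in scene.boxes:
                x1, y1, x2, y2 = b.box
                size = max(x2 - x1, y2 - y1)
                small += size < _SMALL_CUT * side
                total += 1
        # binomial 95% interval around p = 0.5
        p_hat = small / total
        half_width = 1.96 * np.sqrt(0.25 / total)
        assert abs(p_hat - 0.5) < half_width + 0.02

    def test_illumination_gain_scales_brightness(self):
        dim = generate_scene(SceneSpec(seed=3, illumination_gain=0.5))
        bright = generate_scene(SceneSpec(seed=3, illumination_gain=1.3))
        assert bright.pixels.mean() > 1.5 * dim.pixels.mean()

    def test_confusability_pulls_class_colours_together(self):
        def class_colour_spread(confus):
            means = {}
            for seed in range(10):
                scene = generate_scene(SceneSpec(
                    seed=seed, n_objects=12, texture_confusability=confus))
                for b in scene.boxes:
                    x1, y1, x2, y2 = (int(v) for v in b.box)
                    means.setdefault(b.class_id, []).append(
                        scene.pixels[y1:y2, x1:x2].mean(axis=(0, 1))
                    )
            centres = [np.mean(v, axis=0) for v in means.values()]
            return np.std(centres, axis=0).mean()

        assert class_colour_spread(1.0) < 0.6 * class_colour_spread(0.0)

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="class_weights"):
            SceneSpec(class_weights=(1, 0, 0, 0, 0, 0.5))
        with pytest.raises(ValueError, match="size_mix"):
            SceneSpec(size_mix=1.5)
        with pytest.raises(ValueError, match="illumination"):
            SceneSpec(illumination_gain=0)


class TestVocXml:
    def test_roundtrip_identity_on_integer_boxes(self, tmp_path):
        scene = generate_scene(SceneSpec(n_objects=5, seed=8))
        # snap to integers so the round-trip is exact
        scene.boxes = [
            GroundTruthBox(b.class_id, tuple(float(round(v)) for v in b.box))
            for b in scene.boxes
        ]
        path = tmp_path / "scene.xml"
        write_voc_xml(scene, path)
        boxes, shape = read_voc_xml(path)
        assert shape == scene.pixels.shape[:2]
        assert [(b.class_id, b.box) for b in boxes] == [
            (b.class_id, b.box) for b in scene.boxes
        ]

    def test_zero_based_to_one_based_convention(self, tmp_path):
        img = AnnotatedImage(np.zeros((20, 20, 3), np.uint8),
                             [GroundTruthBox(0, (0, 0, 10, 10))])
        path = tmp_path / "box.xml"
        write_voc_xml(img, path)
        root = ET.parse(path).getroot()
        bnd = root.find("object/bndbox")
        assert bnd.findtext("xmin") == "1" and bnd.findtext("ymin") == "1"
        assert bnd.findtext("xmax") == "10" and bnd.findtext("ymax") == "10"

    def test_parse_against_generic_xml_parser(self, tmp_path):
        scene = generate_scene(SceneSpec(n_objects=3, seed=12))
        path = tmp_path / "three.xml"
        write_voc_xml(scene, path)
        generic = ET.parse(path).getroot()
        names = [o.findtext("name") for o in generic.iter("object")]
        boxes, _ = read_voc_xml(path)
        assert len(boxes) == len(names) == len(scene.boxes)
        assert [CLASS_NAMES[b.class_id] for b in boxes] == names

    def test_unknown_class_and_malformed_file_errors(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text(
            "<annotation><size><width>8</width><height>8</height></size>"
            "<object><name>NotABeetle</name><bndbox><xmin>1</xmin><ymin>1</ymin>"
            "<xmax>4</xmax><ymax>4</ymax></bndbox></object></annotation>"
        )
        with pytest.raises(ValueError, match="NotABeetle"):
            read_voc_xml(bad)
        broken = tmp_path / "broken.xml"
        broken.write_text("<annotation><object>")
        with pytest.raises(ValueError, match="malformed"):
            read_voc_xml(broken)


class TestMosaic:
    def test_centre_middle_identical_inputs_tile(self):
        scene = generate_scene(SceneSpec(image_size=(64, 64), n_objects=2, seed=2))
        out = mosaic([scene] * 4, (128, 128), centre=(64, 64))
        # each quadrant holds the full (unscaled) image
        for qy, qx in ((0, 0), (0, 64), (64, 0), (64, 64)):
            assert np.array_equal(out.pixels[qy : qy + 64, qx : qx + 64], scene.pixels)
        assert len(out.boxes) == 4 * len(scene.boxes)

    def test_boxes_inside_canvas(self):
        scenes = [generate_scene(SceneSpec(image_size=(64, 64), n_objects=4, seed=s))
                  for s in range(4)]
        out = mosaic(scenes, (96, 96), seed=5)
        for b in out.boxes:
            x1, y1, x2, y2 = b.box
            assert 0 <= x1 < x2 <= 96 and 0 <= y1 < y2 <= 96

    def test_seam_clipping_matches_geometric_intersection(self):
        """A box crossing the quadrant seam keeps exactly its geometric
        intersection with the quadrant."""
        img = AnnotatedImage(np.zeros((64, 64, 3), np.uint8),
                             [GroundTruthBox(0, (40, 10, 60, 30))])
        blank = AnnotatedImage(np.zeros((64, 64, 3), np.uint8), [])
        out = mosaic([img, blank, blank, blank], (128, 128), centre=(64, 50))
        # quadrant 0 is rows 0:64, cols 0:50; image scaled by max(64/64, 50/64) = 1
        assert len(out.boxes) == 1
        assert out.boxes[0].box == (40, 10, 50, 30)

    def test_tiny_clip_fraction_drops_box(self):
        img = AnnotatedImage(np.zeros((64, 64, 3), np.uint8),
                             [GroundTruthBox(0, (48, 10, 63, 30))])
        blank = AnnotatedImage(np.zeros((64, 64, 3), np.uint8), [])
        out = mosaic([img, blank, blank, blank], (128, 128), centre=(64, 49))
        assert out.boxes == []  # 1/15 of the width survives -> under 10% area

    def test_requires_four_images(self):
        with pytest.raises(ValueError, match="exactly 4"):
            mosaic([AnnotatedImage(np.zeros((8, 8, 3), np.uint8), [])] * 3, (16, 16))


class TestMixup:
    def test_lam_one_returns_first_image(self):
        a = generate_scene(SceneSpec(seed=1, n_objects=2))
        b = generate_scene(SceneSpec(seed=2, n_objects=3))
        out = mixup(a, b, 1.0)
        assert np.array_equal(out.pixels, a.pixels)

    def test_midpoint_of_black_and_white_is_grey(self):
        black = AnnotatedImage(np.zeros((8, 8, 3), np.uint8), [])
        white = AnnotatedImage(np.full((8, 8, 3), 255, np.uint8), [])
        out = mixup(black, white, 0.5)
        assert np.all(np.abs(out.pixels.astype(int) - 128) <= 1)

    def test_box_union_with_source_weights(self):
        a = generate_scene(SceneSpec(seed=1, n_objects=2))
        b = generate_scene(SceneSpec(seed=2, n_objects=3))
        out = mixup(a, b, 0.3)
        assert len(out.boxes) == len(a.boxes) + len(b.boxes)
        assert out.box_weights[: len(a.boxes)] == [0.3] * len(a.boxes)
        assert out.box_weights[len(a.boxes):] == [0.7] * len(b.boxes)
        # each source pair contributes weights summing to 1
        assert out.box_weights[0] + out.box_weights[-1] == pytest.approx(1.0)

    def test_size_mismatch_rejected(self):
        a = AnnotatedImage(np.zeros((8, 8, 3), np.uint8), [])
        b = AnnotatedImage(np.zeros((16, 16, 3), np.uint8), [])
        with pytest.raises(ValueError, match="equal image sizes"):
            mixup(a, b, 0.5)


class TestMakeDataset:
    def test_layout_and_disjoint_manifests(self, tiny_dataset):
        root, index = tiny_dataset
        assert sorted(index) == ["test", "train", "val"]
        assert [len(index[s]) for s in ("train", "val", "test")] == [6, 2, 2]
        assert len(list((root / "images").glob("*.png"))) == 10
        assert len(list((root / "annotations").glob("*.xml"))) == 10
        all_ids = index["train"] + index["val"] + index["test"]
        assert len(set(all_ids)) == len(all_ids)

    def test_annotations_ingest_cleanly_and_oracle_detector_is_perfect(self, tiny_dataset):
        """Returning the ground truth as detections scores a perfect mAP —
        the end-to-end wiring check between generator, VOC I/O and metrics."""
        root, _ = tiny_dataset
        data = load_split(root, "val")
        gts = {img_id: boxes for img_id, _, boxes in data}
        dets = {
            img_id: [DetectionBox(b.class_id, b.box, 1.0) for b in boxes]
            for img_id, boxes in gts.items()
        }
        res = map_suite(dets, gts)
        assert res.map50 == pytest.approx(1.0)
        assert res.map50_95 == pytest.approx(1.0)

    def test_class_frequencies_within_multinomial_interval(self, tmp_path):
        weights = (0.4, 0.2, 0.1, 0.1, 0.1, 0.1)
        template = SceneSpec(image_size=(96, 96), n_objects=6, class_weights=weights)
        make_dataset(tmp_path / "freq", 20, 0, 0, template, seed=2)
        counts = np.zeros(6)
        for _, _, boxes in load_split(tmp_path / "freq", "train"):
            for b in boxes:
                counts[b.class_id] += 1
        total = counts.sum()
        for c, w in enumerate(weights):
            half_width = 1.96 * np.sqrt(w * (1 - w) / total)
            assert abs(counts[c] / total - w) < half_width + 0.03
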