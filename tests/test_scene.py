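"""Scene assembly, placement, label export, and dataset splitting."""

import numpy as np
import pytest

from fieldsynth import (
    BBox,
    PlacementError,
    SceneSpec,
    SplitSpec,
    build_scene,
    export_labels,
    identity_translator,
    import_yolo_labels,
    intersection_area,
    iou,
    place_nonoverlap,
    place_rows,
    sample_background_window,
    split_dataset,
    stats_transfer_translator,
    tight_bbox,
)


def _spec(**kw):
    defaults = dict(n_plants=3, tile_side=128, seed=42, color_correct=False)
    defaults.update(kw)
    return SceneSpec(**defaults)


class TestBackgroundWindow:
    def test_exact_size_soil_returns_whole_image(self, rng):
        soil = np.zeros((64, 64, 3), dtype=np.uint8)
        window, box = sample_background_window(soil, 64, rng)
        assert box == BBox(0, 0, 64, 64) and window.shape == (64, 64, 3)

    def test_reproducible_given_seed(self, soil_image):
        a = sample_background_window(soil_image, 128, np.random.default_rng(3))[1]
        b = sample_background_window(soil_image, 128, np.random.default_rng(3))[1]
        assert a == b

    def test_windows_always_inside_bounds(self, soil_image, rng):
        h, w = soil_image.shape[:2]
        for _ in range(200):
            _, box = sample_background_window(soil_image, 100, rng)
            assert 0 <= box.x0 and box.x1 <= w and 0 <= box.y0 and box.y1 <= h

    def test_too_small_soil_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_background_window(np.zeros((50, 50, 3), dtype=np.uint8), 64, rng)


class TestPlacement:
    def test_empty_canvas_accepts_first_draw(self, rng):
        box = place_nonoverlap([], 64, (256, 256), rng)
        assert box.width == box.height == 64

    def test_saturated_canvas_fails(self, rng):
        with pytest.raises(PlacementError):
            place_nonoverlap([BBox(0, 0, 64, 64)], 64, (64, 64), rng, max_attempts=10)

    def test_pairwise_disjoint_over_many_scenes(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            placed = []
            for _ in range(3):
                placed.append(place_nonoverlap(placed, 64, (320, 320), rng))
            for i in range(len(placed)):
                for j in range(i + 1, len(placed)):
                    assert iou(placed[i], placed[j]) == 0.0

    def test_rows_grid_symmetric_without_jitter(self):
        boxes = place_rows(4, 2, 64, (256, 256))
        assert boxes[0] == BBox(32, 32, 96, 96)
        assert boxes[1] == BBox(160, 32, 224, 96)
        assert boxes[2] == BBox(32, 160, 96, 224)
        assert boxes[3] == BBox(160, 160, 224, 224)

    def test_rows_deterministic(self):
        a = place_rows(5, 2, 40, (300, 300), jitter=8, rng=np.random.default_rng(1))
        b = place_rows(5, 2, 40, (300, 300), jitter=8, rng=np.random.default_rng(1))
        assert a == b

    def test_row_membership_recoverable_from_y(self):
        boxes = place_rows(6, 2, 50, (400, 500), jitter=5, rng=np.random.default_rng(2))
        ys = np.array([b.y0 for b in boxes])
        clusters = (ys > ys.mean()).astype(int)
        assert list(clusters) == [0, 0, 0, 1, 1, 1]

    def test_grid_overflow_rejected(self):
        with pytest.raises(ValueError):
            place_rows(9, 3, 100, (250, 250))


class TestBuildScene:
    def test_identity_pipeline_is_copy_paste(self, cutout_pool, soil_pool):
        # with the identity translator and no color correction the pipeline
        # reduces to copy-paste: every pixel outside the plant masks is
        # bit-equal to the untouched soil image, and each label box equals
        # the mask extent in scene coordinates
        scene = build_scene(_spec(seed=5), cutout_pool, soil_pool, identity_translator())
        soil = next(img for sid, img in soil_pool if sid == scene.soil_id)
        inside = np.zeros(scene.shape, dtype=bool)
        for rec in scene.provenance:
            tb = rec.tile_box
            assert rec.mask.sum() > 0
            assert tight_bbox(rec.mask, 0).shift(tb.x0, tb.y0) == rec.plant_box
            inside[tb.y0 : tb.y1, tb.x0 : tb.x1] |= rec.mask
        assert np.array_equal(scene.image[~inside], soil[~inside])
        assert (scene.image[inside] != soil[inside]).any()

    def test_single_plant_label_coordinates(self, cutout_pool, soil_pool):
        scene = build_scene(
            _spec(n_plants=1, seed=9), cutout_pool, soil_pool, identity_translator()
        )
        assert len(scene.labels) == 1
        rec = scene.provenance[0]
        box, label = scene.labels[0]
        assert label == "plant"
        inner = tight_bbox(rec.mask, 0)
        assert box == inner.shift(rec.tile_box.x0, rec.tile_box.y0)

    def test_deterministic_given_spec(self, cutout_pool, soil_pool):
        mk = lambda: build_scene(_spec(seed=13), cutout_pool, soil_pool, identity_translator())
        a, b = mk(), mk()
        assert np.array_equal(a.image, b.image)
        assert a.labels == b.labels

    def test_adding_plants_keeps_earlier_plants(self, cutout_pool, soil_pool):
        a = build_scene(_spec(n_plants=2, seed=21), cutout_pool, soil_pool, identity_translator())
        b = build_scene(_spec(n_plants=3, seed=21), cutout_pool, soil_pool, identity_translator())
        assert a.labels == b.labels[:2]

    def test_tile_boxes_disjoint(self, cutout_pool, soil_pool):
        scene = build_scene(_spec(n_plants=4, seed=3), cutout_pool, soil_pool, identity_translator())
        boxes = [r.tile_box for r in scene.provenance]
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                assert intersection_area(boxes[i], boxes[j]) == 0

    def test_color_correct_changes_plants_not_background(self, cutout_pool, soil_pool):
        plain = build_scene(_spec(seed=8), cutout_pool, soil_pool, identity_translator())
        corrected = build_scene(
            _spec(seed=8, color_correct=True), cutout_pool, soil_pool, identity_translator()
        )
        assert plain.labels == corrected.labels
        diff = plain.image != corrected.image
        changed = diff.any(axis=-1)
        inside = np.zeros_like(changed)
        for rec in plain.provenance:
            tb = rec.tile_box
            inside[tb.y0 : tb.y1, tb.x0 : tb.x1] |= rec.mask
        assert changed.any() and not changed[~inside].any()

    def test_background_fixed_point_on_pasted_windows(self, cutout_pool, soil_pool):
        from fieldsynth import background_offsets, exterior_mask

        translator = stats_transfer_translator(strength=0.25)
        scene = build_scene(
            _spec(seed=17, color_correct=True), cutout_pool, soil_pool, translator
        )
        # rebuild the pre-paste composites deterministically and compare means
        ref = build_scene(
            _spec(seed=17, color_correct=True), cutout_pool, soil_pool, identity_translator()
        )
        for rec, ref_rec in zip(scene.provenance, ref.provenance):
            tb = rec.tile_box
            window = scene.image[tb.y0 : tb.y1, tb.x0 : tb.x1]
            ref_window = ref.image[tb.y0 : tb.y1, tb.x0 : tb.x1]
            region = exterior_mask(window.shape[:2], tight_bbox(rec.mask, 0))
            d = background_offsets(ref_window, window, region)
            assert np.all(np.abs(d) <= 0.5)

    def test_species_filter_and_class_mode(self, cutout_pool, soil_pool):
        scene = build_scene(
            _spec(seed=2, species_filter=frozenset({"oat"}), class_mode="species"),
            cutout_pool,
            soil_pool,
            identity_translator(),
        )
        assert all(label == "oat" for _, label in scene.labels)

    def test_empty_pool_rejected(self, soil_pool):
        with pytest.raises(ValueError):
            build_scene(_spec(), [], soil_pool, identity_translator())


class TestLabelExport:
    def test_yolo_full_frame_box(self):
        text = export_labels((48, 64), [(BBox(0, 0, 64, 48), "plant")], "yolo")
        assert text.strip() == "0 0.500000 0.500000 1.000000 1.000000"

    def test_yolo_round_trip_within_one_px(self, cutout_pool, soil_pool):
        scene = build_scene(_spec(seed=31), cutout_pool, soil_pool, identity_translator())
        text = export_labels(scene.shape, scene.labels, "yolo")
        back = import_yolo_labels(text, scene.shape)
        assert len(back) == len(scene.labels)
        for (b1, l1), (b2, l2) in zip(scene.labels, back):
            assert l1 == l2
            assert max(abs(b1.x0 - b2.x0), abs(b1.y0 - b2.y0),
                       abs(b1.x1 - b2.x1), abs(b1.y1 - b2.y1)) <= 1

    def test_empty_labels_empty_file(self):
        assert export_labels((10, 10), [], "yolo") == ""

    def test_csv_dialect(self):
        text = export_labels((10, 10), [(BBox(1, 2, 3, 4), "plant")], "csv")
        assert text.strip() == "plant,1,2,3,4"

    def test_voc_xml_one_based_inclusive(self):
        text = export_labels((10, 10), [(BBox(0, 0, 10, 10), "plant")], "voc-xml")
        assert "<xmin>1</xmin>" in text and "<xmax>10</xmax>" in text

    def test_unknown_dialect(self):
        with pytest.raises(ValueError):
            export_labels((10, 10), [], "coco")


class TestSplitDataset:
    def test_canonical_80_10_10(self, rng):
        train, val, test = split_dataset(80_000, SplitSpec(), rng)
        assert (len(train), len(val), len(test)) == (64_000, 8_000, 8_000)

    def test_small_n(self, rng):
        train, val, test = split_dataset(10, SplitSpec(0.8, 0.1, 0.1), rng)
        assert (len(train), len(val), len(test)) == (8, 1, 1)

    def test_partition_property(self, rng):
        for n in (3, 17, 101, 1234):
            train, val, test = split_dataset(n, SplitSpec(), rng)
            union = set(train) | set(val) | set(test)
            assert union == set(range(n))
            assert len(train) + len(val) + len(test) == n

    def test_deterministic_shuffle(self):
        a = split_dataset(50, SplitSpec(), np.random.default_rng(1))
        b = split_dataset(50, SplitSpec(), np.random.default_rng(1))
        assert a == b

    def test_degenerate_inputs(self, rng):
        with pytest.raises(ValueError):
            split_dataset(2, SplitSpec(), rng)
        with pytest.raises(ValueError):
            SplitSpec(0.5, 0.2, 0.2)
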