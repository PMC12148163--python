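"""Synthetic scenes, YOLO label I/O, splits, letterboxing, degradations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scrnet.data_synth import (GTBox, LabelFormatError, Scene,
                               SceneSpec, augment, crop, degrade,
                               flip_horizontal, generate_scene, letterbox,
                               read_yolo_labels, split_dataset,
                               write_yolo_labels)


def test_scene_determinism():
    spec = SceneSpec(img_size=96, count_range=(2, 5))
    a = generate_scene(42, spec)
    b = generate_scene(42, spec)
    assert np.array_equal(a.image, b.image)
    assert a.boxes == b.boxes
    c = generate_scene(43, spec)
    assert not np.array_equal(a.image, c.image)


def test_scene_empty_count_range():
    scene = generate_scene(1, SceneSpec(img_size=64, count_range=(0, 0)))
    assert scene.boxes == []


def test_scene_zero_size_errors():
    with pytest.raises(ValueError, match="positive"):
        generate_scene(1, SceneSpec(img_size=0))


def test_scene_boxes_cover_rendered_objects():
    """Every labelled box overlaps pixels that differ from the background."""
    spec = SceneSpec(img_size=128, count_range=(3, 3),
                     obj_frac_range=(0.1, 0.2))
    scene = generate_scene(7, spec)
    bg = generate_scene(7, SceneSpec(img_size=128, count_range=(0, 0)))
    changed = np.abs(scene.image.astype(int) - bg.image.astype(int)).sum(2) > 30
    for b in scene.boxes:
        x1, y1, x2, y2 = (int(v) for v in b.to_xyxy(128, 128))
        assert changed[y1:y2, x1:x2].mean() > 0.2
        assert 0 <= b.class_id < 4


def test_mean_object_count_law_of_large_numbers():
    """Requested counts are uniform on [1,10]; with generous placement space
    the realised mean stays within 0.2 of the midpoint 5.5."""
    spec = SceneSpec(img_size=128, count_range=(1, 10),
                     obj_frac_range=(0.04, 0.08), iou_cap=0.5)
    counts = [len(generate_scene(s, spec).boxes) for s in range(1000)]
    assert abs(np.mean(counts) - 5.5) <= 0.2


def test_yolo_roundtrip_random_boxes(rng):
    boxes = []
    for _ in range(100):
        w, h = rng.uniform(0.02, 0.3, 2)
        cx = rng.uniform(w / 2, 1 - w / 2)
        cy = rng.uniform(h / 2, 1 - h / 2)
        boxes.append(GTBox(int(rng.integers(0, 4)), cx, cy, w, h))
    import tempfile, os
    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "x.txt")
        write_yolo_labels(boxes, path)
        back = read_yolo_labels(path)
    assert len(back) == 100
    for a, b in zip(boxes, back):
        assert a.class_id == b.class_id
        for f in ("cx", "cy", "w", "h"):
            assert abs(getattr(a, f) - getattr(b, f)) <= 1e-6


def test_yolo_row_parsing(tmp_path):
    p = tmp_path / "l.txt"
    p.write_text("0 0.5 0.5 0.2 0.1\n")
    (box,) = read_yolo_labels(str(p))
    assert box == GTBox(0, 0.5, 0.5, 0.2, 0.1)


def test_yolo_empty_scene_empty_file(tmp_path):
    p = tmp_path / "e.txt"
    write_yolo_labels([], str(p))
    assert p.read_text() == ""
    assert read_yolo_labels(str(p)) == []


@pytest.mark.parametrize("row,msg", [
    ("0 0.5 0.5 0.2", "5 fields"),
    ("0 0.5 0.5 0.2 0.1 9", "5 fields"),
    ("x 0.5 0.5 0.2 0.1", "invalid literal"),
    ("0 1.5 0.5 0.2 0.1", "outside"),
    ("0 0.5 0.5 0.0 0.1", "outside"),
])
def test_yolo_malformed_rows(tmp_path, row, msg):
    p = tmp_path / "bad.txt"
    p.write_text("0 0.5 0.5 0.2 0.1\n" + row + "\n")
    with pytest.raises(LabelFormatError, match=r":2"):
        read_yolo_labels(str(p))


def test_split_ratios():
    m = split_dataset([f"img{i}" for i in range(100)], seed=0)
    assert [len(m.splits[s]) for s in ("train", "val", "test")] == [70, 15, 15]
    m7 = split_dataset([f"img{i}" for i in range(7)], seed=0)
    assert [len(m7.splits[s]) for s in ("train", "val", "test")] == [5, 1, 1]


def test_split_determinism_and_disjointness():
    imgs = [f"img{i}" for i in range(50)]
    a = split_dataset(imgs, seed=3)
    b = split_dataset(imgs, seed=3)
    assert a.splits == b.splits
    allp = a.all_images()
    assert sorted(allp) == sorted(imgs) and len(set(allp)) == 50


def test_split_bad_ratios():
    with pytest.raises(ValueError, match="sum to 1"):
        split_dataset(["a"], ratios=(0.5, 0.4, 0.2))


def test_letterbox_1920x1080():
    img = np.zeros((1080, 1920, 3), np.uint8)
    out, tf = letterbox(img, 640)
    assert out.shape == (640, 640, 3)
    assert abs(tf.scale - 1 / 3) < 1e-9
    assert (tf.pad_x, tf.pad_y) == (0, 140)
    # padded rows take the fill value
    assert (out[:140] == 114).all() and (out[-140:] == 114).all()


def test_letterbox_square_no_pad():
    out, tf = letterbox(np.zeros((64, 64, 3), np.uint8), 128)
    assert (tf.pad_x, tf.pad_y) == (0, 0) and tf.scale == 2.0


def test_letterbox_box_remap_roundtrip(rng):
    src_w, src_h, target = 300, 200, 128
    for _ in range(50):
        w, h = rng.uniform(0.1, 0.4, 2)
        b = GTBox(0, rng.uniform(w / 2, 1 - w / 2),
                  rng.uniform(h / 2, 1 - h / 2), w, h)
        _, tf = letterbox(np.zeros((src_h, src_w, 3), np.uint8), target)
        mapped = tf.apply_box(b, src_w, src_h, target)
        back = tf.invert_xyxy(*mapped.to_xyxy(target, target))
        orig = b.to_xyxy(src_w, src_h)
        assert max(abs(a - o) for a, o in zip(back, orig)) <= 0.5


def test_flip_twice_is_identity():
    scene = generate_scene(5, SceneSpec(img_size=64, count_range=(2, 2)))
    twice = flip_horizontal(flip_horizontal(scene))
    assert np.array_equal(twice.image, scene.image)
    for a, b in zip(twice.boxes, scene.boxes):
        assert a.class_id == b.class_id
        assert abs(a.cx - b.cx) < 1e-9
        assert (a.cy, a.w, a.h) == (b.cy, b.w, b.h)


def test_crop_full_frame_is_identity():
    scene = generate_scene(6, SceneSpec(img_size=64, count_range=(2, 2)))
    c = crop(scene, 0, 0, 64, 64)
    assert np.array_equal(c.image, scene.image)
    assert len(c.boxes) == len(scene.boxes)
    for a, b in zip(c.boxes, scene.boxes):
        assert abs(a.cx - b.cx) < 1e-6 and abs(a.w - b.w) < 1e-6


def test_crop_drops_boxes_below_area_threshold():
    boxes = [GTBox(0, 0.5, 0.5, 0.2, 0.2),   # fully inside the crop
             GTBox(1, 0.05, 0.5, 0.08, 0.2)]  # almost fully outside
    scene = Scene(np.zeros((100, 100, 3), np.uint8), boxes)
    c = crop(scene, 40, 0, 100, 100)
    assert [b.class_id for b in c.boxes] == [0]


def test_flip_frequency():
    scene = generate_scene(8, SceneSpec(img_size=32, count_range=(1, 1)))
    flipped = 0
    for s in range(1000):
        out = augment(scene, seed=s, p_flip=0.5, p_crop=0.0, p_jitter=0.0)
        if not np.array_equal(out.image, scene.image):
            flipped += 1
    assert abs(flipped / 1000 - 0.5) <= 0.05


@pytest.mark.parametrize("kind", ["hazing", "blur", "low_contrast",
                                  "imbalanced_light"])
def test_degrade_zero_strength_identity(kind):
    img = generate_scene(9, SceneSpec(img_size=48)).image
    np.testing.assert_array_equal(degrade(img, kind, 0.0), img)


def test_degrade_blur_preserves_mean():
    img = generate_scene(10, SceneSpec(img_size=96)).image
    out = degrade(img, "blur", 0.6)
    assert abs(out.mean() - img.mean()) <= 0.01 * img.mean()


def test_degrade_low_contrast_reduces_std():
    img = generate_scene(11, SceneSpec(img_size=96)).image
    out = degrade(img, "low_contrast", 0.5)
    assert out.std() < img.std()


def test_degrade_hazing_moves_toward_airlight():
    img = generate_scene(12, SceneSpec(img_size=48)).image
    out = degrade(img, "hazing", 1.0)
    from scrnet.data_synth import _AIRLIGHT
    assert np.abs(out - _AIRLIGHT).mean() < np.abs(img - _AIRLIGHT).mean()


def test_degrade_errors():
    img = np.zeros((8, 8, 3), np.uint8)
    with pytest.raises(ValueError, match="unknown degradation"):
        degrade(img, "vignette", 0.5)
    with pytest.raises(ValueError, match="strength"):
        degrade(img, "blur", 1.5)


@given(cid=st.integers(0, 3),
       cx=st.floats(0.2, 0.8), cy=st.floats(0.2, 0.8),
       w=st.floats(0.01, 0.3), h=st.floats(0.01, 0.3))
@settings(derandomize=True, max_examples=50)
def test_gtbox_pixel_roundtrip(cid, cx, cy, w, h):
    """Normalised -> pixel -> normalised is exact up to float rounding."""
    b = GTBox(cid, cx, cy, w, h)
    back = GTBox.from_xyxy(cid, *b.to_xyxy(640, 640), 640, 640)
    for f in ("cx", "cy", "w", "h"):
        assert abs(getattr(b, f) - getattr(back, f)) < 1e-6
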