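"""Target assignment, loss behaviour and short learning checks.

Full-length overfitting lives in the acceptance suite; here each variant is
only required to reduce its loss over a few optimisation steps (gradient
flow through every block type), plus unit checks of the assigner and loss.
"""

import numpy as np
import pytest

from scrnet.assembly import VARIANTS, build_variant
from scrnet.autodiff import Tensor
from scrnet.train_smoke import (REG_MAX, TrainConfig, assign_targets,
                                detection_loss, make_anchors, predict,
                                train_overfit)

NC = 4


def _uniform_scores(A):
    return np.full((1, NC, A), 0.5, np.float32)


def _anchor_boxes(anchors, half=4.0):
    """Degenerate predicted boxes: a small square around each anchor."""
    A = anchors.shape[0]
    b = np.empty((1, 4, A), np.float32)
    b[0, 0], b[0, 1] = anchors[:, 0] - half, anchors[:, 1] - half
    b[0, 2], b[0, 3] = anchors[:, 0] + half, anchors[:, 1] + half
    return b


def test_assign_single_centered_gt():
    """A centred ground truth claims anchors; the anchor at its centre cell
    is among them."""
    anchors, strides = make_anchors(64)
    gt = (2, (24.0, 24.0, 40.0, 40.0))  # centred on (32, 32)
    tgt = assign_targets(_uniform_scores(len(anchors)),
                         _anchor_boxes(anchors), anchors, [[gt]], NC, 64)
    assert tgt.fg_mask.sum() >= 1
    centre = np.nonzero((anchors[:, 0] > 24) & (anchors[:, 0] < 40)
                        & (anchors[:, 1] > 24) & (anchors[:, 1] < 40))[0]
    assert tgt.fg_mask[0, centre].any()
    # assigned class is the gt class
    assert (tgt.scores[0, 2, tgt.fg_mask[0]] > 0).all()
    assert (tgt.scores[0, [0, 1, 3]][:, tgt.fg_mask[0]] == 0).all()


def test_assign_empty_gts_all_background():
    anchors, _ = make_anchors(64)
    tgt = assign_targets(_uniform_scores(len(anchors)),
                         _anchor_boxes(anchors), anchors, [[]], NC, 64)
    assert not tgt.fg_mask.any()
    assert tgt.scores.sum() == 0.0


def test_assign_every_gt_gets_an_anchor():
    """Even a box smaller than one grid cell receives its nearest anchor."""
    anchors, _ = make_anchors(64)
    tiny = (0, (1.0, 1.0, 3.0, 3.0))  # contains no stride-8 anchor centre
    tgt = assign_targets(_uniform_scores(len(anchors)),
                         _anchor_boxes(anchors), anchors, [[tiny]], NC, 64)
    assert tgt.fg_mask.sum() >= 1


def test_assign_two_gts_vs_ranking_oracle():
    """Conflicted anchors go to the gt with higher IoU; checked against an
    independent recomputation of the alignment ranking."""
    anchors, _ = make_anchors(64)
    A = len(anchors)
    rng = np.random.default_rng(0)
    scores = rng.uniform(0.1, 0.9, (1, NC, A)).astype(np.float32)
    boxes = _anchor_boxes(anchors, half=6.0)
    g1 = (1, (8.0, 8.0, 28.0, 28.0))
    g2 = (1, (20.0, 8.0, 40.0, 28.0))  # overlaps g1's territory
    tgt = assign_targets(scores, boxes, anchors, [[g1, g2]], NC, 64)
    from scrnet.metrics import iou
    for ai in np.nonzero(tgt.fg_mask[0])[0]:
        pb = tuple(boxes[0, :, ai])
        # winner must be the IoU-preferred gt among those claiming the anchor
        i1, i2 = iou(pb, g1[1]), iou(pb, g2[1])
        assigned_box = tuple(tgt.boxes[0, :, ai])
        if assigned_box == g1[1]:
            assert i1 >= i2 or not _inside(anchors[ai], g2[1])
        elif assigned_box == g2[1]:
            assert i2 >= i1 or not _inside(anchors[ai], g1[1])


def _inside(pt, box):
    return box[0] < pt[0] < box[2] and box[1] < pt[1] < box[3]


def test_gt_outside_image_rejected():
    anchors, strides = make_anchors(64)
    model = build_variant("baseline", num_classes=NC, input_size=64)
    model.eval()
    x = np.zeros((1, 3, 64, 64), np.float32)
    with pytest.raises(ValueError, match="outside the image"):
        detection_loss(model(x), [[(0, (-5.0, 0.0, 30.0, 30.0))]],
                       model.head.dfl, anchors, strides, NC, 64)


def test_loss_zero_box_loss_for_perfect_boxes():
    """Box logits placed as delta distributions on the exact bin reproduce
    the ground-truth box, so the CIoU term vanishes."""
    model = build_variant("baseline", num_classes=NC, input_size=64, seed=0)
    model.eval()
    anchors, strides = make_anchors(64)
    A = len(anchors)
    gt = (1, (16.0, 16.0, 48.0, 48.0))
    # craft raw maps: for every anchor, logits whose DFL expectation is the
    # exact (fractional) distance to the gt edges -- probability mass split
    # between the two neighbouring bins via log-weights
    dist = np.stack([(anchors[:, 0] - gt[1][0]), (anchors[:, 1] - gt[1][1]),
                     (gt[1][2] - anchors[:, 0]), (gt[1][3] - anchors[:, 1])])
    dist = np.clip(dist / strides, 0, REG_MAX - 1 - 1e-3)
    tl = np.floor(dist).astype(int)
    frac = dist - tl
    raw = []
    offset = 0
    for s in (8, 16, 32):
        g = 64 // s
        box = np.full((1, 4 * REG_MAX, g * g), -100.0, np.float32)
        for side in range(4):
            for a in range(g * g):
                t, f = tl[side, offset + a], frac[side, offset + a]
                box[0, side * REG_MAX + t, a] = np.log(max(1 - f, 1e-9))
                if t + 1 < REG_MAX:
                    box[0, side * REG_MAX + t + 1, a] = np.log(max(f, 1e-9))
        cls = np.full((1, NC, g * g), -20.0, np.float32)
        cls[0, 1] = 10.0  # confident on the right class
        raw.append((Tensor(box.reshape(1, 64, g, g)),
                    Tensor(cls.reshape(1, NC, g, g))))
        offset += g * g
    loss, comps = detection_loss(raw, [[gt]], model.head.dfl, anchors,
                                 strides, NC, 64)
    assert comps["box"] < 1e-4
    assert comps["n_fg"] >= 1


def test_loss_background_only_confident_negatives():
    """With no objects and strongly negative class logits, the loss -> 0."""
    model = build_variant("baseline", num_classes=NC, input_size=64, seed=0)
    anchors, strides = make_anchors(64)
    raw = []
    for s in (8, 16, 32):
        g = 64 // s
        raw.append((Tensor(np.zeros((1, 64, g, g), np.float32)),
                    Tensor(np.full((1, NC, g, g), -60.0, np.float32))))
    loss, comps = detection_loss(raw, [[]], model.head.dfl, anchors, strides,
                                 NC, 64)
    assert comps["cls"] < 1e-6
    assert comps["box"] == 0.0 and comps["dfl"] == 0.0


def test_loss_nan_input_aborts():
    model = build_variant("baseline", num_classes=NC, input_size=64, seed=0)
    model.eval()
    anchors, strides = make_anchors(64)
    x = np.full((1, 3, 64, 64), np.nan, np.float32)
    with pytest.raises(FloatingPointError, match="non-finite"):
        detection_loss(model(x), [[(0, (10.0, 10.0, 30.0, 30.0))]],
                       model.head.dfl, anchors, strides, NC, 64)


def test_zero_steps_empty_history(tiny_scenes):
    model = build_variant("CRS", num_classes=NC, input_size=64, seed=0)
    hist = train_overfit(model, tiny_scenes[:2],
                         TrainConfig(input_size=64, steps=0))
    assert hist.losses == [] and hist.maps == []


def test_training_determinism(tiny_scenes):
    finals = []
    for _ in range(2):
        model = build_variant("S", num_classes=NC, input_size=64, seed=7)
        hist = train_overfit(model, tiny_scenes[:2],
                             TrainConfig(input_size=64, steps=5, seed=7,
                                         eval_every=100))
        finals.append(hist.losses[-1]["total"])
    assert finals[0] == finals[1]


@pytest.mark.parametrize("variant", sorted(VARIANTS))
def test_loss_descends_for_every_variant(variant, tiny_scenes):
    """Twelve SGD steps must reduce the loss: gradients reach every block."""
    model = build_variant(variant, num_classes=NC, input_size=64, seed=0)
    cfg = TrainConfig(input_size=64, steps=12, batch_size=4, seed=0,
                      eval_every=100)
    hist = train_overfit(model, tiny_scenes[:4], cfg)
    first = np.mean([l["total"] for l in hist.losses[:3]])
    last = np.mean([l["total"] for l in hist.losses[-3:]])
    assert last < first, f"{variant}: {first:.3f} -> {last:.3f}"


def test_predict_returns_valid_detections(tiny_scenes):
    from scrnet.train_smoke import scenes_to_batch
    model = build_variant("baseline", num_classes=NC, input_size=64, seed=0)
    images, _ = scenes_to_batch(tiny_scenes[:2], 64)
    dets = predict(model, images, conf_thr=0.01)
    assert len(dets) == 2
    for img_dets in dets:
        for d in img_dets:
            assert 0 <= d.class_id < NC and 0.0 <= d.confidence <= 1.0
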