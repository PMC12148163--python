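"""Detection metrics against brute-force and hand-integration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scrnet.metrics import (ConfusionCounts, Detection, average_precision,
                            evaluate_detections, iou, map50, match_detections,
                            measure_speed, nms, pr_curve, precision, recall)


def D(c, conf, x1, y1, x2, y2):
    return Detection(c, conf, (x1, y1, x2, y2))


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------

def test_iou_examples():
    assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
    assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0
    # unit squares overlapping half: 0.5 / 1.5
    assert abs(iou((0, 0, 1, 1), (0.5, 0, 1.5, 1)) - 1 / 3) < 1e-12


# ---------------------------------------------------------------------------
# NMS vs brute force
# ---------------------------------------------------------------------------

def nms_bruteforce(dets, iou_thr, conf_thr):
    """O(n^2) reference suppression, implemented independently."""
    alive = sorted([d for d in dets if d.confidence >= conf_thr],
                   key=lambda d: -d.confidence)
    out = []
    while alive:
        best = alive.pop(0)
        out.append(best)
        alive = [d for d in alive
                 if d.class_id != best.class_id or iou(d.box, best.box) <= iou_thr]
    return out


def test_nms_trivial_cases():
    d = D(0, 0.9, 0, 0, 10, 10)
    assert nms([d]) == [d]
    d2 = D(0, 0.8, 0, 0, 10, 10)
    assert nms([d2, d], iou_thr=0.5, conf_thr=0.0) == [d]
    # different classes never suppress each other
    d3 = D(1, 0.8, 0, 0, 10, 10)
    assert nms([d, d3], iou_thr=0.5, conf_thr=0.0) == [d, d3]


def test_nms_randomized_vs_bruteforce(rng):
    for trial in range(30):
        dets = []
        for _ in range(int(rng.integers(1, 15))):
            x1, y1 = rng.uniform(0, 50, 2)
            w, h = rng.uniform(5, 30, 2)
            dets.append(D(int(rng.integers(0, 3)),
                          round(float(rng.uniform(0.01, 1.0)), 6),
                          x1, y1, x1 + w, y1 + h))
        got = nms(dets, iou_thr=0.45, conf_thr=0.1)
        ref = nms_bruteforce(dets, 0.45, 0.1)
        assert got == ref
        # no surviving same-class pair above the threshold
        for a, b in itertools.combinations(got, 2):
            assert a.class_id != b.class_id or iou(a.box, b.box) <= 0.45


# ---------------------------------------------------------------------------
# matching vs exhaustive oracles
# ---------------------------------------------------------------------------

def greedy_match_reference(dets, gts, thr):
    """Independent recursive statement of the greedy rule."""
    remaining = set(range(len(gts)))
    tp = 0
    for d in sorted(dets, key=lambda x: -x.confidence):
        cands = [(iou(d.box, gts[j][1]), j) for j in remaining
                 if gts[j][0] == d.class_id and iou(d.box, gts[j][1]) >= thr]
        if cands:
            _, j = max(cands)
            remaining.discard(j)
            tp += 1
    return tp


def max_matching_tp(dets, gts, thr):
    """Maximum attainable TP over all one-to-one assignments (enumeration)."""
    valid = [[j for j, g in enumerate(gts)
              if g[0] == d.class_id and iou(d.box, g[1]) >= thr]
             for d in dets]
    best = 0
    def rec(i, used, count):
        nonlocal best
        best = max(best, count)
        if i == len(dets):
            return
        rec(i + 1, used, count)
        for j in valid[i]:
            if j not in used:
                rec(i + 1, used | {j}, count + 1)
    rec(0, frozenset(), 0)
    return best


def test_match_perfect_predictions():
    gts = [(0, (0, 0, 10, 10)), (1, (20, 20, 30, 30))]
    dets = [D(0, 0.9, 0, 0, 10, 10), D(1, 0.8, 20, 20, 30, 30)]
    counts, flags = match_detections(dets, gts)
    assert (counts.TP, counts.FP, counts.FN) == (2, 0, 0)
    assert flags == [True, True]


def test_match_no_predictions():
    counts, flags = match_detections([], [(0, (0, 0, 5, 5))] * 3)
    assert (counts.TP, counts.FP, counts.FN) == (0, 0, 3)
    assert flags == []


def test_match_three_dets_two_gts_exhaustive():
    """Constructed 3-det/2-gt case checked against both oracles."""
    gts = [(0, (0, 0, 10, 10)), (0, (8, 0, 18, 10))]
    dets = [D(0, 0.9, 1, 0, 11, 10),   # overlaps both gts, best with gt0
            D(0, 0.8, 7, 0, 17, 10),   # best remaining: gt1
            D(0, 0.7, 2, 0, 12, 10)]   # everything already matched -> FP
    counts, flags = match_detections(dets, gts, iou_thr=0.5)
    assert (counts.TP, counts.FP, counts.FN) == (2, 1, 0)
    assert counts.TP == greedy_match_reference(dets, gts, 0.5)
    assert counts.TP == max_matching_tp(dets, gts, 0.5)


def test_match_random_instances_vs_oracles(rng):
    """On every random instance with <=6 boxes the greedy TP equals the
    independent greedy restatement and never exceeds the enumeration bound."""
    for trial in range(60):
        n_det, n_gt = int(rng.integers(0, 4)), int(rng.integers(0, 3))
        gts = []
        for _ in range(n_gt):
            x, y = rng.uniform(0, 30, 2)
            gts.append((int(rng.integers(0, 2)), (x, y, x + 10, y + 10)))
        dets = []
        for _ in range(n_det):
            x, y = rng.uniform(0, 30, 2)
            dets.append(D(int(rng.integers(0, 2)), float(rng.uniform(0.1, 1)),
                          x, y, x + 10, y + 10))
        counts, _ = match_detections(dets, gts, 0.5)
        assert counts.TP == greedy_match_reference(dets, gts, 0.5)
        assert counts.TP <= max_matching_tp(dets, gts, 0.5)
        assert counts.TP + counts.FN == n_gt
        assert counts.TP + counts.FP == n_det


# ---------------------------------------------------------------------------
# precision / recall / AP
# ---------------------------------------------------------------------------

def test_precision_recall_examples():
    assert precision(ConfusionCounts(TP=8, FP=2)) == 0.8
    assert recall(ConfusionCounts(TP=8, FN=8)) == 0.5
    c = ConfusionCounts(TP=5)
    assert precision(c) == 1.0 and recall(c) == 1.0
    z = ConfusionCounts()
    assert precision(z) == 0.0 and recall(z) == 0.0


def ap_fine_grid_reference(confs, flags, n_gt, grid=20001):
    """Independent AP: integrate the interpolated-precision envelope on a
    dense recall grid (p_interp(r) = max precision among points with
    recall >= r)."""
    order = np.argsort(-np.asarray(confs))
    tp = np.asarray(flags, bool)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    prec = cum_tp / (cum_tp + cum_fp)
    rec = cum_tp / n_gt
    rs = np.linspace(0, 1, grid)
    ps = np.zeros_like(rs)
    for i, r in enumerate(rs):
        cand = prec[rec >= r - 1e-12]
        ps[i] = cand.max() if len(cand) else 0.0
    return np.trapezoid(ps, rs)


def test_ap_perfect_and_allwrong():
    perfect = pr_curve([0.9, 0.8, 0.7], [True, True, True], 3)
    assert average_precision(perfect) == 1.0
    wrong = pr_curve([0.9, 0.8], [False, False], 2)
    assert average_precision(wrong) == 0.0


def test_ap_five_point_curve_vs_hand_integration():
    confs = [0.9, 0.8, 0.7, 0.6, 0.5]
    flags = [True, False, True, True, False]
    n_gt = 4
    ap = average_precision(pr_curve(confs, flags, n_gt))
    ref = ap_fine_grid_reference(confs, flags, n_gt, grid=200001)
    assert abs(ap - ref) < 1e-4
    # and against the literal hand computation of the envelope rectangles:
    # recall steps at 1/4 (p_env=1), 2/4 (p_env=3/4), 3/4 (p_env=3/4)
    assert abs(ap - (0.25 * 1.0 + 0.25 * 0.75 + 0.25 * 0.75)) < 1e-12


@given(st.lists(st.tuples(st.floats(0.01, 0.99), st.booleans()),
                min_size=1, max_size=20))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_ap_matches_fine_grid_reference(points):
    confs = [p[0] for p in points]
    flags = [p[1] for p in points]
    n_gt = max(sum(flags), 1) + 2
    ap = average_precision(pr_curve(confs, flags, n_gt))
    assert 0.0 <= ap <= 1.0
    assert abs(ap - ap_fine_grid_reference(confs, flags, n_gt)) < 1e-3


def test_ap_invariant_to_confidence_rescaling():
    confs = [0.9, 0.6, 0.4, 0.2]
    flags = [True, False, True, False]
    a = average_precision(pr_curve(confs, flags, 3))
    b = average_precision(pr_curve([c * 0.5 for c in confs], flags, 3))
    assert a == b


def test_ap_monotonicity_properties(rng):
    confs = list(rng.uniform(0.1, 0.9, 8))
    flags = list(rng.uniform(size=8) < 0.5)
    n_gt = int(sum(flags)) + 2
    base = average_precision(pr_curve(confs, flags, n_gt))
    # adding a false positive never increases AP
    worse = average_precision(pr_curve(confs + [0.5], flags + [False], n_gt))
    assert worse <= base + 1e-12
    # adding a true positive at top confidence never decreases it
    better = average_precision(pr_curve(confs + [0.99], flags + [True], n_gt))
    assert better >= base - 1e-12


def test_ap_undefined_without_gt():
    with pytest.raises(ValueError, match="no ground truth"):
        average_precision(pr_curve([0.5], [False], 0))


# ---------------------------------------------------------------------------
# mAP
# ---------------------------------------------------------------------------

def test_map_examples():
    assert map50([1.0, 1.0, 1.0, 1.0]) == 1.0
    assert abs(map50([0.8, 0.6]) - 0.7) < 1e-12
    with pytest.raises(ValueError):
        map50([])


def test_map_constructed_error_rates(rng):
    """A detector whose hits all rank above its false positives has, per
    class, AP exactly equal to its realised recall fraction (precision stays
    1 up to that recall, then drops to 0)."""
    per_image = []
    hits = {0: 0, 1: 0}
    total = {0: 0, 1: 0}
    for i in range(40):
        gts, dets = [], []
        for c in range(2):
            for j in range(5):
                x = 40.0 * j + 200.0 * c
                gts.append((c, (x, 0.0, x + 20, 20.0)))
                total[c] += 1
                if rng.uniform() < 0.8:
                    hits[c] += 1
                    dets.append(D(c, float(rng.uniform(0.6, 1.0)),
                                  x, 0.0, x + 20, 20.0))
                else:  # miss, plus a low-ranked false positive elsewhere
                    dets.append(D(c, float(rng.uniform(0.05, 0.4)),
                                  x + 1000, 0.0, x + 1020, 20.0))
        per_image.append((dets, gts))
    res = evaluate_detections(per_image, num_classes=2)
    expected = np.mean([hits[c] / total[c] for c in (0, 1)])
    assert abs(res.map50 - expected) <= 1e-9
    assert abs(res.map50 - 0.8) <= 0.06  # 3 sigma of the sampling noise


def test_evaluate_skips_absent_classes():
    per_image = [([D(0, 0.9, 0, 0, 10, 10)], [(0, (0, 0, 10, 10))])]
    res = evaluate_detections(per_image, num_classes=4)
    assert res.skipped_classes == [1, 2, 3]
    assert res.map50 == 1.0


def test_measure_speed():
    assert measure_speed([1.0, 1.0, 1.0]) == 1.0
    assert measure_speed([2.0, 4.0]) == 3.0
    with pytest.raises(ValueError):
        measure_speed([])
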