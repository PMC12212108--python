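"""IoU, ensemble fusion, detection evaluation, FP reclassification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protodbt.detection import (Detection, evaluate_detection, fuse_ensemble,
                                iou, read_predictions,
                                reclassify_false_positives)


# ----------------------------------------------------------------------- IoU

@pytest.mark.parametrize("a,b,expected", [
    ((0, 0, 2, 2), (0, 0, 2, 2), 1.0),
    ((0, 0, 2, 2), (5, 5, 2, 2), 0.0),
    ((0, 0, 2, 2), (1, 1, 2, 2), 1 / 7),
])
def test_iou_examples(a, b, expected):
    assert iou(a, b) == pytest.approx(expected)


def test_iou_zero_area_warns():
    with pytest.warns(UserWarning):
        assert iou((0, 0, 0, 2), (0, 0, 2, 2)) == 0.0


boxes = st.tuples(st.floats(0, 50), st.floats(0, 50),
                  st.floats(0.5, 30), st.floats(0.5, 30))


@given(a=boxes, b=boxes)
@settings(max_examples=200, derandomize=True)
def test_iou_symmetric_bounded_and_matches_shapely(a, b):
    """Geometric oracle: shapely polygon intersection/union."""
    from shapely.geometry import box as shapely_box

    v = iou(a, b)
    assert v == pytest.approx(iou(b, a))
    assert 0.0 <= v <= 1.0
    pa = shapely_box(a[0], a[1], a[0] + a[2], a[1] + a[3])
    pb = shapely_box(b[0], b[1], b[0] + b[2], b[1] + b[3])
    expected = pa.intersection(pb).area / pa.union(pb).area
    assert v == pytest.approx(expected, abs=1e-9)


# -------------------------------------------------------------------- fusion

def det(img, box, conf, src="model_a"):
    return Detection(img, box, conf, src)


def test_fusion_matched_pair_gets_mean_confidence():
    fused = fuse_ensemble([det("i", (0, 0, 10, 10), 0.6)],
                          [det("i", (1, 1, 10, 10), 0.8, "model_b")])
    assert len(fused) == 1
    assert fused[0].confidence == pytest.approx(0.7)
    assert fused[0].source == "ensemble"
    # box of the higher-confidence member is kept
    assert fused[0].bbox == (1, 1, 10, 10)


def test_fusion_below_threshold_keeps_both_with_halved_confidence():
    fused = fuse_ensemble([det("i", (0, 0, 10, 10), 0.6)],
                          [det("i", (8, 8, 10, 10), 0.8, "model_b")])
    confs = sorted(d.confidence for d in fused)
    assert confs == [0.3, 0.4]
    assert len(fused) == 2


def test_fusion_empty_inputs():
    assert fuse_ensemble([], []) == []


def test_fusion_output_sorted_by_confidence():
    fused = fuse_ensemble(
        [det("i", (0, 0, 5, 5), 0.2), det("i", (20, 20, 5, 5), 0.9)],
        [det("i", (0, 0, 5, 5), 0.4, "model_b")])
    confs = [d.confidence for d in fused]
    assert confs == sorted(confs, reverse=True)


def _greedy_oracle(da, db, thresh):
    """Independent re-implementation: repeatedly take the globally largest
    IoU pair above threshold (full re-scan each step)."""
    pairs = set()
    avail_a, avail_b = set(range(len(da))), set(range(len(db)))
    while True:
        best, arg = thresh, None
        for i in avail_a:
            for j in avail_b:
                ov = iou(da[i], db[j])
                if ov > best:
                    best, arg = ov, (i, j)
        if arg is None:
            return pairs
        pairs.add(arg)
        avail_a.discard(arg[0])
        avail_b.discard(arg[1])


def test_fusion_agrees_with_bruteforce_greedy_on_small_instances():
    rng = np.random.default_rng(12)
    for _ in range(40):
        na, nb = rng.integers(1, 7), rng.integers(1, 7)
        da = [(x, y, w, h) for x, y, w, h in
              zip(rng.uniform(0, 30, na), rng.uniform(0, 30, na),
                  rng.uniform(4, 15, na), rng.uniform(4, 15, na))]
        db = [(x, y, w, h) for x, y, w, h in
              zip(rng.uniform(0, 30, nb), rng.uniform(0, 30, nb),
                  rng.uniform(4, 15, nb), rng.uniform(4, 15, nb))]
        ious = [iou(a, b) for a in da for b in db]
        if len(set(ious)) != len(ious):  # ties void the comparison
            continue
        preds_a = [det("i", b, 0.5) for b in da]
        preds_b = [det("i", b, 0.6, "model_b") for b in db]
        fused = fuse_ensemble(preds_a, preds_b)
        merged = sum(1 for d in fused if d.confidence == pytest.approx(0.55))
        assert merged == len(_greedy_oracle(da, db, 0.3))


def test_fusion_total_iou_at_least_half_of_optimal():
    """Greedy matching is a 1/2-approximation of the optimal assignment."""
    from scipy.optimize import linear_sum_assignment

    rng = np.random.default_rng(3)
    for _ in range(25):
        na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        da = [(x, y, w, h) for x, y, w, h in
              zip(rng.uniform(0, 25, na), rng.uniform(0, 25, na),
                  rng.uniform(5, 18, na), rng.uniform(5, 18, na))]
        db = [(x, y, w, h) for x, y, w, h in
              zip(rng.uniform(0, 25, nb), rng.uniform(0, 25, nb),
                  rng.uniform(5, 18, nb), rng.uniform(5, 18, nb))]
        mat = np.array([[iou(a, b) for b in db] for a in da])
        mat = np.where(mat > 0.3, mat, 0.0)
        ri, ci = linear_sum_assignment(-mat)
        optimal = mat[ri, ci].sum()
        greedy_pairs = _greedy_oracle(da, db, 0.3)
        greedy_total = sum(iou(da[i], db[j]) for i, j in greedy_pairs)
        assert greedy_total >= 0.5 * optimal - 1e-9


# ---------------------------------------------------------------- evaluation

GT = {"img": [(0.0, 0.0, 10.0, 10.0)]}


def test_eval_tp_at_low_iou_and_conf():
    preds = [det("img", (6, 6, 10, 10), 0.5)]  # IoU = 16/184 ~ 0.087 < 0.1
    r = evaluate_detection(preds, GT, iou_min=0.05, conf_min=0.1)
    assert (r.tp, r.fp, r.fn) == (1, 0, 0)
    preds2 = [det("img", (5, 5, 10, 10), 0.5)]  # IoU = 25/175 ~ 0.143 > 0.1
    r2 = evaluate_detection(preds2, GT, iou_min=0.1, conf_min=0.1)
    assert (r2.tp, r2.recall, r2.precision) == (1, 1.0, 1.0)


def test_eval_below_confidence_threshold_ignored():
    r = evaluate_detection([det("img", (0, 0, 10, 10), 0.05)], GT,
                           conf_min=0.1)
    assert (r.tp, r.fp, r.fn) == (0, 0, 1)


def test_eval_one_to_one_matching():
    preds = [det("img", (0, 0, 10, 10), 0.9),
             det("img", (1, 1, 10, 10), 0.8)]
    r = evaluate_detection(preds, GT)
    assert (r.tp, r.fp) == (1, 1)


def test_eval_predictions_without_ground_truth_are_fp():
    r = evaluate_detection([det("ghost", (0, 0, 5, 5), 0.9)], GT)
    assert (r.tp, r.fp, r.fn) == (0, 1, 1)


def test_threshold_monotonicity():
    rng = np.random.default_rng(7)
    gts = {f"i{k}": [(rng.uniform(0, 40), rng.uniform(0, 40), 12.0, 12.0)]
           for k in range(15)}
    preds = []
    for k in range(15):
        g = gts[f"i{k}"][0]
        for _ in range(3):
            preds.append(det(f"i{k}",
                             (g[0] + rng.uniform(-8, 8),
                              g[1] + rng.uniform(-8, 8), 12.0, 12.0),
                             float(rng.uniform(0.05, 1.0))))
    prev_r, prev_fp = 1.1, np.inf
    for conf in (0.0, 0.2, 0.4, 0.6, 0.8):
        r = evaluate_detection(preds, gts, conf_min=conf)
        assert (r.recall or 0.0) <= prev_r + 1e-12
        assert r.fp <= prev_fp
        prev_r, prev_fp = (r.recall or 0.0), r.fp
    prev_r = 1.1
    for thr in (0.05, 0.1, 0.3, 0.5):
        r = evaluate_detection(preds, gts, iou_min=thr, conf_min=0.1)
        assert (r.recall or 0.0) <= prev_r + 1e-12
        prev_r = r.recall or 0.0


def test_ensemble_recall_at_least_single_models():
    """Complementary detectors: fused predictions recover both models' hits."""
    rng = np.random.default_rng(5)
    gts, pa, pb = {}, [], []
    for k in range(30):
        g = (float(rng.uniform(0, 40)), float(rng.uniform(0, 40)), 12.0, 12.0)
        gts[f"i{k}"] = [g]
        hit = (g[0] + 1, g[1] + 1, 12.0, 12.0)
        miss = (g[0] + 30, g[1] + 30, 12.0, 12.0)
        if k % 3 == 0:      # only model A finds it
            pa.append(det(f"i{k}", hit, 0.8))
            pb.append(det(f"i{k}", miss, 0.6, "model_b"))
        elif k % 3 == 1:    # only model B finds it
            pa.append(det(f"i{k}", miss, 0.6))
            pb.append(det(f"i{k}", hit, 0.8, "model_b"))
        else:               # both find it
            pa.append(det(f"i{k}", hit, 0.9))
            pb.append(det(f"i{k}", hit, 0.7, "model_b"))
    ra = evaluate_detection(pa, gts, conf_min=0.1).recall
    rb = evaluate_detection(pb, gts, conf_min=0.1).recall
    fused = fuse_ensemble(pa, pb)
    re = evaluate_detection(fused, gts, conf_min=0.05).recall
    assert re >= max(ra, rb)


# ------------------------------------------------------------ reclassify FPs

def _result_with_fps():
    gts = {f"i{k}": [(0.0, 0.0, 10.0, 10.0)] for k in range(15)}
    preds = []
    for k in range(15):
        if k < 10:
            preds.append(det(f"i{k}", (1, 1, 10, 10), 0.9))  # TP
        preds.append(det(f"i{k}", (40, 40, 10, 10), 0.8))    # FP (10 of them)
    return evaluate_detection(preds, gts, conf_min=0.1)


def test_reclassify_count_arithmetic():
    gts = {f"i{k}": [(0.0, 0.0, 10.0, 10.0)] for k in range(15)}
    preds = []
    for k in range(15):
        if k < 10:
            preds.append(det(f"i{k}", (1, 1, 10, 10), 0.9))
    for k in range(10):
        preds.append(det(f"i{k}", (40, 40, 10, 10), 0.8))
    r = evaluate_detection(preds, gts, conf_min=0.1)
    assert (r.tp, r.fp, r.fn) == (10, 10, 5)
    r2 = reclassify_false_positives(r, set(r.fp_ids[:4]))
    assert (r2.tp, r2.fp, r2.fn) == (14, 6, 5)
    assert r2.recall == pytest.approx(14 / 19)
    assert r2.precision == pytest.approx(0.7)
    # never decreases either metric
    assert r2.recall >= r.recall and r2.precision >= r.precision


def test_reclassify_empty_and_full_sets():
    r = _result_with_fps()
    same = reclassify_false_positives(r, set())
    assert (same.tp, same.fp, same.fn) == (r.tp, r.fp, r.fn)
    allacc = reclassify_false_positives(r, set(r.fp_ids))
    assert allacc.precision == 1.0


def test_fp_review_csv_round_trip(tmp_path):
    from protodbt.detection import read_accepted_fps, write_fp_review_csv

    r = _result_with_fps()
    path = write_fp_review_csv(r, tmp_path / "review.csv")
    rows = path.read_text().splitlines()
    assert rows[0] == "pred_id,image_id,confidence,accepted"
    assert len(rows) - 1 == r.fp
    # reviewer accepts the first two
    edited = [rows[0]] + [row + ("yes" if i < 2 else "no")
                          for i, row in enumerate(rows[1:])]
    path.write_text("\n".join(edited) + "\n")
    accepted = read_accepted_fps(path)
    assert len(accepted) == 2
    r2 = reclassify_false_positives(r, accepted)
    assert r2.tp == r.tp + 2 and r2.fp == r.fp - 2


def test_reclassify_unknown_id_rejected():
    r = _result_with_fps()
    with pytest.raises(ValueError):
        reclassify_false_positives(r, {"not-an-fp"})


# ------------------------------------------------------------ prediction I/O

def test_read_predictions_denormalizes(tmp_path):
    (tmp_path / "img1.txt").write_text("0 0.5 0.5 0.1 0.2 0.9\n")
    (tmp_path / "img2.txt").write_text("")
    dets = read_predictions(tmp_path, (1000, 1000))
    assert len(dets) == 1
    d = dets[0]
    assert d.image_id == "img1"
    assert d.bbox == pytest.approx((450.0, 400.0, 100.0, 200.0))
    assert d.confidence == 0.9


def test_read_predictions_rejects_malformed(tmp_path):
    (tmp_path / "a.txt").write_text("0 0.5 0.5 0.1\n")
    with pytest.raises(ValueError, match="line 1"):
        read_predictions(tmp_path, (100, 100))
    (tmp_path / "a.txt").write_text("0 0.5 0.5 0.1 0.1 1.5\n")
    with pytest.raises(ValueError, match="confidence"):
        read_predictions(tmp_path, (100, 100))
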