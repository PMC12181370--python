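import numpy as np
import pytest

from pigtag.annotations_io import BBox
from pigtag.evalmetrics import (
    EvalCounts,
    MAP_THRESHOLDS,
    PRCurve,
    average_precision,
    frame_gap_stats,
    frame_gap_table,
    match_detections,
    mean_ap,
    pr_curve,
    precision,
    recall,
    usecase_counts,
)


def random_instance(rng, n_preds=10, n_truths=10, n_cls=2):
    def mk(with_conf):
        cx, cy = rng.uniform(0.25, 0.75, 2)
        return BBox(int(rng.integers(0, n_cls)), cx, cy,
                    float(rng.uniform(0.05, 0.4)), float(rng.uniform(0.05, 0.4)),
                    conf=float(rng.uniform(0, 1)) if with_conf else 1.0)
    preds = [mk(True) for _ in range(int(rng.integers(0, n_preds + 1)))]
    truths = [mk(False) for _ in range(int(rng.integers(1, n_truths + 1)))]
    return preds, truths


def oracle_ap(preds, truths, iou_thr=0.5):
    """Independent brute-force Eq-5 evaluation by threshold enumeration."""
    flags, _ = match_detections(preds, truths, iou_thr)
    n_truth = len(truths)
    thresholds = sorted({b.conf for b in preds})  # ascending = recall non-increasing
    points = []
    for t in thresholds:
        sel = [i for i, b in enumerate(preds) if b.conf >= t]
        tp = sum(1 for i in sel if flags[i])
        p = tp / len(sel) if sel else 1.0
        r = tp / n_truth if n_truth else 0.0
        points.append((p, r))
    ap = 0.0
    m = len(points)
    for k in range(m):
        r_k = points[k][1]
        r_next = points[k + 1][1] if k + 1 < m else 0.0
        ap += (r_k - r_next) * points[k][0]
    return ap


class TestPrecisionRecall:
    def test_contingency_values(self):
        c = EvalCounts(tp=1020, fp=97, fn=110)
        assert round(precision(c), 3) == 0.913
        assert round(recall(c), 3) == 0.903
        assert c.tp + c.fn == 1130

    def test_zero_denominators(self):
        assert precision(EvalCounts()) == 0.0
        assert recall(EvalCounts()) == 0.0

    def test_simple_values(self):
        assert precision(EvalCounts(tp=5, fp=5)) == 0.5
        assert recall(EvalCounts(tp=3, fn=1)) == 0.75

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            EvalCounts(tp=-1)

    def test_addition(self):
        assert EvalCounts(1, 2, 3) + EvalCounts(4, 5, 6) == EvalCounts(5, 7, 9)

    def test_outputs_in_unit_interval(self, rng):
        for _ in range(50):
            c = EvalCounts(*(int(v) for v in rng.integers(0, 100, 3)))
            assert 0.0 <= precision(c) <= 1.0
            assert 0.0 <= recall(c) <= 1.0


class TestMatchDetections:
    def test_exact_match(self):
        t = BBox(0, 0.5, 0.5, 0.2, 0.2)
        p = BBox(0, 0.5, 0.5, 0.2, 0.2, conf=0.9)
        flags, fn = match_detections([p], [t])
        assert flags == [True] and fn == 0

    def test_pred_without_truth(self):
        p = BBox(0, 0.5, 0.5, 0.2, 0.2, conf=0.9)
        flags, fn = match_detections([p], [])
        assert flags == [False] and fn == 0

    def test_truth_without_pred(self):
        t = BBox(0, 0.5, 0.5, 0.2, 0.2)
        flags, fn = match_detections([], [t])
        assert flags == [] and fn == 1

    def test_class_mismatch_never_matches(self):
        t = BBox(1, 0.5, 0.5, 0.2, 0.2)
        p = BBox(0, 0.5, 0.5, 0.2, 0.2, conf=0.9)
        flags, fn = match_detections([p], [t])
        assert flags == [False] and fn == 1

    def test_greedy_oracle_equivalence(self, rng):
        from pigtag.detect import iou

        def oracle(preds, truths, thr):
            flags = [False] * len(preds)
            fn = 0
            for cls in {b.cls for b in preds} | {b.cls for b in truths}:
                order = sorted([i for i, b in enumerate(preds) if b.cls == cls],
                               key=lambda i: -preds[i].conf)
                avail = [j for j, b in enumerate(truths) if b.cls == cls]
                for i in order:
                    scored = [(iou(preds[i], truths[j]), j) for j in avail]
                    scored = [s for s in scored if s[0] >= thr]
                    if scored:
                        best = max(scored)[1]
                        avail.remove(best)
                        flags[i] = True
                fn += len([j for j, b in enumerate(truths) if b.cls == cls]) - (
                    len([1 for i in order if flags[i]]))
            return flags, fn

        for _ in range(30):
            preds, truths = random_instance(rng)
            assert match_detections(preds, truths) == oracle(preds, truths, 0.5)


class TestAveragePrecision:
    def test_single_correct_prediction(self):
        t = BBox(0, 0.5, 0.5, 0.2, 0.2)
        p = BBox(0, 0.5, 0.5, 0.2, 0.2, conf=0.9)
        assert average_precision(pr_curve([p], [t])) == pytest.approx(1.0)

    def test_no_predictions(self):
        t = BBox(0, 0.5, 0.5, 0.2, 0.2)
        assert average_precision(pr_curve([], [t])) == 0.0

    def test_two_threshold_example(self):
        t = BBox(0, 0.5, 0.5, 0.2, 0.2)
        correct = BBox(0, 0.5, 0.5, 0.2, 0.2, conf=0.9)
        wrong = BBox(0, 0.1, 0.1, 0.05, 0.05, conf=0.8)
        preds = [correct, wrong]
        got = average_precision(pr_curve(preds, [t]))
        assert got == pytest.approx(oracle_ap(preds, [t]), abs=1e-12)
        assert got == pytest.approx(1.0)  # the correct pred has higher conf

    def test_oracle_equivalence_random_sets(self, rng):
        for _ in range(50):
            preds, truths = random_instance(rng, n_cls=1)
            got = average_precision(pr_curve(preds, truths))
            assert got == pytest.approx(oracle_ap(preds, truths), abs=1e-9)

    def test_duplicate_threshold_invariance(self):
        curve = PRCurve(thresholds=(0.8, 0.8, 0.5),
                        precisions=(1.0, 1.0, 0.5),
                        recalls=(0.5, 0.5, 0.5))
        dedup = PRCurve(thresholds=(0.8, 0.5), precisions=(1.0, 0.5),
                        recalls=(0.5, 0.5))
        assert average_precision(curve) == pytest.approx(average_precision(dedup))


class TestMeanAP:
    def _perfect(self, rng, n=20):
        truths, preds = [], []
        for _ in range(n):
            cx, cy = rng.uniform(0.3, 0.7, 2)
            b = BBox(int(rng.integers(0, 3)), cx, cy, 0.05, 0.05)
            truths.append(b)
            preds.append(BBox(b.cls, b.cx, b.cy, b.w, b.h, conf=0.99))
        return preds, truths

    def test_perfect_detector(self, rng):
        preds, truths = self._perfect(rng)
        res = mean_ap(preds, truths)
        assert res.map50 == pytest.approx(1.0)
        assert res.map50_95 == pytest.approx(1.0)

    def test_silent_detector(self, rng):
        _, truths = self._perfect(rng)
        res = mean_ap([], truths)
        assert res.map50 == 0.0 and res.map50_95 == 0.0

    def test_no_truth_error(self):
        with pytest.raises(ValueError):
            mean_ap([BBox(0, 0.5, 0.5, 0.1, 0.1, conf=0.9)], [])

    def test_single_threshold_equals_class_mean(self, rng):
        preds, truths = random_instance(rng, n_cls=3)
        res = mean_ap(preds, truths, thresholds=(0.5,))
        assert res.map50_95 == pytest.approx(np.mean(list(res.per_class_ap.values())))

    def test_default_thresholds(self):
        assert len(MAP_THRESHOLDS) == 10
        assert MAP_THRESHOLDS[0] == 0.5 and MAP_THRESHOLDS[-1] == 0.95


class TestUsecaseCounts:
    def test_set_arithmetic_example(self):
        c = usecase_counts([["41", "57"]], [["41", "39"]])
        assert (c.tp, c.fp, c.fn) == (1, 1, 1)

    def test_perfect_frames(self):
        frames = [["10", "20"], ["33"]]
        c = usecase_counts(frames, frames)
        assert c.fp == 0 and c.fn == 0 and c.tp == 3

    def test_conservation(self, rng):
        ids = [str(v) for v in range(10, 30)]
        for _ in range(20):
            props = list(rng.choice(ids, size=rng.integers(0, 5)))
            truth = list(rng.choice(ids, size=rng.integers(0, 5)))
            c = usecase_counts([props], [truth])
            assert c.tp + c.fp == len(props)
            assert c.tp + c.fn == len(truth)

    def test_multiset_duplicates(self):
        c = usecase_counts([["41", "41"]], [["41"]])
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            usecase_counts([["41"]], [])

    def test_table_totals(self):
        # per-frame counts summing to the published contingency row
        frames_p, frames_t = [], []
        for _ in range(1020):
            frames_p.append(["11"]); frames_t.append(["11"])
        for _ in range(97):
            frames_p.append(["12"]); frames_t.append(["13"])
        for _ in range(13):
            frames_p.append([]); frames_t.append(["14"])
        c = usecase_counts(frames_p, frames_t)
        assert (c.tp, c.fp, c.fn) == (1020, 97, 110)
        assert round(precision(c), 3) == 0.913
        assert round(recall(c), 3) == 0.903


class TestFrameGap:
    def test_three_detections(self):
        assert frame_gap_stats([3, 5, 9]) == (3, 3.0)

    def test_single_detection(self):
        assert frame_gap_stats([7]) == (1, None)

    def test_empty(self):
        assert frame_gap_stats([]) == (0, None)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            frame_gap_stats([5, 3])

    def test_table(self):
        table = frame_gap_table({"41": [9, 3, 5], "57": [2]})
        assert table == {"41": (3, 3.0), "57": (1, None)}
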