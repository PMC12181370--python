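"""Detection and identification metrics.

Detection metrics are the standard precision / recall / AP family:

    Recall    = TP / (TP + FN)
    Precision = TP / (TP + FP)
    AP_c      = sum_{k=0}^{m-1} [Recall(k) - Recall(k+1)] * Precision(k)

with the sentinel Recall(m) = 0 and Precision(m) = 1, where k indexes the
confidence thresholds in descending order.  mAP0.5 averages AP_c over
classes at IoU 0.5; mAP0.5:0.95 additionally averages over the ten IoU
thresholds 0.50, 0.55, ..., 0.95.  The AP sum is implemented literally
(no 11-point or monotone-envelope interpolation).

ID-level "use case" accounting counts a TP when an ID is correctly
identified, an FP when a tag is detected but its ID is wrong, and an FN
when a visible ID is not proposed.  Frame-gap statistics summarize, per
ID, how often it was detected and the mean frame spacing between
consecutive detections.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from typing import Mapping, Sequence

import numpy as np

from .annotations_io import BBox
from .detect import iou

__all__ = [
    "EvalCounts",
    "PRCurve",
    "MAPResult",
    "precision",
    "recall",
    "match_detections",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "usecase_counts",
    "frame_gap_stats",
    "MAP_THRESHOLDS",
]

MAP_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclasses.dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclasses.dataclass(frozen=True)
class PRCurve:
    """Precision/recall pairs indexed by confidence threshold.

    Index k runs 0..m-1 with recall non-increasing in k (thresholds
    ascend, so k = 0 is the most permissive operating point); the
    sentinel point Recall(m) = 0, Precision(m) = 1 closes the curve and
    is implicit in :func:`average_precision`.
    """

    thresholds: tuple
    precisions: tuple
    recalls: tuple


@dataclasses.dataclass(frozen=True)
class MAPResult:
    per_class_ap: dict
    map50: float
    map50_95: float


def precision(c: EvalCounts) -> float:
    """TP / (TP + FP); 0 when the denominator is 0."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def recall(c: EvalCounts) -> float:
    """TP / (TP + FN); 0 when the denominator is 0."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def match_detections(
    preds: Sequence[BBox],
    truths: Sequence[BBox],
    iou_thr: float = 0.5,
) -> tuple[list[bool], int]:
    """Greedy per-class matching (Pascal-VOC style).

    Within each class, predictions sorted by confidence descending are
    matched to the unmatched truth of maximal IoU >= ``iou_thr``.  Returns
    a TP flag per prediction (in the original order) and the FN count
    (unmatched truths).
    """
    flags = [False] * len(preds)
    fn = 0
    classes = {b.cls for b in preds} | {b.cls for b in truths}
    for cls in classes:
        p_idx = sorted(
            (i for i, b in enumerate(preds) if b.cls == cls),
            key=lambda i: -preds[i].conf,
        )
        t_idx = [i for i, b in enumerate(truths) if b.cls == cls]
        taken: set[int] = set()
        for i in p_idx:
            best_j, best_iou = -1, iou_thr
            for j in t_idx:
                if j in taken:
                    continue
                v = iou(preds[i], truths[j])
                if v >= best_iou:
                    best_iou, best_j = v, j
            if best_j >= 0:
                taken.add(best_j)
                flags[i] = True
        fn += len(t_idx) - len(taken)
    return flags, fn


def pr_curve(preds: Sequence[BBox], truths: Sequence[BBox], iou_thr: float = 0.5) -> PRCurve:
    """Build the threshold-indexed PR curve for one class's detections.

    One operating point per distinct confidence value, ordered so recall
    is non-increasing in the index k (see :class:`PRCurve`).
    """
    n_truth = len(truths)
    flags, _ = match_detections(preds, truths, iou_thr)
    order = sorted(range(len(preds)), key=lambda i: -preds[i].conf)
    thresholds, precisions, recalls = [], [], []
    tp = fp = 0
    for rank, i in enumerate(order):
        if flags[i]:
            tp += 1
        else:
            fp += 1
        # one curve point per distinct confidence (last entry at that conf)
        if rank + 1 < len(order) and preds[order[rank + 1]].conf == preds[i].conf:
            continue
        thresholds.append(preds[i].conf)
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_truth if n_truth else 0.0)
    # cumulative processing gives ascending recall; reverse for the
    # non-increasing-recall indexing the AP sum uses
    return PRCurve(tuple(thresholds[::-1]), tuple(precisions[::-1]),
                   tuple(recalls[::-1]))


def average_precision(curve: PRCurve) -> float:
    """The literal AP sum: sum_k [R(k) - R(k+1)] * P(k) with R(m) = 0."""
    m = len(curve.thresholds)
    ap = 0.0
    for k in range(m):
        r_k = curve.recalls[k]
        r_next = curve.recalls[k + 1] if k + 1 < m else 0.0  # Recall(m) = 0
        ap += (r_k - r_next) * curve.precisions[k]
    return ap


def _ap_for_class(preds, truths, iou_thr) -> float:
    return average_precision(pr_curve(preds, truths, iou_thr))


def mean_ap(
    preds: Sequence[BBox],
    truths: Sequence[BBox],
    thresholds: Sequence[float] = MAP_THRESHOLDS,
) -> MAPResult:
    """Per-class AP and its means over classes and IoU thresholds.

    Classes with no ground truth are excluded from the class means.
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    truth_classes = sorted({b.cls for b in truths})
    if not truth_classes:
        raise ValueError("no class has any ground truth")
    per_class: dict[int, float] = {}
    per_thr_means = []
    for thr in thresholds:
        aps = {}
        for cls in truth_classes:
            p = [b for b in preds if b.cls == cls]
            t = [b for b in truths if b.cls == cls]
            aps[cls] = _ap_for_class(p, t, thr)
        per_thr_means.append(float(np.mean(list(aps.values()))))
        if np.isclose(thr, 0.5):
            per_class = aps
    map50 = float(np.mean(list(per_class.values()))) if per_class else per_thr_means[0]
    return MAPResult(per_class_ap=per_class, map50=map50,
                     map50_95=float(np.mean(per_thr_means)))


def usecase_counts(
    per_frame_proposals: Sequence[Sequence[str]],
    per_frame_truth: Sequence[Sequence[str]],
) -> EvalCounts:
    """ID-level contingency totals over aligned frame lists.

    Per frame: TP += |proposals ∩ truth|, FP += |proposals \\ truth|,
    FN += |truth \\ proposals| (multiset arithmetic).
    """
    if len(per_frame_proposals) != len(per_frame_truth):
        raise ValueError("frame lists must be aligned")
    total = EvalCounts()
    for props, truth in zip(per_frame_proposals, per_frame_truth):
        cp, ct = Counter(props), Counter(truth)
        tp = sum((cp & ct).values())
        total = total + EvalCounts(tp, sum(cp.values()) - tp, sum(ct.values()) - tp)
    return total


def frame_gap_stats(detection_frames: Sequence[int]) -> tuple[int, float | None]:
    """(frequency, average gap between consecutive detections or None).

    Input must be strictly increasing frame indices for one ID.
    """
    frames = list(detection_frames)
    if any(b <= a for a, b in zip(frames, frames[1:])):
        raise ValueError("detection frames must be strictly increasing")
    if len(frames) < 2:
        return len(frames), None
    gaps = np.diff(frames)
    return len(frames), float(gaps.mean())


def frame_gap_table(
    results: Mapping[str, Sequence[int]]
) -> dict[str, tuple[int, float | None]]:
    """Per-ID frequency / average-gap table from id -> frame indices."""
    return {id_: frame_gap_stats(sorted(fr)) for id_, fr in sorted(results.items())}
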