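"""Segmentation and vessel-detection metrics.

Pixel-level: Dice score and Jaccard index per class, and a 10x10 confusion
matrix (rows = true class, columns = predicted class).

Instance-level: a predicted vessel that covers more than half of a true
vessel's pixels is a candidate true positive; predictions are matched
one-to-one to truths greedily by descending coverage (ties broken by true
vessel size, then index). Unmatched predictions are false positives,
unmatched truths false negatives. Because the coverage fractions of one
truth by disjoint predictions sum to at most 1, at most one prediction can
exceed 50% of any truth — conflicts arise only when one prediction covers
more than half of several truths, which is exactly the *merge* phenomenon.
A *split* is a truth covered substantially (> ``split_min_frac``) by two or
more predictions, none individually above 50%. Both are reported as
percentages of the number of true vessels. Metrics over several images are
pooled (micro-averaged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imageio import LabelMap, N_CLASSES
from .morphometry import VesselInstance


def dice_jaccard(pred_mask: np.ndarray, true_mask: np.ndarray) -> tuple[float, float]:
    """Dice = 2|A∩B|/(|A|+|B|), Jaccard = |A∩B|/|A∪B|; NaN when both empty."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(true_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int((a & b).sum())
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return float("nan"), float("nan")
    dice = 2.0 * inter / (sa + sb)
    jaccard = inter / (sa + sb - inter)
    return dice, jaccard


def confusion_matrix(pred: LabelMap, true: LabelMap, n_classes: int = N_CLASSES) -> np.ndarray:
    """Pixel-wise counts; ``cm[i, j]`` = pixels of true class i predicted j."""
    if pred.shape != true.shape:
        raise ValueError(f"label map shapes differ: {pred.shape} vs {true.shape}")
    joint = true.codes.astype(np.int64).ravel() * n_classes + pred.codes.astype(np.int64).ravel()
    return np.bincount(joint, minlength=n_classes * n_classes).reshape(n_classes, n_classes)


@dataclass
class DetectionReport:
    n_true: int
    n_pred: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    merged_pct: float
    split_pct: float


def _coverage_table(pred_instances: list[VesselInstance], true_instances: list[VesselInstance],
                    shape: tuple[int, int]) -> np.ndarray:
    """``cov[p, t]`` = fraction of true vessel t's pixels covered by pred p."""
    pred_lab = _instances_to_labels(pred_instances, shape)
    true_lab = _instances_to_labels(true_instances, shape)
    np_, nt = len(pred_instances), len(true_instances)
    counts = np.zeros((np_ + 1, nt + 1), dtype=np.int64)
    joint = pred_lab.ravel() * (nt + 1) + true_lab.ravel()
    bc = np.bincount(joint, minlength=(np_ + 1) * (nt + 1))
    counts = bc.reshape(np_ + 1, nt + 1)
    cov = np.zeros((np_, nt), dtype=np.float64)
    for t, inst in enumerate(true_instances):
        if inst.area_px:
            cov[:, t] = counts[1:, t + 1] / inst.area_px
    return cov


def _instances_to_labels(instances: list[VesselInstance], shape: tuple[int, int]) -> np.ndarray:
    lab = np.zeros(shape, dtype=np.int64)
    for i, inst in enumerate(instances, start=1):
        r0, c0 = inst.offset_rc
        h, w = inst.mask.shape
        view = lab[r0 : r0 + h, c0 : c0 + w]
        view[inst.mask] = i
    return lab


def detect_vessels(
    pred_instances: list[VesselInstance],
    true_instances: list[VesselInstance],
    shape: tuple[int, int],
    overlap_frac: float = 0.5,
    split_min_frac: float = 0.1,
) -> DetectionReport:
    """Instance-level detection report under the >50%-coverage rule."""
    n_true, n_pred = len(true_instances), len(pred_instances)
    nan = float("nan")
    if n_true == 0:
        return DetectionReport(0, n_pred, 0, n_pred, 0, nan, nan, nan, nan, nan)
    cov = _coverage_table(pred_instances, true_instances, shape)

    # candidate (coverage, pred, true) pairs above threshold, matched greedily
    cand = [
        (cov[p, t], true_instances[t].area_px, p, t)
        for p in range(n_pred)
        for t in range(n_true)
        if cov[p, t] > overlap_frac
    ]
    cand.sort(key=lambda x: (-x[0], -x[1], x[3]))
    used_pred: set[int] = set()
    used_true: set[int] = set()
    tp = 0
    for _, _, p, t in cand:
        if p in used_pred or t in used_true:
            continue
        used_pred.add(p)
        used_true.add(t)
        tp += 1
    fp = n_pred - len(used_pred)
    fn = n_true - tp

    precision = tp / n_pred if n_pred else nan
    recall = tp / n_true
    f1 = 2 * precision * recall / (precision + recall) if (n_pred and precision + recall > 0) else (0.0 if n_pred else nan)

    merged = 0
    for p in range(n_pred):
        hits = np.flatnonzero(cov[p] > overlap_frac)
        if len(hits) >= 2:
            merged += len(hits)
    split = 0
    for t in range(n_true):
        col = cov[:, t]
        if (col > overlap_frac).any():
            continue
        if int((col > split_min_frac).sum()) >= 2:
            split += 1

    return DetectionReport(
        n_true=n_true,
        n_pred=n_pred,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1,
        merged_pct=100.0 * merged / n_true,
        split_pct=100.0 * split / n_true,
    )


def pool_reports(reports: list[DetectionReport]) -> DetectionReport:
    """Micro-average: pool tp/fp/fn counts across images, recompute rates."""
    n_true = sum(r.n_true for r in reports)
    n_pred = sum(r.n_pred for r in reports)
    tp = sum(r.tp for r in reports)
    fp = sum(r.fp for r in reports)
    fn = sum(r.fn for r in reports)
    merged = sum(r.merged_pct * r.n_true / 100.0 for r in reports)
    split = sum(r.split_pct * r.n_true / 100.0 for r in reports)
    nan = float("nan")
    precision = tp / n_pred if n_pred else nan
    recall = tp / n_true if n_true else nan
    f1 = 2 * precision * recall / (precision + recall) if n_pred and n_true and precision + recall > 0 else nan
    return DetectionReport(n_true, n_pred, tp, fp, fn, precision, recall, f1,
                           100.0 * merged / n_true if n_true else nan,
                           100.0 * split / n_true if n_true else nan)
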