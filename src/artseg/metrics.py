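"""Segmentation and detection metrics.

Pixel-wise precision/recall/F1/IoU, image-level classification F1 with
"artifact" as the positive class, object-wise F1 over greedily matched
connected components, and pooled-pixel precision-recall curves.

Metrics whose denominator is zero (e.g. precision when nothing was
predicted) are reported as ``None`` rather than silently coerced to 0;
aggregation skips undefined entries so clean images do not deflate
dataset averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi

Granularity = Literal["pixel", "object", "image"]

_STRUCTS = {1: ndi.generate_binary_structure(2, 1),   # 4-connectivity
            2: ndi.generate_binary_structure(2, 2)}   # 8-connectivity


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class MetricsReport:
    """Precision/recall/F1/IoU at one granularity; None marks undefined."""

    precision: float | None
    recall: float | None
    f1: float | None
    iou: float | None
    granularity: Granularity
    n_units: int
    counts: ConfusionCounts | None = None


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def report_from_counts(c: ConfusionCounts, granularity: Granularity,
                       n_units: int) -> MetricsReport:
    precision = _safe_div(c.tp, c.tp + c.fp)
    recall = _safe_div(c.tp, c.tp + c.fn)
    # equivalent to the harmonic mean of precision and recall, but defined
    # whenever any positive exists on either side
    f1 = _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    iou = _safe_div(c.tp, c.tp + c.fp + c.fn)
    return MetricsReport(precision=precision, recall=recall, f1=f1, iou=iou,
                         granularity=granularity, n_units=n_units, counts=c)


def _check_binary_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return pred, gt


def pixel_metrics(pred_mask: np.ndarray, gt_mask: np.ndarray) -> MetricsReport:
    """Pixel-wise confusion of a binary prediction against ground truth."""
    pred, gt = _check_binary_pair(pred_mask, gt_mask)
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = pred.size - tp - fp - fn
    return report_from_counts(ConfusionCounts(tp, fp, fn, tn), "pixel", pred.size)


def image_level_f1(pred_labels: Sequence[str], true_labels: Sequence[str],
                   positive: str = "artifact") -> MetricsReport:
    """Image-level detection metrics with the artifact class as positive."""
    if len(pred_labels) != len(true_labels):
        raise ValueError("label lists must have equal length")
    valid = {positive, "clean"}
    for lab in list(pred_labels) + list(true_labels):
        if lab not in valid:
            raise ValueError(f"unknown label {lab!r}")
    p = np.array([l == positive for l in pred_labels])
    t = np.array([l == positive for l in true_labels])
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = len(p) - tp - fp - fn
    return report_from_counts(ConfusionCounts(tp, fp, fn, tn), "image", len(p))


def _label_components(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    return ndi.label(mask, structure=_STRUCTS[connectivity])


def match_objects(pred_mask: np.ndarray, gt_mask: np.ndarray,
                  iou_threshold: float = 0.5,
                  connectivity: int = 2) -> tuple[list[tuple[int, int, float]], int, int]:
    """Greedy one-to-one matching of connected components by descending IoU.

    Returns (matches as (pred_id, gt_id, iou) with iou >= threshold,
    n_pred_objects, n_gt_objects).
    """
    pred, gt = _check_binary_pair(pred_mask, gt_mask)
    pl, np_obj = _label_components(pred, connectivity)
    gl, ng_obj = _label_components(gt, connectivity)
    if np_obj == 0 or ng_obj == 0:
        return [], np_obj, ng_obj
    pairs: dict[tuple[int, int], int] = {}
    both = (pl > 0) & (gl > 0)
    for pi, gi in zip(pl[both], gl[both]):
        pairs[(int(pi), int(gi))] = pairs.get((int(pi), int(gi)), 0) + 1
    p_sizes = np.bincount(pl.ravel(), minlength=np_obj + 1)
    g_sizes = np.bincount(gl.ravel(), minlength=ng_obj + 1)
    cands = []
    for (pi, gi), inter in pairs.items():
        union = p_sizes[pi] + g_sizes[gi] - inter
        cands.append((inter / union, pi, gi))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    matches = []
    for iou, pi, gi in cands:
        if pi in used_p or gi in used_g or iou < iou_threshold:
            continue
        used_p.add(pi)
        used_g.add(gi)
        matches.append((pi, gi, float(iou)))
    return matches, np_obj, ng_obj


def object_f1(pred_mask: np.ndarray, gt_mask: np.ndarray,
              iou_threshold: float = 0.5, connectivity: int = 2) -> MetricsReport:
    """Object-wise F1: matched components are TP, the rest FP/FN."""
    matches, np_obj, ng_obj = match_objects(pred_mask, gt_mask,
                                            iou_threshold, connectivity)
    tp = len(matches)
    c = ConfusionCounts(tp=tp, fp=np_obj - tp, fn=ng_obj - tp, tn=0)
    return report_from_counts(c, "object", np_obj + ng_obj - tp)


def pr_curve(score_maps: Sequence[np.ndarray], gt_masks: Sequence[np.ndarray],
             thresholds: Sequence[float]) -> tuple[list[dict], float]:
    """Pooled-pixel precision/recall at each threshold plus trapezoidal area.

    Pixels from all images are pooled before counting (one curve per
    model/dataset). Predictions use the strict rule ``score > threshold``.
    The area is integrated over recall with an anchor at recall 0 carrying
    the precision of the most conservative defined point.
    """
    if len(score_maps) == 0 or len(score_maps) != len(gt_masks):
        raise ValueError("need equally many nonempty score maps and masks")
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    scores = np.concatenate([np.asarray(m).ravel() for m in score_maps])
    gt = np.concatenate([np.asarray(m).ravel().astype(bool) for m in gt_masks])
    n_pos = int(gt.sum())
    if n_pos == 0:
        raise ValueError("ground truth contains no positive pixels")
    points = []
    for t in thresholds:
        pred = scores > t
        tp = int(np.count_nonzero(pred & gt))
        fp = int(np.count_nonzero(pred & ~gt))
        prec = _safe_div(tp, tp + fp)
        rec = tp / n_pos
        points.append({"threshold": float(t), "precision": prec, "recall": rec})
    defined = [(p["recall"], p["precision"]) for p in points if p["precision"] is not None]
    defined.sort()
    if defined:
        # anchor at recall 0 (precision of the lowest-recall defined point)
        rs = [0.0] + [r for r, _ in defined]
        ps = [defined[0][1]] + [p for _, p in defined]
        area = float(np.trapezoid(ps, rs))
    else:
        area = float("nan")
    return points, area


def aggregate_reports(reports: Sequence[MetricsReport]) -> dict[str, float | None]:
    """Per-image mean of each metric, skipping undefined entries."""
    out: dict[str, float | None] = {}
    for name in ("precision", "recall", "f1", "iou"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        out[name] = float(np.mean(vals)) if vals else None
    out["n_images"] = len(reports)
    return out


def pooled_pixel_metrics(pred_masks: Sequence[np.ndarray],
                         gt_masks: Sequence[np.ndarray]) -> MetricsReport:
    """Alternative aggregation: pool pixel counts across all images."""
    tp = fp = fn = tn = 0
    for pm, gm in zip(pred_masks, gt_masks, strict=True):
        r = pixel_metrics(pm, gm)
        tp += r.counts.tp
        fp += r.counts.fp
        fn += r.counts.fn
        tn += r.counts.tn
    return report_from_counts(ConfusionCounts(tp, fp, fn, tn), "pixel",
                              tp + fp + fn + tn)
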