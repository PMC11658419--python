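"""Segmentation-quality metrics: SEG and DET.

SEG: each ground-truth object is matched to the (at most one) predicted
object covering strictly more than half of its voxels; SEG is the mean
Jaccard index over all ground-truth objects, counting unmatched ones as 0.

DET: normalized detection graph-edit cost. With the same >50% coverage
matching, AOGM-D = 10*FN + 1*FP + 5*NS, where FN are unmatched ground-truth
objects, FP are predicted objects matched to no ground-truth object, and NS
counts the split operations for predicted objects matched to two or more
ground-truth objects. DET = 1 - min(AOGM-D, AOGM-D0)/AOGM-D0 with
AOGM-D0 = 10 * (number of ground-truth objects), the cost of building the
detection from nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import LabelVolume

__all__ = ["SegEvalResult", "evaluate_segmentation", "seg_score", "det_score"]

W_FN, W_FP, W_NS = 10.0, 1.0, 5.0


@dataclass
class SegEvalResult:
    seg: float
    det: float
    # one row per GT object: (gt id, matched pred id or None, jaccard)
    matches: list[tuple[int, int | None, float]]
    n_false_negative: int
    n_false_positive: int
    n_split: int


def _as_array(labels) -> np.ndarray:
    return labels.labels if isinstance(labels, LabelVolume) else np.asarray(labels)


def _overlap_counts(gt: np.ndarray, pred: np.ndarray):
    """Sparse voxel-overlap counts between positive gt and all pred ids."""
    m = gt > 0
    g = gt[m].astype(np.int64)
    p = pred[m].astype(np.int64)
    stride = int(pred.max()) + 1
    pairs, counts = np.unique(g * stride + p, return_counts=True)
    return pairs // stride, pairs % stride, counts


def evaluate_segmentation(gt, pred) -> SegEvalResult:
    gt = _as_array(gt)
    pred = _as_array(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    gt_ids, gt_sizes = np.unique(gt[gt > 0], return_counts=True)
    if gt_ids.size == 0:
        raise ValueError("ground truth contains no objects")
    gt_size = dict(zip(gt_ids.tolist(), gt_sizes.tolist()))
    pred_ids, pred_sizes = np.unique(pred[pred > 0], return_counts=True)
    pred_size = dict(zip(pred_ids.tolist(), pred_sizes.tolist()))

    og, op, ov = _overlap_counts(gt, pred)
    # match: pred object covering > 50% of the GT object's voxels
    match: dict[int, tuple[int, float]] = {}
    matched_per_pred: dict[int, int] = {}
    for g, p, n in zip(og.tolist(), op.tolist(), ov.tolist()):
        if p == 0:
            continue
        if n * 2 > gt_size[g]:
            jac = n / (gt_size[g] + pred_size[p] - n)
            match[g] = (p, jac)
            matched_per_pred[p] = matched_per_pred.get(p, 0) + 1

    matches = []
    jaccards = []
    for g in gt_ids.tolist():
        if g in match:
            p, jac = match[g]
            matches.append((g, p, jac))
            jaccards.append(jac)
        else:
            matches.append((g, None, 0.0))
            jaccards.append(0.0)
    seg = float(np.mean(jaccards))

    fn = sum(1 for g in gt_ids.tolist() if g not in match)
    fp = sum(1 for p in pred_ids.tolist() if p not in matched_per_pred)
    ns = sum(max(0, k - 1) for k in matched_per_pred.values())
    aogm_d = W_FN * fn + W_FP * fp + W_NS * ns
    aogm_d0 = W_FN * len(gt_ids)
    det = 1.0 - min(aogm_d, aogm_d0) / aogm_d0
    return SegEvalResult(
        seg=seg, det=float(det), matches=matches,
        n_false_negative=fn, n_false_positive=fp, n_split=ns,
    )


def seg_score(gt, pred) -> float:
    return evaluate_segmentation(gt, pred).seg


def det_score(gt, pred) -> float:
    return evaluate_segmentation(gt, pred).det
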