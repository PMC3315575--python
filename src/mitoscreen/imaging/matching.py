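"""Label-mask matching utilities for segmentation validation."""

from __future__ import annotations

import numpy as np

__all__ = ["match_labels", "matched_fraction"]


def match_labels(truth: np.ndarray, pred: np.ndarray, iou_threshold: float = 0.7):
    """Greedy 1-1 matching of truth and predicted labels by IoU.

    Returns a list of (truth_label, pred_label, iou) sorted by descending IoU;
    each label appears in at most one pair and all pairs meet the threshold.
    """
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if truth.shape != pred.shape:
        raise ValueError("masks must share a shape")
    tmax, pmax = int(truth.max()), int(pred.max())
    if tmax == 0 or pmax == 0:
        return []
    # contingency table of overlaps via a single bincount
    joint = truth.astype(np.int64) * (pmax + 1) + pred.astype(np.int64)
    counts = np.bincount(joint, minlength=(tmax + 1) * (pmax + 1))
    counts = counts.reshape(tmax + 1, pmax + 1)
    t_area = counts.sum(axis=1)
    p_area = counts.sum(axis=0)
    inter = counts[1:, 1:]
    union = t_area[1:, None] + p_area[None, 1:] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)

    pairs = []
    order = np.argsort(iou, axis=None)[::-1]
    used_t: set[int] = set()
    used_p: set[int] = set()
    for flat in order:
        ti, pi = np.unravel_index(flat, iou.shape)
        v = iou[ti, pi]
        if v < iou_threshold:
            break
        tl, pl = int(ti) + 1, int(pi) + 1
        if t_area[tl] == 0 or p_area[pl] == 0:
            continue
        if tl in used_t or pl in used_p:
            continue
        used_t.add(tl)
        used_p.add(pl)
        pairs.append((tl, pl, float(v)))
    return pairs


def matched_fraction(truth: np.ndarray, pred: np.ndarray, iou_threshold: float = 0.7) -> float:
    """Fraction of ground-truth cells with a 1-1 predicted match at the IoU cut."""
    truth = np.asarray(truth)
    t_labels = np.unique(truth[truth > 0])
    if t_labels.size == 0:
        return float("nan")
    pairs = match_labels(truth, pred, iou_threshold)
    return len(pairs) / t_labels.size
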