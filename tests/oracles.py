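"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plain per-pixel loops over small grids and
deliberately shares no code path with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def brute_confusion(pred, truth, num_classes):
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            cm[truth[i, j], pred[i, j]] += 1
    return cm


def brute_binary_counts(pred, truth, c):
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j] == c, truth[i, j] == c
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif t and not p:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def _safe(num, den, absent_both):
    if den == 0:
        return 1.0 if absent_both else 0.0
    return num / den


def brute_class_metrics(pred, truth, c):
    """dice, jaccard, sensitivity, specificity, ppv, npv for one class."""
    tp, fp, fn, tn = brute_binary_counts(pred, truth, c)
    absent = (tp + fn == 0) and (tp + fp == 0)
    return {
        "dice": _safe(2 * tp, 2 * tp + fp + fn, absent),
        "jaccard": _safe(tp, tp + fp + fn, absent),
        "sensitivity": _safe(tp, tp + fn, absent),
        "specificity": _safe(tn, tn + fp, absent),
        "ppv": _safe(tp, tp + fp, absent),
        "npv": _safe(tn, tn + fn, absent),
    }


def brute_dataset_metrics(pred, truth, num_classes):
    """global accuracy, mean accuracy, mean IoU, weighted IoU by direct counting."""
    total = pred.size
    correct = int((pred == truth).sum())
    recalls, ious, weighted = [], [], 0.0
    for c in range(num_classes):
        tp, fp, fn, tn = brute_binary_counts(pred, truth, c)
        absent = (tp + fn == 0) and (tp + fp == 0)
        recalls.append(_safe(tp, tp + fn, absent))
        iou = _safe(tp, tp + fp + fn, absent)
        ious.append(iou)
        weighted += (tp + fn) / total * iou
    return correct / total, float(np.mean(recalls)), float(np.mean(ious)), weighted


def brute_boundary(mask, c):
    """Boundary pixels of class c: 4-neighbor (or image edge) outside class c."""
    h, w = mask.shape
    pts = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] != c:
                continue
            edge = False
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or mask[ni, nj] != c:
                    edge = True
                    break
            if edge:
                pts.append((i, j))
    return pts


def brute_bf_score(pred, truth, c, tolerance):
    """All-pairs boundary-distance boundary F1."""
    bp = brute_boundary(pred, c)
    bt = brute_boundary(truth, c)
    if not bp and not bt:
        return 1.0
    if not bp or not bt:
        return 0.0

    def matched(points, others):
        hits = 0
        for (i, j) in points:
            if min(math.hypot(i - oi, j - oj) for (oi, oj) in others) <= tolerance:
                hits += 1
        return hits / len(points)

    precision = matched(bp, bt)
    recall = matched(bt, bp)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def brute_rescale(matrix, lo, hi):
    """Per-pixel half-up linear rescale to [0, 255]."""
    out = np.zeros(matrix.shape, dtype=np.uint8)
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            v = 255.0 * (matrix[i, j] - lo) / (hi - lo)
            v = min(max(v, 0.0), 255.0)
            out[i, j] = int(math.floor(v + 0.5))
    return out


def brute_accuracy(probs, target):
    """Percent of pixels where the max-probability channel equals the target."""
    n, c, h, w = probs.shape
    hits = 0
    for b in range(n):
        for i in range(h):
            for j in range(w):
                best, best_c = -1.0, 0
                for k in range(c):
                    if probs[b, k, i, j] > best:
                        best, best_c = probs[b, k, i, j], k
                hits += best_c == target[b, i, j]
    return 100.0 * hits / (n * h * w)
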