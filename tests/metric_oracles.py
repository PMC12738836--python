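"""From-formula metric implementations, independent of the package's
evaluation path, used to cross-check the metric suite."""

import numpy as np


def confusion(y_true, y_pred):
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[t, p] += 1
    return cm


def mcc_from_counts(y_true, y_pred):
    cm = confusion(y_true, y_pred)
    tn, fp, fn, tp = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / denom


def weighted_f1(y_true, y_pred):
    total = len(y_true)
    out = 0.0
    for c in (0, 1):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out += f1 * sum(1 for t in y_true if t == c) / total
    return out


def auc_pairwise(y_true, scores):
    """ROC-AUC by direct pairwise comparison counting (ties count half)."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def average_precision_step(y_true, scores):
    """AP by step-wise integration of the precision-recall curve:
    sum over ranks of (recall_i - recall_{i-1}) * precision_i."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    order = np.argsort(-scores, kind="mergesort")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    n_pos = y_sorted.sum()
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(y_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:  # process score ties together
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += int((1 - y_sorted[i:j]).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap
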