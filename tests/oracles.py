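"""Independent brute-force oracles shared across test modules."""

import numpy as np


def mann_whitney_auroc(labels, scores):
    """Exhaustive rank oracle: fraction of (positive, negative) score pairs
    that are concordant, counting ties as 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_confusion(labels, scores, threshold):
    """Count TP/TN/FP/FN one example at a time."""
    tp = tn = fp = fn = 0
    for y, s in zip(labels, scores):
        pred = s >= threshold
        if y == 1 and pred:
            tp += 1
        elif y == 1:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn
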