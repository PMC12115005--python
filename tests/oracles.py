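"""Independent brute-force oracles used to validate the package's primitives.

Everything here is deliberately written in the most literal way possible
(explicit loops, exhaustive search) and shares no code with the
implementations it checks.
"""

import numpy as np

import surgloc as sl


def brute_force_otsu(gray):
    """Exhaustive search over all 256 thresholds for max between-class variance.

    Uses exact rational arithmetic (``fractions.Fraction``) so that true
    mathematical ties break toward the smallest threshold rather than on
    floating-point rounding.
    """
    from fractions import Fraction

    hist = np.bincount(gray.ravel(), minlength=256)
    n = int(hist.sum())
    best_t, best_var = None, Fraction(-1)
    for t in range(256):
        w0 = int(hist[: t + 1].sum())
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = Fraction(int((hist[: t + 1] * np.arange(t + 1)).sum()), w0)
        mu1 = Fraction(int((hist[t + 1 :] * np.arange(t + 1, 256)).sum()), w1)
        var = Fraction(w0 * w1, n * n) * (mu0 - mu1) ** 2
        if var > best_var:  # strict improvement: ties keep the smallest t
            best_var, best_t = var, t
    return best_t


def brute_force_nms(dets, thr):
    """Greedy suppression oracle; tie-break by confidence, area, input order."""
    pool = list(enumerate(dets))
    kept = []
    while pool:
        pool.sort(key=lambda t: (-t[1].confidence, -t[1].area, t[0]))
        idx, best = pool.pop(0)
        kept.append(best)
        pool = [(i, d) for i, d in pool if sl.iou(d.box, best.box) <= thr]
    return kept


def brute_force_ap(scores, labels):
    """Recompute precision/recall at every rank from scratch."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    n_pos = y.sum()
    ap = 0.0
    prev_recall = 0.0
    tp = 0
    for k, yk in enumerate(y, start=1):
        tp += yk
        precision = tp / k
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def naive_bce(logits, targets, weights):
    """Direct-formula loss oracle: -(y log p + (1-y) log(1-p)) summed with weights."""
    p = 1.0 / (1.0 + np.exp(-np.asarray(logits, dtype=float)))
    y = np.asarray(targets, dtype=float)
    return float(np.sum(np.asarray(weights) * -(y * np.log(p) + (1 - y) * np.log(1 - p))))


def random_detections(rng, n, span=40, max_side=25):
    dets = []
    for _ in range(n):
        x0, y0 = rng.integers(0, span, size=2)
        w, h = rng.integers(1, max_side, size=2)
        dets.append(
            sl.Detection(0, (int(x0), int(y0), int(x0 + w), int(y0 + h)), float(rng.random()))
        )
    return dets
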