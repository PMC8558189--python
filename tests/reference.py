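"""Independent reference implementations used as test oracles.

Deliberately naive, per-sample / per-fold code with no shared logic with the
package: plain Python loops, explicit arithmetic, itertools enumeration.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def naive_run_channel(signal, n=6, mu=1.0, eps=1.0, bias=1.0, reduction="max"):
    """Per-sample NLMS + novelty reference: returns (weights_at_k, errors, c)."""
    y = [float(v) for v in signal]
    m = len(y)
    p = n + 1
    w = [0.0] * p
    errors = [0.0] * m
    c = [0.0] * m
    weights = [[0.0] * p for _ in range(m)]
    for k in range(n, m):
        x = [bias] + [y[k - 1 - i] for i in range(n)]
        yhat = 0.0
        xx = 0.0
        for i in range(p):
            yhat += w[i] * x[i]
            xx += x[i] * x[i]
        e = y[k] - yhat
        eta = mu / (eps + xx)
        weights[k] = list(w)
        errors[k] = e
        cs = []
        for i in range(p):
            dwi = eta * e * x[i]
            cs.append(abs(e * dwi))
            w[i] += dwi
        c[k] = max(cs) if reduction == "max" else sum(cs) / p
    return np.array(weights), np.array(errors), np.array(c)


def brute_force_lpo(values, is_positive, p):
    """Exhaustive leave-p-out midpoint-threshold CV by direct enumeration.

    Returns pooled (tp, fn, tn, fp, n_folds, n_skipped).
    """
    values = list(map(float, values))
    is_positive = list(map(bool, is_positive))
    n = len(values)
    tp = fn = tn = fp = folds = skipped = 0
    for held in combinations(range(n), p):
        train = [i for i in range(n) if i not in held]
        pos = [values[i] for i in train if is_positive[i]]
        neg = [values[i] for i in train if not is_positive[i]]
        if not pos or not neg:
            skipped += 1
            continue
        folds += 1
        crit = 0.5 * (sum(pos) / len(pos) + sum(neg) / len(neg))
        for i in held:
            pred_pos = values[i] > crit
            if is_positive[i]:
                tp += pred_pos
                fn += not pred_pos
            else:
                fp += pred_pos
                tn += not pred_pos
    return tp, fn, tn, fp, folds, skipped


def normal_equations_line(y):
    """Least-squares line fit by explicit normal equations; returns fitted line."""
    y = np.asarray(y, dtype=float)
    k = np.arange(y.size, dtype=float)
    n = y.size
    sk, sk2, sy, sky = k.sum(), (k * k).sum(), y.sum(), (k * y).sum()
    det = n * sk2 - sk * sk
    b = (n * sky - sk * sy) / det
    a = (sy - b * sk) / n
    return a + b * k


def two_pass_std(values):
    """Population standard deviation by explicit two-pass summation."""
    values = [float(v) for v in values]
    m = sum(values) / len(values)
    return (sum((v - m) ** 2 for v in values) / len(values)) ** 0.5
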