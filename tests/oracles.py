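"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from its definition with naive loops /
direct sums, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def direct_moments(x):
    """(mean, sample std, kurtosis) by direct summation of the defining sums."""
    n = len(x)
    mean = sum(x) / n
    ss = sum((v - mean) ** 2 for v in x)
    std = math.sqrt(ss / (n - 1))
    m2 = ss / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    kurt = m4 / m2**2 if m2 > 0 else 0.0
    return mean, std, kurt


def direct_quantile(x, q):
    """Linear-interpolation quantile from the sorted sample (h = (n-1)q)."""
    s = sorted(x)
    h = (len(s) - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def direct_dft_power(x):
    """One-sided power spectrum of the mean-removed signal by the O(N^2) DFT sum."""
    n = len(x)
    mean = sum(x) / n
    xc = [v - mean for v in x]
    bins = n // 2 + 1
    power = []
    for k in range(bins):
        s = sum(xc[t] * cmath.exp(-2j * math.pi * k * t / n) for t in range(n))
        power.append(abs(s) ** 2)
    return power


def brute_relieff(X, y, k):
    """Naive multiclass ReliefF: explicit loops over pivots and neighbours.

    Every instance is a pivot; Manhattan distance on range-normalised
    features; distance ties break by instance index; per-class neighbour
    counts clipped to availability.
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    n, p = X.shape
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0
    Xn = (X - lo) / rng

    classes = sorted(set(y))
    prior = {c: y.count(c) / n for c in classes}

    def dist(i, j):
        return sum(abs(Xn[i, f] - Xn[j, f]) for f in range(p))

    W = [0.0] * p
    for r in range(n):
        for c in classes:
            cand = [i for i in range(n) if i != r and y[i] == c]
            cand.sort(key=lambda i: (dist(r, i), i))
            nbrs = cand[: min(k, len(cand))]
            for f in range(p):
                d = sum(abs(Xn[r, f] - Xn[i, f]) for i in nbrs)
                if c == y[r]:
                    W[f] -= d / (n * len(nbrs))
                else:
                    W[f] += prior[c] / (1 - prior[y[r]]) * d / (n * len(nbrs))
    return np.array(W)


def instance_level_metrics(truth, pred, classes):
    """Per-class TP/FP/FN/TN by enumerating instances, then the metric ratios."""
    out = {}
    n = len(truth)
    for c in classes:
        tp = sum(1 for t, p in zip(truth, pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(truth, pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(truth, pred) if t == c and p != c)
        tn = n - tp - fp - fn
        out[c] = {
            "precision": tp / (tp + fp) if tp + fp else None,
            "recall": tp / (tp + fn) if tp + fn else None,
            "specificity": tn / (tn + fp) if tn + fp else None,
        }
        pr, rc = out[c]["precision"], out[c]["recall"]
        out[c]["f_score"] = (
            2 * pr * rc / (pr + rc) if pr is not None and rc is not None
            and (pr + rc) > 0 else None
        )
    return out


def enumerate_window_count(n_samples, length, hop):
    """Count window start positions by explicit enumeration."""
    count = 0
    start = 0
    while start + length <= n_samples:
        count += 1
        start += hop
    return count
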