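"""Independent brute-force reference implementations used as test oracles.

These deliberately use plain Python loops / direct formula transcription
and never call into :mod:`hybci`, so they stay independent of the code
paths they check.
"""

import math

import numpy as np


def brute_features(x, fs=1.0):
    """The 7 statistics (mean, max, slope, var, skew, kurt, median) by direct sums."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    mx = max(x)
    # least-squares slope against t = k / fs
    t = [k / fs for k in range(n)]
    tbar = sum(t) / n
    slope = sum((ti - tbar) * (xi - mean) for ti, xi in zip(t, x)) / \
        sum((ti - tbar) ** 2 for ti in t)
    var = sum((xi - mean) ** 2 for xi in x) / (n - 1)
    m2 = sum((xi - mean) ** 2 for xi in x) / n
    m3 = sum((xi - mean) ** 3 for xi in x) / n
    m4 = sum((xi - mean) ** 4 for xi in x) / n
    skew = 0.0 if m2 == 0 else m3 / m2 ** 1.5
    kurt = 0.0 if m2 == 0 else m4 / m2 ** 2
    xs = sorted(x)
    med = xs[n // 2] if n % 2 else 0.5 * (xs[n // 2 - 1] + xs[n // 2])
    return np.array([mean, mx, slope, var, skew, kurt, med])


def min_sse_bipartition_1d(points):
    """Exhaustive minimum-SSE 2-cluster split of a 1-D point set.

    The optimal 2-means partition in 1-D is contiguous in sorted order, so
    all threshold splits are enumerated.
    """
    xs = sorted(map(float, points))
    n = len(xs)
    best = math.inf
    best_centers = None
    for split in range(1, n):
        left, right = xs[:split], xs[split:]
        cl = sum(left) / len(left)
        cr = sum(right) / len(right)
        sse = sum((v - cl) ** 2 for v in left) + sum((v - cr) ** 2 for v in right)
        if sse < best:
            best = sse
            best_centers = (cl, cr)
    return best, best_centers


def min_sse_bipartition(points):
    """Exhaustive minimum-SSE 2-partition of at most ~15 points in any dimension."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    best = math.inf
    best_centers = None
    for mask in range(1, 2 ** (n - 1)):  # fix point 0 in cluster A
        sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        a, b = pts[~sel], pts[sel]
        if len(a) == 0 or len(b) == 0:
            continue
        ca, cb = a.mean(axis=0), b.mean(axis=0)
        sse = ((a - ca) ** 2).sum() + ((b - cb) ** 2).sum()
        if sse < best:
            best = sse
            best_centers = (ca, cb)
    return best, best_centers
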