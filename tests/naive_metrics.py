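"""Straight-loop reference implementations of the ten pair metrics.

Deliberately written as plain Python loops, independent of the package's
vectorized code paths, to serve as oracles in the tests.
"""

import math


def naive_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def _ranks(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def naive_spearman(x, y):
    return naive_pearson(_ranks(x), _ranks(y))


def naive_euclidean(x, y):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))


def naive_manhattan(x, y):
    return sum(abs(a - b) for a, b in zip(x, y))


def naive_chebyshev(x, y):
    return max(abs(a - b) for a, b in zip(x, y))


def naive_minkowski(x, y, p):
    return sum(abs(a - b) ** p for a, b in zip(x, y)) ** (1.0 / p)


def _binarize(x, cutoff):
    return [1 if v < cutoff else 0 for v in x]


def naive_dice(x, y, cutoff):
    a, b = _binarize(x, cutoff), _binarize(y, cutoff)
    inter = sum(1 for u, v in zip(a, b) if u and v)
    denom = sum(a) + sum(b)
    return 2.0 * inter / denom if denom else 0.0


def naive_jaccard(x, y, cutoff):
    a, b = _binarize(x, cutoff), _binarize(y, cutoff)
    inter = sum(1 for u, v in zip(a, b) if u and v)
    union = sum(1 for u, v in zip(a, b) if u or v)
    return inter / union if union else 0.0


def naive_harmonic_mean(x, y):
    p = [v - min(x) for v in x]
    q = [v - min(y) for v in y]
    sp, sq = sum(p), sum(q)
    if sp == 0 or sq == 0:
        return 0.0
    p = [v / sp for v in p]
    q = [v / sq for v in q]
    total = 0.0
    for a, b in zip(p, q):
        if a + b > 0:
            total += 2.0 * a * b / (a + b)
    return total


def _equal_freq_bins(x, bins):
    order = sorted(range(len(x)), key=lambda i: (x[i], i))
    assignment = [0] * len(x)
    for rank, idx in enumerate(order):
        assignment[idx] = (rank * bins) // len(x)
    return assignment


def naive_mutual_information(x, y, bins):
    a = _equal_freq_bins(x, bins)
    b = _equal_freq_bins(y, bins)
    n = len(x)
    joint = {}
    for u, v in zip(a, b):
        joint[(u, v)] = joint.get((u, v), 0) + 1
    pa = {}
    pb = {}
    for u, v in zip(a, b):
        pa[u] = pa.get(u, 0) + 1
        pb[v] = pb.get(v, 0) + 1
    mi = 0.0
    for (u, v), c in joint.items():
        pj = c / n
        mi += pj * math.log2(pj / ((pa[u] / n) * (pb[v] / n)))
    return mi


def naive_metric(name, x, y, params):
    """Dispatch matching cofitnet.features.compute_metric's signature."""
    if name == "pearson":
        return naive_pearson(x, y)
    if name == "spearman":
        return naive_spearman(x, y)
    if name == "euclidean":
        return naive_euclidean(x, y)
    if name == "manhattan":
        return naive_manhattan(x, y)
    if name == "chebyshev":
        return naive_chebyshev(x, y)
    if name == "minkowski":
        return naive_minkowski(x, y, params.minkowski_order)
    if name == "dice":
        return naive_dice(x, y, params.binarize_cutoff)
    if name == "jaccard":
        return naive_jaccard(x, y, params.binarize_cutoff)
    if name == "harmonic_mean":
        return naive_harmonic_mean(x, y)
    if name == "mutual_information":
        return naive_mutual_information(x, y, params.mi_bins)
    raise ValueError(name)
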