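"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive each quantity from first principles (exact
rational arithmetic, exhaustive enumeration, step-by-step recomputation) and
share no code with the implementations they check.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def hypergeom_upper_tail_exact(k, K, n, N) -> Fraction:
    """P(X >= k) as an exact rational via direct enumeration."""
    total = comb(N, n)
    num = 0
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        num += comb(K, i) * comb(N - K, n - i)
    return Fraction(num, total)


def segmentation_best_cost(values, penalty) -> float:
    """Exhaustive minimum of SSE + penalty * n_segments over all
    segmentations (every subset of the n-1 possible change points)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    best = np.inf
    for r in range(n):
        for cuts in combinations(range(1, n), r):
            bounds = [0, *cuts, n]
            cost = penalty * (len(bounds) - 1)
            for a, b in zip(bounds, bounds[1:]):
                seg = x[a:b]
                cost += float(np.sum((seg - seg.mean()) ** 2))
            if cost < best:
                best = cost
    return best


def _tie_key(min_labels, a, b):
    return tuple(sorted((min_labels[a], min_labels[b])))


def agglomerate_bruteforce(d, labels, method):
    """Reference agglomeration that recomputes every inter-cluster distance
    from the original leaf matrix at every step (no incremental updates).

    Returns a list of merges as (leaf-label frozenset, leaf-label frozenset,
    height) with the same tie rule as the implementation: minimal distance,
    then lexicographic (min label, min label).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            pairs = [(i, j) for i in clusters[a] for j in clusters[b]]
            if method == "average":
                dist = sum(d[i, j] for i, j in pairs) / len(pairs)
            else:
                dist = max(d[i, j] for i, j in pairs)
            la = min(labels[i] for i in clusters[a])
            lb = min(labels[i] for i in clusters[b])
            key = (dist, tuple(sorted((la, lb))))
            if best is None or key < best[0]:
                best = (key, a, b, dist)
        _, a, b, dist = best
        height = dist / 2.0 if method == "average" else dist
        merged = clusters[a] | clusters[b]
        merges.append(
            (
                frozenset(labels[i] for i in clusters[a]),
                frozenset(labels[i] for i in clusters[b]),
                height,
            )
        )
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)]
        clusters.append(merged)
    return merges


def dendrogram_merge_sets(tree):
    """The implementation's merges as comparable (leafset, leafset, height)."""
    out = []
    for left, right, height in tree.merges:
        out.append(
            (
                frozenset(tree.labels[i] for i in tree.leaves_of(left)),
                frozenset(tree.labels[i] for i in tree.leaves_of(right)),
                height,
            )
        )
    return out


def merge_lists_equal(a, b, tol=1e-12):
    if len(a) != len(b):
        return False
    for (la, ra, ha), (lb, rb, hb) in zip(a, b):
        if {la, ra} != {lb, rb}:
            return False
        if abs(ha - hb) > tol:
            return False
    return True
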