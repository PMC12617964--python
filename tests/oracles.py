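"""Independent reference computations used to validate the implementation.

Everything here is deliberately naive — direct formulas, exhaustive
enumeration, brute-force recursion — and shares no code path with the
package.
"""

import itertools
import math

import numpy as np


def normal_equations(X, y):
    """Least-squares coefficients by solving the normal equations directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def average_ranks(values):
    """Tie-averaged ranks computed by explicit grouping."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return np.array(ranks)


def pearson(a, b):
    """Pearson correlation from its definition."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am @ bm) / math.sqrt((am @ am) * (bm @ bm)))


def spearman_rho(x, y):
    return pearson(average_ranks(x), average_ranks(y))


def kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H from the rank formula."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = average_ranks(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def kruskal_permutation_p(groups, h_observed):
    """Exact permutation p-value by enumerating all pooled orderings."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]
    count = total = 0
    for perm in itertools.permutations(pooled):
        regrouped, start = [], 0
        for s in sizes:
            regrouped.append(perm[start:start + s])
            start += s
        if kruskal_h(regrouped) >= h_observed - 1e-12:
            count += 1
        total += 1
    return count / total


def dtw_brute_force(x, y):
    """Minimal accumulated |x_i - y_j| over all admissible warping paths."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def rec(i, j):
        c = abs(x[i] - y[j])
        if i == 0 and j == 0:
            return c
        best = math.inf
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        return c + best

    return rec(len(x) - 1, len(y) - 1)
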