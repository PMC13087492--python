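"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (sets, loops, closed-form
formulas) and deliberately avoids the code paths it checks.
"""

import itertools
import math

import numpy as np


def set_jaccard(row_a, row_b) -> float:
    """Jaccard dissimilarity between two binary rows via python sets."""
    a = {i for i, v in enumerate(row_a) if v}
    b = {i for i, v in enumerate(row_b) if v}
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def lcbd_bruteforce(matrix) -> np.ndarray:
    """LCBD from the per-site sum-of-squares formula on the Gower-centred
    matrix of -D^2/2, with D the set-based Jaccard dissimilarity."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    A = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            d = set_jaccard(matrix[i], matrix[j])
            A[i, j] = -0.5 * d * d
    g = np.empty(n)
    for i in range(n):
        g[i] = A[i, i] - 2.0 / n * A[i].sum() + A.sum() / n ** 2
    return g / g.sum()


def tjur_bruteforce(y, p) -> float:
    ones = [pi for yi, pi in zip(y, p) if yi == 1]
    zeros = [pi for yi, pi in zip(y, p) if yi == 0]
    return sum(ones) / len(ones) - sum(zeros) / len(zeros)


def holm_bruteforce(pvals, alpha=0.05):
    """Classic Holm step-down: reject while p_(i) <= alpha / (m - i)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    reject = [False] * m
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def _ranks_average_ties(values):
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
    return ranks


def spearman_bruteforce(x, y):
    """Spearman rho (average ranks) and two-sided p via the t-approximation."""
    from scipy.stats import t as tdist

    rx = _ranks_average_ties(list(x))
    ry = _ranks_average_ties(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    rho = num / den
    if abs(rho) >= 1.0:
        return rho, 0.0
    tstat = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2.0 * tdist.sf(abs(tstat), n - 2)
    return rho, p


def shortest_paths_bruteforce(nodes, edges):
    """All-pairs unweighted shortest paths by Floyd-Warshall."""
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    INF = float("inf")
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for a, b in edges:
        d[idx[a]][idx[b]] = 1
        d[idx[b]][idx[a]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def mean_path_length_bruteforce(nodes, edges):
    d = shortest_paths_bruteforce(nodes, edges)
    finite = [v for row in d for v in row if 0 < v < float("inf")]
    return sum(finite) / len(finite)


def modularity_bruteforce(nodes, edges, partition):
    """Q = sum_c (e_c / m - (d_c / 2m)^2) for an unweighted graph."""
    m = len(edges)
    degree = {v: 0 for v in nodes}
    for a, b in edges:
        degree[a] += 1
        degree[b] += 1
    q = 0.0
    for comm in partition:
        e_c = sum(1 for a, b in edges if a in comm and b in comm)
        d_c = sum(degree[v] for v in comm)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1:]
        yield part + [{first}]


def max_modularity_bruteforce(nodes, edges):
    """Exhaustive search over all set partitions (use only for <= 8 nodes)."""
    best = -1.0
    for part in _set_partitions(list(nodes)):
        q = modularity_bruteforce(nodes, edges, part)
        if q > best:
            best = q
    return best
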