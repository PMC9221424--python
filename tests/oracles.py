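"""Brute-force reference implementations used only to check the library.

Each oracle is written in the most direct way possible (exhaustive
enumeration, pure Python) and shares no code with the implementations under
test.
"""

from __future__ import annotations

import itertools
import math


def rank_sum_exact_p(a: list[float], b: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every group assignment.

    For the pooled no-tie sample, every way of choosing which m of the m+n
    values belong to the first group is equally likely under the null. The
    two-sided p-value is the probability mass of assignments whose U lies at
    or beyond the observed U's distance from the extremes (equal-tail
    convention: P(U <= min(u, mn-u)) + P(U >= max(u, mn-u))).
    """
    m, n = len(a), len(b)
    pooled = list(a) + list(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    lo, hi = min(u_obs, m * n - u_obs), max(u_obs, m * n - u_obs)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(m + n), m):
        grp = set(idx)
        u = sum(1 for i in grp for j in range(m + n)
                if j not in grp and pooled[i] > pooled[j])
        total += 1
        if u <= lo or u >= hi:
            extreme += 1
    return extreme / total


def _midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _pearson(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)
                    * sum((b - my) ** 2 for b in y))
    return num / den


def spearman_perm_p(x: list[float], y: list[float]) -> tuple[float, float]:
    """(rho, two-sided permutation p) over all n! permutations of y's ranks."""
    rx = _midranks(list(x))
    ry = _midranks(list(y))
    rho = _pearson(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_pearson(rx, list(perm))) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total


def ward_merge_history(points: list[list[float]]) -> list[frozenset[int]]:
    """Greedy Ward agglomeration by direct minimization of the SSE increase.

    Merging clusters A and B increases the total within-cluster sum of
    squares by |A||B|/(|A|+|B|) * ||centroid(A) - centroid(B)||^2; at each
    step the pair with the smallest increase merges. Returns the member set
    of each newly formed cluster in merge order.
    """
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(len(points))]
    history: list[frozenset[int]] = []

    def centroid(members: frozenset[int]) -> list[float]:
        dims = len(points[0])
        return [sum(points[i][d] for i in members) / len(members)
                for d in range(dims)]

    while len(clusters) > 1:
        best = None
        best_cost = math.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ca, cb = centroid(clusters[i]), centroid(clusters[j])
                d2 = sum((u - v) ** 2 for u, v in zip(ca, cb))
                na, nb = len(clusters[i]), len(clusters[j])
                cost = na * nb / (na + nb) * d2
                if cost < best_cost:
                    best_cost = cost
                    best = (i, j)
        i, j = best
        merged = clusters[i] | clusters[j]
        history.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return history
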