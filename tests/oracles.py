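"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the code paths they validate: the
hypergeometric tail is computed by exhaustive enumeration of draws, the
BH adjustment by a direct transcription of the step-up formula, and
modularity by the O(n^2) double sum over node pairs.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def hypergeom_tail_enumerated(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws of n items from N.

    Items 0..K-1 are the successes; every subset of size n is equally
    likely, and we count those containing at least k successes.
    """
    hits = sum(
        1
        for draw in combinations(range(N), n)
        if sum(1 for x in draw if x < K) >= k
    )
    return hits / comb(N, n)


def bh_stepup(p_values: list[float]) -> list[float]:
    """BH adjusted p-values: q_(i) = min_{j>=i} p_(j) * m / j, input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def modularity_double_sum(graph, labels: dict) -> float:
    """Newman Q as (1/2m) * sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("undefined for edgeless graph")
    nodes = list(graph.nodes)
    deg = dict(graph.degree)
    q = 0.0
    for i in nodes:
        for j in nodes:
            if labels[i] != labels[j]:
                continue
            a_ij = 1.0 if graph.has_edge(i, j) and i != j else 0.0
            q += a_ij - deg[i] * deg[j] / (2.0 * m)
    return q / (2.0 * m)
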