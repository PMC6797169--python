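"""Independent brute-force oracles used to validate the statistics.

Everything here is written from first principles (explicit pair counting,
explicit rank averaging, explicit enumeration) and deliberately shares no
code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def brute_tau_b(x, y) -> float:
    """Kendall tau-b by O(n^2) concordant/discordant/tie pair counting."""
    n = len(x)
    assert n == len(y)
    concordant = discordant = ties_x = ties_y = ties_both = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_both += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif (dx > 0) == (dy > 0):
                concordant += 1
            else:
                discordant += 1
    n_pairs = n * (n - 1) // 2
    denom = math.sqrt(
        (n_pairs - ties_x - ties_both) * (n_pairs - ties_y - ties_both)
    )
    if denom == 0:
        raise ZeroDivisionError("tau-b undefined for a constant vector")
    return (concordant - discordant) / denom


def brute_tau_score(x, y) -> int:
    """Raw concordance score S = #concordant - #discordant."""
    s = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx != 0 and dy != 0:
                s += 1 if (dx > 0) == (dy > 0) else -1
    return s


def brute_exact_tau_p(x, y) -> float:
    """Two-sided exact p for tau by full enumeration of y permutations.

    Compares permutations on |S| (the denominator of tau-b is constant
    across permutations of y).
    """
    observed = abs(brute_tau_score(x, y))
    count = total = 0
    for perm in itertools.permutations(y):
        if abs(brute_tau_score(x, perm)) >= observed:
            count += 1
        total += 1
    return count / total


def hand_ranks(values):
    """Average ranks computed by explicit position counting."""
    ordered = sorted(values)
    first_position = {}
    for pos, v in enumerate(ordered, start=1):
        first_position.setdefault(v, []).append(pos)
    return [sum(first_position[v]) / len(first_position[v]) for v in values]


def kw_two_group_statistic(a, b) -> float:
    """Tie-corrected Kruskal-Wallis H for two groups via hand-ranked sums."""
    pooled = list(a) + list(b)
    n = len(pooled)
    ranks = hand_ranks(pooled)
    r_a = ranks[: len(a)]
    r_b = ranks[len(a):]
    grand_mean = (n + 1) / 2
    h = (12.0 / (n * (n + 1))) * (
        len(a) * (sum(r_a) / len(a) - grand_mean) ** 2
        + len(b) * (sum(r_b) / len(b) - grand_mean) ** 2
    )
    tie_counts = Counter(pooled)
    correction = 1.0 - sum(t**3 - t for t in tie_counts.values()) / (n**3 - n)
    if correction == 0:
        raise ZeroDivisionError("all values identical")
    return h / correction


def neighborhood_mean_scores(edges, scores):
    """(own score, mean neighbor score) per node, from an explicit edge list."""
    neighbors: dict = {}
    for u, v in edges:
        neighbors.setdefault(u, set()).add(v)
        neighbors.setdefault(v, set()).add(u)
    return {
        node: (scores[node], sum(scores[v] for v in nbrs) / len(nbrs))
        for node, nbrs in neighbors.items()
    }
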