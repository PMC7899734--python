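"""Independent shortest-path oracle: exhaustive simple-path enumeration.

Deliberately naive (depth-first enumeration of ALL simple directed paths
with exact rational lengths) and kept separate from the package's Dijkstra
route so the two can be compared on small random digraphs.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from dnetgaze import AOIState, IntervalNetwork


def enumerate_paths(net: IntervalNetwork, k: AOIState, l: AOIState) -> list[tuple[Fraction, tuple[AOIState, ...]]]:
    """All simple directed paths k -> l with their exact summed inverse-weight lengths."""
    counts = net.matrix.counts
    states = net.states
    idx = {s: i for i, s in enumerate(states)}
    out: list[tuple[Fraction, tuple[AOIState, ...]]] = []

    def dfs(node: AOIState, dist: Fraction, path: tuple[AOIState, ...]):
        if node == l:
            out.append((dist, path))
            return
        for nxt in states:
            w = int(counts[idx[node], idx[nxt]])
            if w > 0 and nxt not in path:
                dfs(nxt, dist + Fraction(1, w), path + (nxt,))

    dfs(k, Fraction(0), (k,))
    return out


def brute_shortest(net: IntervalNetwork, k: AOIState, l: AOIState):
    """(min distance or inf, #shortest paths, {intermediate: #shortest through it})."""
    paths = enumerate_paths(net, k, l)
    if not paths:
        return math.inf, 0, {s: 0 for s in net.states if s not in (k, l)}
    dmin = min(d for d, _ in paths)
    shortest = [p for d, p in paths if d == dmin]
    through = {
        s: sum(1 for p in shortest if s in p[1:-1]) for s in net.states if s not in (k, l)
    }
    return dmin, len(shortest), through


def brute_closeness(net: IntervalNetwork, j: AOIState) -> Fraction:
    total = Fraction(0)
    for k in net.states:
        if k == j:
            continue
        d, _, _ = brute_shortest(net, j, k)
        if d != math.inf and d > 0:
            total += 1 / d
    return total


def brute_betweenness(net: IntervalNetwork, j: AOIState) -> Fraction:
    total = Fraction(0)
    for k in net.states:
        if k == j:
            continue
        for l in net.states:
            if l in (j, k):
                continue
            _, n, through = brute_shortest(net, k, l)
            if n:
                total += Fraction(through[j], n)
    return total


def random_weight_matrix(rng: np.random.Generator, n_max: int = 6, w_max: int = 5) -> np.ndarray:
    n = int(rng.integers(2, n_max + 1))
    weights = rng.integers(0, w_max + 1, size=(n, n))
    np.fill_diagonal(weights, 0)
    return weights
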