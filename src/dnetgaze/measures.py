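"""Time-resolved AOI importance measures: indegree, closeness, betweenness.

The attention network of one interval is a weighted digraph whose edge
weight w_ij is the number of gaze transitions i -> j.  Distance between
AOIs is the *inverse* transition count, d_ij = 1/w_ij (no transitions means
no edge, i.e. infinite distance): frequently-linked AOIs are "close" in the
observer's scanning strategy.  On that distance the three measures are, per
interval t with vertex set of size m_t:

- indegree   I_j(t) = sum_k w_kj(t)            (direct attention received)
- closeness  C_j(t) = sum_{k != j} 1 / d*_jk(t)  (access to the rest of the
  network; unreachable AOIs contribute 0, the harmonic convention)
- betweenness B_j(t) = sum_{k != l, both != j} SP_klj(t) / SP_kl(t)
  (share of shortest attention routes brokered by j)

where d*_jk is the minimum over directed paths of summed edge distances,
SP_kl the number of distinct shortest k -> l paths and SP_klj those passing
through j as an intermediate.

Edge distances are unit fractions of small integers, so all shortest-path
arithmetic here uses exact rationals (``fractions.Fraction``): path-length
ties — which Eq-style betweenness must count, not break — are detected
exactly rather than within a float tolerance.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .network import DynamicNetwork, IntervalNetwork
from .states import AOIState

__all__ = [
    "edge_distance",
    "DistanceTable",
    "distance_table",
    "shortest_distances",
    "count_shortest_paths",
    "indegree",
    "outdegree",
    "closeness",
    "betweenness",
    "measure_table",
]


def edge_distance(weight: int) -> Fraction | float:
    """Inverse-transition-count distance: 1/w for w > 0, +inf for w = 0."""
    if weight < 0:
        raise ValueError("transition count must be non-negative")
    if weight == 0:
        return math.inf
    return Fraction(1, int(weight))


def _adjacency(net: IntervalNetwork) -> dict[AOIState, dict[AOIState, Fraction]]:
    adj: dict[AOIState, dict[AOIState, Fraction]] = {s: {} for s in net.states}
    counts = net.matrix.counts
    for i, src in enumerate(net.states):
        for j, dst in enumerate(net.states):
            w = int(counts[i, j])
            if w > 0 and src != dst:
                adj[src][dst] = Fraction(1, w)
    return adj


def _single_source(
    adj: dict[AOIState, dict[AOIState, Fraction]], source: AOIState
) -> tuple[dict[AOIState, Fraction], dict[AOIState, int]]:
    """Dijkstra from ``source``: exact distances and shortest-path counts.

    Returns (dist, sigma) over reachable vertices only; sigma[v] is the
    number of distinct shortest source->v paths, counted by accumulating
    over tight edges (dist[u] + l_uv == dist[v]) in settled order.
    """
    dist: dict[AOIState, Fraction] = {source: Fraction(0)}
    order: list[AOIState] = []
    heap: list[tuple[Fraction, int, AOIState]] = [(Fraction(0), 0, source)]
    tiebreak = 1
    settled: set[AOIState] = set()
    while heap:
        d, _, u = heapq.heappop(heap)
        if u in settled:
            continue
        settled.add(u)
        order.append(u)
        for v, length in adj[u].items():
            nd = d + length
            if v not in dist or nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, tiebreak, v))
                tiebreak += 1
    sigma: dict[AOIState, int] = {source: 1}
    for v in order:
        if v == source:
            continue
        sigma[v] = sum(
            sigma.get(u, 0)
            for u in dist
            if v in adj[u] and dist[u] + adj[u][v] == dist[v]
        )
    return dist, sigma


@dataclass(frozen=True)
class DistanceTable:
    """All-pairs exact shortest distances and shortest-path counts of one interval."""

    states: tuple[AOIState, ...]
    dist: dict[tuple[AOIState, AOIState], Fraction]  # finite entries only
    sigma: dict[tuple[AOIState, AOIState], int]  # shortest-path counts, reachable pairs

    def distance(self, j: AOIState, k: AOIState) -> Fraction | float:
        if j == k:
            return Fraction(0)
        return self.dist.get((j, k), math.inf)

    def n_shortest(self, k: AOIState, l: AOIState) -> int:
        return self.sigma.get((k, l), 0)

    def n_shortest_through(self, k: AOIState, l: AOIState, j: AOIState) -> int:
        """Shortest k->l paths passing through intermediate j (j != k, l)."""
        if j in (k, l):
            raise ValueError("intermediate must differ from the endpoints")
        d_kl = self.dist.get((k, l))
        d_kj = self.dist.get((k, j))
        d_jl = self.dist.get((j, l))
        if d_kl is None or d_kj is None or d_jl is None or d_kj + d_jl != d_kl:
            return 0
        return self.sigma[(k, j)] * self.sigma[(j, l)]


def distance_table(net: IntervalNetwork) -> DistanceTable:
    adj = _adjacency(net)
    dist: dict[tuple[AOIState, AOIState], Fraction] = {}
    sigma: dict[tuple[AOIState, AOIState], int] = {}
    for source in net.states:
        d, s = _single_source(adj, source)
        for v, dv in d.items():
            dist[(source, v)] = dv
            sigma[(source, v)] = s[v]
    return DistanceTable(net.states, dist, sigma)


def shortest_distances(net: IntervalNetwork, source: AOIState) -> dict[AOIState, Fraction | float]:
    """Minimum summed edge distance from ``source`` to every vertex (inf if unreachable)."""
    net.matrix.index_of(source)  # KeyError on unknown source
    d, _ = _single_source(_adjacency(net), source)
    return {v: d.get(v, math.inf) for v in net.states}


def count_shortest_paths(
    net: IntervalNetwork, k: AOIState, l: AOIState
) -> tuple[int, dict[AOIState, int]]:
    """Number of distinct shortest k->l paths, and counts through each intermediate.

    Returns (SP_kl, {j: SP_klj for intermediates j != k, l}).  Both are zero
    / an all-zero map when l is unreachable from k.
    """
    if k == l:
        raise ValueError("endpoints of a shortest-path query must differ")
    net.matrix.index_of(k)
    net.matrix.index_of(l)
    table = distance_table(net)
    through = {j: table.n_shortest_through(k, l, j) for j in net.states if j not in (k, l)}
    return table.n_shortest(k, l), through


def indegree(net: IntervalNetwork, j: AOIState) -> int:
    """Total transitions received by j: the column sum of the count matrix."""
    return int(net.matrix.counts[:, net.matrix.index_of(j)].sum())


def outdegree(net: IntervalNetwork, j: AOIState) -> int:
    """Total transitions emitted by j: the row sum of the count matrix."""
    return int(net.matrix.counts[net.matrix.index_of(j), :].sum())


def closeness(net: IntervalNetwork, j: AOIState, table: DistanceTable | None = None) -> float:
    """Sum over k != j of 1 / d*_jk; unreachable vertices contribute 0."""
    net.matrix.index_of(j)
    table = table if table is not None else distance_table(net)
    total = Fraction(0)
    for k in net.states:
        if k == j:
            continue
        d = table.dist.get((j, k))
        if d is not None and d > 0:
            total += 1 / d
    return float(total)


def betweenness(net: IntervalNetwork, j: AOIState, table: DistanceTable | None = None) -> float:
    """Fraction-weighted count of shortest paths between other pairs passing through j."""
    net.matrix.index_of(j)
    table = table if table is not None else distance_table(net)
    total = Fraction(0)
    for k in net.states:
        if k == j:
            continue
        for l in net.states:
            if l in (j, k):
                continue
            sp = table.n_shortest(k, l)
            if sp:
                total += Fraction(table.n_shortest_through(k, l, j), sp)
    return float(total)


def measure_table(dnet: DynamicNetwork) -> pd.DataFrame:
    """Tidy per-(interval, AOI) table of all measures, in deterministic order.

    Columns: interval, aoi, indegree, outdegree, closeness, betweenness,
    fixations, dwell_ms.  Rows are ordered by interval then canonical state.
    """
    rows = []
    for net in dnet:
        table = distance_table(net)
        for state in net.states:  # matrix states are already in canonical order
            rows.append(
                {
                    "interval": net.window.index,
                    "aoi": state.canonical,
                    "indegree": indegree(net, state),
                    "outdegree": outdegree(net, state),
                    "closeness": closeness(net, state, table),
                    "betweenness": betweenness(net, state, table),
                    "fixations": int(net.fix_counts.get(state, 0)),
                    "dwell_ms": float(net.dwell_totals.get(state, 0.0)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["interval", "aoi", "indegree", "outdegree", "closeness", "betweenness", "fixations", "dwell_ms"],
    )
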