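"""Importance measures against an exhaustive path-enumeration oracle.

Frozen expected values below were computed with the brute-force oracle in
``oracle_paths`` (exhaustive simple-path enumeration with exact rationals)
on the worked-example networks.
"""

import math
from fractions import Fraction

import numpy as np
import pytest

from dnetgaze import (
    AOIState,
    TimeWindow,
    assemble_dnet,
    betweenness,
    build_interval_network,
    closeness,
    count_shortest_paths,
    edge_distance,
    indegree,
    measure_table,
    outdegree,
    shortest_distances,
)
from dnetgaze.network import TransitionMatrix

from conftest import EXAMPLE_SEQUENCES, network_from_text, network_from_weights
from oracle_paths import brute_betweenness, brute_closeness, brute_shortest, random_weight_matrix

A, B, C, E = (AOIState(x) for x in "ABCE")


@pytest.fixture(scope="module")
def net1():
    return network_from_text(EXAMPLE_SEQUENCES[1])


class TestEdgeDistance:
    def test_inverse_of_count(self):
        assert edge_distance(3) == Fraction(1, 3)
        assert edge_distance(1) == 1

    def test_zero_count_means_no_edge(self):
        assert edge_distance(0) == math.inf

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            edge_distance(-1)


class TestShortestDistances:
    def test_two_hop_route_beats_direct_edge(self, net1):
        # B->E: direct edge weight 1 (distance 1) vs B->A->E (1/3 + 1/3)
        assert shortest_distances(net1, B)[E] == Fraction(2, 3)

    def test_single_direct_edge(self, net1):
        assert shortest_distances(net1, B)[A] == Fraction(1, 3)

    def test_composite_route(self, net1):
        assert shortest_distances(net1, B)[C] == Fraction(5, 6)  # B->A->C

    def test_source_distance_zero_and_unknown_source_rejected(self, net1):
        assert shortest_distances(net1, A)[A] == 0
        with pytest.raises(KeyError):
            shortest_distances(net1, AOIState("Z"))

    def test_unreachable_is_infinite(self):
        net = network_from_weights("AB", [[0, 1], [0, 0]])
        assert shortest_distances(net, B)[A] == math.inf


class TestCountShortestPaths:
    def test_parallel_tied_routes_both_counted(self):
        # A->D directly costs 1; A->B->D and A->C->D each cost 1/2+1/2 = 1: tie
        weights = np.array([
            [0, 2, 2, 0],
            [0, 0, 0, 2],
            [0, 0, 0, 2],
            [0, 0, 0, 0],
        ])
        net = network_from_weights("ABCD", weights)
        sp, through = count_shortest_paths(net, AOIState("A"), AOIState("D"))
        assert sp == 2
        assert through[AOIState("B")] == 1 and through[AOIState("C")] == 1

    def test_unique_route_through_intermediate(self, net1):
        sp, through = count_shortest_paths(net1, E, C)
        assert sp == 1
        assert through[A] == 1

    def test_unreachable_pair(self):
        net = network_from_weights("AB", [[0, 1], [0, 0]])
        sp, through = count_shortest_paths(net, B, A)
        assert sp == 0 and all(v == 0 for v in through.values())

    def test_identical_endpoints_rejected(self, net1):
        with pytest.raises(ValueError):
            count_shortest_paths(net1, A, A)


class TestDegrees:
    def test_indegree_is_column_sum(self, net1):
        assert indegree(net1, B) == 4

    def test_indegree_changes_across_intervals(self):
        assert indegree(network_from_text(EXAMPLE_SEQUENCES[2]), B) == 3

    def test_outdegree_is_row_sum(self, net1):
        assert outdegree(net1, A) == 8
        assert indegree(net1, A) == 8  # closed walk: balanced

    def test_isolated_vertex_degrees_zero(self):
        net = network_from_weights("AB", [[0, 0], [0, 0]])
        assert indegree(net, A) == 0 and outdegree(net, A) == 0

    def test_degree_sums_conserve_transition_total(self, net1):
        total = net1.matrix.total
        assert sum(indegree(net1, s) for s in net1.states) == total
        assert sum(outdegree(net1, s) for s in net1.states) == total


class TestCloseness:
    def test_worked_network_values(self, net1):
        assert closeness(net1, A) == pytest.approx(8.0)  # 3 + 2 + 3
        assert closeness(net1, B) == pytest.approx(5.7)  # 3 + 6/5 + 3/2

    def test_matches_oracle_on_worked_network(self, net1):
        for s in net1.states:
            assert closeness(net1, s) == pytest.approx(float(brute_closeness(net1, s)))

    def test_isolated_vertex_is_zero(self):
        net = network_from_weights("ABC", [[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        assert closeness(net, AOIState("C")) == 0.0


class TestBetweenness:
    def test_directed_star_closed_form(self):
        # center X, peripherals only reachable through X: B(X) = p(p-1)
        p = 4
        weights = np.zeros((p + 1, p + 1), dtype=int)
        weights[0, 1:] = 1
        weights[1:, 0] = 1
        net = network_from_weights("XABCD", weights)
        assert betweenness(net, AOIState("X")) == p * (p - 1)

    def test_worked_network_values(self, net1):
        assert betweenness(net1, A) == pytest.approx(6.0)
        assert betweenness(net1, B) == pytest.approx(0.0)

    def test_bounded_by_ordered_pair_count(self, example_dnet):
        for net in example_dnet:
            m = len(net.states)
            for s in net.states:
                assert 0 <= betweenness(net, s) <= (m - 1) * (m - 2)


class TestOracleEquivalence:
    """Dijkstra + tight-edge counting vs exhaustive simple-path enumeration."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_digraphs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        for _ in range(10):
            weights = random_weight_matrix(rng)
            net = network_from_weights("ABCDEF"[: weights.shape[0]], weights)
            for k in net.states:
                dist = shortest_distances(net, k)
                for l in net.states:
                    if k == l:
                        continue
                    d_brute, n_brute, through_brute = brute_shortest(net, k, l)
                    assert dist[l] == d_brute
                    sp, through = count_shortest_paths(net, k, l)
                    assert sp == n_brute
                    assert through == through_brute

    @pytest.mark.parametrize("seed", range(4))
    def test_measures_match_oracle(self, seed):
        rng = np.random.default_rng(2000 + seed)
        weights = random_weight_matrix(rng)
        net = network_from_weights("ABCDEF"[: weights.shape[0]], weights)
        for s in net.states:
            assert closeness(net, s) == pytest.approx(float(brute_closeness(net, s)))
            assert betweenness(net, s) == pytest.approx(float(brute_betweenness(net, s)))


class TestStructuralProperties:
    def test_adding_isolated_vertex_changes_nothing(self, net1):
        m = net1.matrix
        bigger = TransitionMatrix(
            m.states + (AOIState("Z"),),
            np.pad(m.counts, ((0, 1), (0, 1))),
        )
        net2 = build_interval_network(bigger, window=net1.window)
        for s in m.states:
            assert closeness(net2, s) == closeness(net1, s)
            assert betweenness(net2, s) == betweenness(net1, s)
            assert indegree(net2, s) == indegree(net1, s)

    def test_weight_scaling_homogeneity(self, net1):
        # d -> d/c scales closeness by c and leaves betweenness unchanged
        c = 3
        scaled = build_interval_network(
            TransitionMatrix(net1.matrix.states, net1.matrix.counts * c), window=net1.window
        )
        for s in net1.states:
            assert closeness(scaled, s) == pytest.approx(c * closeness(net1, s))
            assert betweenness(scaled, s) == pytest.approx(betweenness(net1, s))


class TestMeasureTable:
    def test_one_record_per_interval_vertex(self, example_dnet):
        table = measure_table(example_dnet)
        assert sorted(table["interval"].unique()) == [1, 2, 3, 4]
        for net in example_dnet:
            sub = table[table["interval"] == net.window.index]
            assert list(sub["aoi"]) == [s.canonical for s in net.states]

    def test_single_vertex_network(self):
        net = network_from_text("A")
        table = measure_table(assemble_dnet([net]))
        row = table.iloc[0]
        assert (row["indegree"], row["closeness"], row["betweenness"]) == (0, 0.0, 0.0)
        assert row["fixations"] == 1

    def test_deterministic_ordering(self, example_dnet):
        t1 = measure_table(example_dnet)
        t2 = measure_table(example_dnet)
        assert t1.equals(t2)
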