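"""Node-level statistics: degrees, eccentricity, betweenness, path occurrence."""

from __future__ import annotations

import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aopnet import (
    AopnetError,
    ConvergenceClass,
    EccentricityBand,
    PathExplosionError,
    band_eccentricity,
    betweenness,
    build_network,
    classify_convergence,
    degrees,
    directed_eccentricity,
    enumerate_mie_ao_paths,
    generate_collection,
    GeneratorConfig,
    ke_sharing,
    path_occurrence,
    simple_paths_between,
    summarise,
    woe_distribution,
)
from aopnet.metrics import round_half_away
from conftest import collection_from_rows
from oracles import brute_betweenness, brute_simple_paths, random_digraph


def digraph(*edges: tuple[str, str]) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return g


DIAMOND = (("M", "A"), ("M", "B"), ("A", "Z"), ("B", "Z"))


class TestDegrees:
    def test_linear_chain(self):
        g = digraph(("M", "K"), ("K", "A"))
        assert degrees(g) == {
            "M": (0, 1, 1),
            "K": (1, 1, 2),
            "A": (1, 0, 1),
        }

    def test_diamond(self):
        d = degrees(digraph(*DIAMOND))
        assert d["M"] == (0, 2, 2)
        assert d["Z"] == (2, 0, 2)
        assert d["A"] == (1, 1, 2) and d["B"] == (1, 1, 2)

    def test_isolated_node_present_with_zeros(self):
        g = digraph(("A", "B"))
        g.add_node("C")
        assert degrees(g)["C"] == (0, 0, 0)


class TestConvergence:
    def test_diamond_classes(self):
        conv = classify_convergence(degrees(digraph(*DIAMOND)))
        assert conv["M"] is ConvergenceClass.DIVERGENT
        assert conv["Z"] is ConvergenceClass.CONVERGENT
        assert conv["A"] is ConvergenceClass.BALANCED
        assert conv["B"] is ConvergenceClass.BALANCED

    def test_in_one_out_one_is_balanced(self):
        # e.g. an initiating event that is also fed by an upstream event
        g = digraph(("X", "G"), ("G", "R"))
        assert classify_convergence(degrees(g))["G"] is ConvergenceClass.BALANCED

    def test_classes_partition_nodes(self):
        g = random_digraph(8, 0.3, random.Random(7))
        conv = classify_convergence(degrees(g))
        assert len(conv) == g.number_of_nodes()


class TestEccentricity:
    def test_seven_chain_incoming(self):
        names = [f"n{i}" for i in range(7)]
        g = digraph(*zip(names, names[1:]))
        ecc = directed_eccentricity(g, "incoming")
        assert ecc[names[0]] == 0 and ecc[names[-1]] == 6

    def test_outgoing_orientation_mirrors_chain(self):
        g = digraph(("a", "b"), ("b", "c"))
        assert directed_eccentricity(g, "outgoing") == {"a": 2, "b": 1, "c": 0}

    def test_cycle_distances_stay_finite(self):
        # entry M -> A with cycle A -> B -> C -> A; frozen from all-pairs
        # shortest distances computed by hand on the 4-node graph
        g = digraph(("M", "A"), ("A", "B"), ("B", "C"), ("C", "A"))
        assert directed_eccentricity(g, "incoming") == {"M": 0, "A": 2, "B": 2, "C": 3}

    def test_unreachable_pairs_ignored(self):
        g = digraph(("a", "b"))
        g.add_node("island")
        ecc = directed_eccentricity(g)
        assert ecc["island"] == 0

    @pytest.mark.parametrize(
        "ecc,band",
        [
            (0, EccentricityBand.UPSTREAM),
            (2, EccentricityBand.UPSTREAM),
            (3, EccentricityBand.MIDDLE),
            (6, EccentricityBand.MIDDLE),
            (7, EccentricityBand.DOWNSTREAM),
        ],
    )
    def test_band_thresholds(self, ecc, band):
        assert band_eccentricity({"v": ecc})["v"] is band

    def test_adding_disjoint_chain_never_decreases_incoming_ecc(self):
        g = digraph(*DIAMOND)
        before = directed_eccentricity(g, "incoming")
        g.add_edges_from((("p", "q"), ("q", "r")))
        after = directed_eccentricity(g, "incoming")
        assert all(after[v] >= before[v] for v in before)


class TestBetweenness:
    def test_three_chain_middle_node(self):
        # one interior pair M -> AO through K, normalised by (n-1)(n-2) = 2
        assert betweenness(digraph(("M", "K"), ("K", "AO")))["K"] == pytest.approx(0.5)

    def test_star_centre_is_maximal(self):
        edges = [(f"in{i}", "c") for i in range(3)] + [("c", f"out{i}") for i in range(3)]
        b = betweenness(digraph(*edges))
        assert b["c"] == max(b.values()) > 0

    def test_matches_bruteforce_on_random_dags(self):
        rng = random.Random(11)
        for _ in range(20):
            n = rng.randint(4, 10)
            names = [str(i) for i in range(n)]
            g = nx.DiGraph()
            g.add_nodes_from(names)
            for i in range(n):
                for j in range(i + 1, n):  # forward edges only: acyclic
                    if rng.random() < 0.35:
                        g.add_edge(names[i], names[j])
            oracle = brute_betweenness(g)
            ours = betweenness(g)
            assert ours.keys() == oracle.keys()
            for v in ours:
                assert ours[v] == pytest.approx(oracle[v], abs=1e-12)


class TestPathEnumeration:
    def test_diamond_two_paths(self):
        paths = simple_paths_between(digraph(*DIAMOND), {"M"}, {"Z"})
        assert paths == [("M", "A", "Z"), ("M", "B", "Z")]

    def test_feedback_loop_no_revisit(self):
        g = digraph(("A", "B"), ("B", "A"), ("M", "A"), ("B", "Z"))
        assert simple_paths_between(g, {"M"}, {"Z"}) == [("M", "A", "B", "Z")]

    def test_node_both_endpoint_types_yields_no_trivial_path(self):
        g = digraph(("M", "X"), ("X", "Z"))
        # Z plays both roles: no zero-length path (Z,) may appear
        paths = simple_paths_between(g, {"M", "Z"}, {"Z"})
        assert paths == [("M", "X", "Z")]

    def test_path_through_intermediate_target_counts_both(self):
        g = digraph(("M", "A1"), ("A1", "A2"))
        paths = simple_paths_between(g, {"M"}, {"A1", "A2"})
        assert paths == [("M", "A1"), ("M", "A1", "A2")]

    def test_guard_trips_on_explosion(self):
        g = nx.complete_graph(7, create_using=nx.DiGraph)
        g = nx.relabel_nodes(g, {i: str(i) for i in g.nodes})
        with pytest.raises(PathExplosionError):
            simple_paths_between(g, set(g.nodes), set(g.nodes), max_paths=50)

    def test_annotation_driven_endpoints(self, feedback_collection):
        net = build_network(feedback_collection)
        assert enumerate_mie_ao_paths(net) == [("M", "A", "B", "Z")]

    def test_matches_bruteforce_on_random_digraphs(self):
        rng = random.Random(5)
        for _ in range(30):
            g = random_digraph(rng.randint(2, 7), 0.4, rng)
            nodes = set(g.nodes)
            sources = {v for v in nodes if rng.random() < 0.5} or nodes
            targets = {v for v in nodes if rng.random() < 0.5} or nodes
            assert simple_paths_between(g, sources, targets) == brute_simple_paths(
                g, sources, targets
            )


class TestPathOccurrence:
    def test_linear_chain_all_one(self):
        paths = [("M", "K", "A")]
        occ = path_occurrence(paths, ["M", "K", "A"])
        assert occ == {"M": 1.0, "K": 1.0, "A": 1.0}

    def test_diamond_halves(self):
        paths = simple_paths_between(digraph(*DIAMOND), {"M"}, {"Z"})
        occ = path_occurrence(paths, ["M", "A", "B", "Z"])
        assert occ == {"M": 1.0, "A": 0.5, "B": 0.5, "Z": 1.0}

    def test_off_path_node_scores_zero(self):
        occ = path_occurrence([("M", "Z")], ["M", "Z", "elsewhere"])
        assert occ["elsewhere"] == 0.0

    def test_empty_path_list_rejected(self):
        with pytest.raises(AopnetError):
            path_occurrence([], ["A"])

    def test_deleting_zero_occurrence_node_changes_nothing(self, tmp_path):
        col = collection_from_rows(
            tmp_path,
            [
                [1, "M", "MIE", "K", "KE", "adjacent", ""],
                [1, "K", "KE", "A", "AO", "adjacent", ""],
                [2, "K", "MIE", "Off", "AO", "adjacent", ""],
            ],
        )
        net = build_network(col)
        paths = enumerate_mie_ao_paths(net, mie_set={"M"}, ao_set={"A"})
        occ = path_occurrence(paths, net.graph.nodes)
        assert occ["Off"] == 0.0
        net.graph.remove_node("Off")
        paths2 = enumerate_mie_ao_paths(net, mie_set={"M"}, ao_set={"A"})
        occ2 = path_occurrence(paths2, net.graph.nodes)
        assert {v: occ[v] for v in occ2} == occ2


class TestDistributions:
    def test_single_aop_sharing_all_ones(self, linear_collection):
        net = build_network(linear_collection)
        share, hist = ke_sharing(net)
        assert set(share.values()) == {1}
        assert hist == {1: 3}

    def test_woe_thirds_round_to_33(self, tmp_path):
        col = collection_from_rows(
            tmp_path,
            [
                [1, "M", "MIE", "K1", "KE", "adjacent", "H"],
                [1, "K1", "KE", "K2", "KE", "adjacent", "M"],
                [1, "K2", "KE", "A", "AO", "adjacent", "L"],
            ],
        )
        net = build_network(col)
        dist = woe_distribution(net)
        assert {k.value: v for k, v in dist.items()} == {
            "high": 33,
            "medium": 33,
            "low": 33,
            "unspecified": 0,
        }
        summary, _ = summarise(net)
        assert any("WoE" in note for note in summary.rounding_notes)

    def test_all_unspecified_is_100(self, tmp_path):
        col = collection_from_rows(
            tmp_path, [[1, "M", "MIE", "A", "AO", "adjacent", ""]]
        )
        dist = woe_distribution(build_network(col))
        assert {k.value: v for k, v in dist.items()}["unspecified"] == 100

    @pytest.mark.parametrize(
        "num,den,expected", [(26, 45, 58), (11, 45, 24), (7, 45, 16), (27, 45, 60), (5, 8, 63)]
    )
    def test_round_half_away(self, num, den, expected):
        assert round_half_away(100 * num / den) == expected


class TestSummarise:
    def test_ranking_and_invariants(self, diamond_collection):
        summary, records = summarise(build_network(diamond_collection))
        assert summary.n_nodes == 4 and summary.n_edges == 4
        assert summary.n_paths == 2
        # ranked by occurrence desc then degree desc then title asc
        assert [r.node for r in records] == ["M", "Z", "A", "B"]
        assert summary.n_convergent + summary.n_divergent + summary.n_balanced == 4
        assert sum(r.in_degree for r in records) == summary.n_edges
        assert sum(r.out_degree for r in records) == summary.n_edges
        for r in records:
            assert 0.0 <= r.path_occurrence <= 1.0
            assert r.degree == r.in_degree + r.out_degree

    def test_metrics_invariant_to_input_row_order(self, tmp_path):
        config = GeneratorConfig(n_aops=6, seed=3)
        col = generate_collection(config)
        net = build_network(col)
        reversed_col = type(col)(
            records=list(reversed(col.records)), key_events=col.key_events
        )
        net2 = build_network(reversed_col)
        s1, r1 = summarise(net)
        s2, r2 = summarise(net2)
        assert s1 == s2 and r1 == r2

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_summary_consistent_on_generated_collections(self, seed):
        col = generate_collection(GeneratorConfig(n_aops=5, seed=seed))
        summary, records = summarise(build_network(col))
        assert summary.n_convergent + summary.n_divergent + summary.n_balanced == summary.n_nodes
        assert sum(r.in_degree for r in records) == summary.n_edges
        assert sum(r.out_degree for r in records) == summary.n_edges
        assert all(0.0 <= r.path_occurrence <= 1.0 for r in records)
        assert sum(summary.share_histogram.values()) == summary.n_nodes
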