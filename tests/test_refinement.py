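"""Splitting into per-time-point sub-clusters and temporal assembling."""

import networkx as nx
import numpy as np
import pytest

from jitrefine.activity import ActivityTable
from jitrefine.io import ComplexCatalog, write_complexes
from jitrefine.refine import (
    RefinementConfig,
    SubCluster,
    active_time_set,
    assemble,
    cluster_overlap,
    refine_catalog,
    refine_complex,
    split_complex,
)

from conftest import random_activity_table


def oracle_components(nodes, edges):
    """Connected components by union-find, independent of networkx."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        parent[find(a)] = find(b)
    comps = {}
    for v in nodes:
        comps.setdefault(find(v), set()).add(v)
    return {frozenset(c) for c in comps.values()}


class TestActiveTimeSet:
    def test_worked_example(self, worked_complex, worked_activity):
        assert active_time_set(worked_complex, worked_activity) == {1, 2, 3, 4}

    def test_all_wildcard_members(self):
        act = ActivityTable({"A": {0}, "B": {0}}, n=4)
        assert active_time_set({"A", "B"}, act) == {0}

    def test_equals_brute_force_union(self):
        rng = np.random.default_rng(11)
        proteins = [f"p{i}" for i in range(8)]
        act = random_activity_table(rng, proteins, 6)
        expected = set().union(*(act.get(p) for p in proteins))
        assert active_time_set(proteins, act) == expected


class TestSplitComplex:
    def test_worked_example_subclusters(self, worked_complex, worked_network, worked_activity):
        subs = split_complex(worked_complex, worked_network, worked_activity)
        got = {(s.time, s.members) for s in subs}
        assert got == {
            (1, frozenset("ACE")),
            (2, frozenset("ABE")),
            (3, frozenset("B")),
            (4, frozenset("B")),
            (4, frozenset("D")),
        }

    def test_fully_coactive_connected_complex_stays_whole(self):
        act = ActivityTable({p: {3} for p in "XYZ"}, n=4)
        net = nx.Graph([("X", "Y"), ("Y", "Z")])
        subs = split_complex("XYZ", net, act)
        assert [(s.time, s.members) for s in subs] == [(3, frozenset("XYZ"))]

    def test_member_absent_from_network_becomes_singleton(self):
        act = ActivityTable({"X": {1}, "Y": {1}, "Q": {1}}, n=4)
        net = nx.Graph([("X", "Y")])
        subs = split_complex({"X", "Y", "Q"}, net, act)
        assert {s.members for s in subs} == {frozenset("XY"), frozenset("Q")}

    def test_wildcard_members_split_at_time_zero(self):
        act = ActivityTable({"X": {1}, "W1": {0}, "W2": {0}}, n=4)
        net = nx.Graph([("X", "W1"), ("W1", "W2")])
        subs = split_complex({"X", "W1", "W2"}, net, act)
        assert (0, frozenset({"W1", "W2"})) in {(s.time, s.members) for s in subs}

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            m = int(rng.integers(3, 9))
            proteins = [f"p{i}" for i in range(m)]
            act = random_activity_table(rng, proteins, 6)
            net = nx.Graph()
            net.add_nodes_from(proteins)
            for i in range(m):
                for j in range(i + 1, m):
                    if rng.random() < 0.4:
                        net.add_edge(proteins[i], proteins[j])
            subs = split_complex(proteins, net, act)
            for t in active_time_set(proteins, act):
                if t == 0:
                    present = {p for p in proteins if act.get(p) == {0}}
                else:
                    present = {p for p in proteins if t in act.get(p)}
                edges = [(a, b) for a, b in net.edges() if a in present and b in present]
                expected = oracle_components(present, edges)
                got = {s.members for s in subs if s.time == t}
                assert got == expected


class TestClusterOverlap:
    def test_worked_example_pair(self):
        assert cluster_overlap(set("ACE"), set("ABE")) == pytest.approx(2 / 3)

    def test_disjoint_and_nested(self):
        assert cluster_overlap({"A"}, {"B"}) == 0.0
        assert cluster_overlap({"A", "B", "C"}, {"B", "C"}) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_overlap(set(), {"A"})


class TestAssemble:
    def test_worked_example_produces_single_complex(self, worked_complex, worked_network,
                                                    worked_activity):
        subs = split_complex(worked_complex, worked_network, worked_activity)
        assert assemble(subs, T=0.6) == [frozenset("ABCE")]

    def test_unreachable_threshold_merges_nothing(self):
        subs = [
            SubCluster(1, frozenset({"A", "B"})),
            SubCluster(2, frozenset({"B", "C"})),
            SubCluster(3, frozenset({"C", "D"})),
        ]
        out = assemble(subs, T=1.0)
        assert set(out) == {s.members for s in subs}

    def test_zero_threshold_cascades_whole_chain(self):
        # OV >= 0 holds even for disjoint sets, so a 3-time-point chain
        # collapses to a single complex containing every member
        subs = [
            SubCluster(1, frozenset({"A"})),
            SubCluster(2, frozenset({"B"})),
            SubCluster(3, frozenset({"C"})),
        ]
        assert assemble(subs, T=0.0) == [frozenset({"A", "B", "C"})]

    def test_wildcard_subclusters_merge_at_any_time_point_when_threshold_allows(self):
        # member sets of time-0 and real-time sub-clusters are disjoint by
        # construction, so OV = 0: they combine only at T = 0
        subs = [
            SubCluster(0, frozenset({"W"})),
            SubCluster(2, frozenset({"A", "B"})),
            SubCluster(5, frozenset({"C", "D"})),
        ]
        out = assemble(subs, T=0.0)
        assert out == [frozenset({"A", "B", "W"}), frozenset({"C", "D", "W"})]

    def test_unmerged_wildcard_subcluster_survives(self):
        subs = [
            SubCluster(0, frozenset({"W1", "W2"})),
            SubCluster(2, frozenset({"A", "B"})),
        ]
        out = assemble(subs, T=0.6)
        assert frozenset({"W1", "W2"}) in out

    def test_non_adjacent_time_points_never_merge_directly(self):
        subs = [
            SubCluster(1, frozenset({"A", "B"})),
            SubCluster(3, frozenset({"A", "B", "C"})),
        ]
        out = assemble(subs, T=0.5)
        assert set(out) == {frozenset({"A", "B"}), frozenset({"A", "B", "C"})}


class TestRefineCatalog:
    def test_worked_example_catalog(self, worked_catalog, worked_network, worked_activity):
        out = refine_catalog(worked_catalog, worked_network, worked_activity)
        assert list(out) == [frozenset("ABCE")]

    def test_small_complexes_pass_through(self, worked_network, worked_activity):
        cat = ComplexCatalog([frozenset({"A", "D"})])
        out = refine_catalog(cat, worked_network, worked_activity)
        assert list(out) == [frozenset({"A", "D"})]

    def test_identical_inputs_deduplicate(self, worked_complex, worked_catalog,
                                          worked_network, worked_activity):
        cat = ComplexCatalog([worked_complex, worked_complex])
        out = refine_catalog(cat, worked_network, worked_activity)
        assert len(out) == 1

    def _random_instance(self, rng):
        m = int(rng.integers(4, 10))
        proteins = [f"p{i}" for i in range(m)]
        act = random_activity_table(rng, proteins, 6)
        net = nx.Graph()
        net.add_nodes_from(proteins)
        for i in range(m):
            for j in range(i + 1, m):
                if rng.random() < 0.5:
                    net.add_edge(proteins[i], proteins[j])
        return proteins, net, act

    def test_no_invented_proteins(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            proteins, net, act = self._random_instance(rng)
            for refined in refine_complex(proteins, net, act):
                assert refined <= set(proteins)

    def test_refined_complexes_are_connected_after_removing_wildcards(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            proteins, net, act = self._random_instance(rng)
            for refined in refine_complex(proteins, net, act):
                real = {p for p in refined if act.get(p) != {0}}
                if len(real) >= 2:
                    assert nx.is_connected(net.subgraph(real))

    def test_raising_threshold_never_grows_largest_output(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            proteins, net, act = self._random_instance(rng)
            maxima = []
            for t in (0.2, 0.4, 0.6, 0.8, 1.0):
                out = refine_complex(proteins, net, act, RefinementConfig(T=t))
                maxima.append(max((len(c) for c in out), default=0))
            assert maxima == sorted(maxima, reverse=True)

    def test_byte_identical_output_across_runs(self, tmp_path, worked_network, worked_activity):
        rng = np.random.default_rng(6)
        proteins, net, act = self._random_instance(rng)
        cat = ComplexCatalog([frozenset(proteins)])
        paths = []
        for tag in ("a", "b"):
            out = refine_catalog(cat, net, act)
            p = tmp_path / f"{tag}.txt"
            write_complexes(out, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
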