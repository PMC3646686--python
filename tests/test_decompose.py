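"""Decomposition algorithms against brute-force reachability oracles."""

import pytest

from pathdissect import (
    MalformedNameError,
    Network,
    SubnetworkSet,
    bowtie_partition,
    cluster_subnetworks,
    connected_components,
    enumerate_cycles,
    filter_hubs,
    fixtures,
    material_components,
    strongly_connected_components,
)

from _oracles import oracle_cycles, oracle_scc, reachable_from, simple_adjacency


def net_from_edges(*edges, name="net"):
    net = Network(name)
    for u, v in edges:
        net.add_edge(u, v, interaction="activates", sign=+1)
    return net


# ---------------------------------------------------------------------------
# connected & strongly connected components
# ---------------------------------------------------------------------------

def test_connected_components_splits_disjoint_pieces():
    net = net_from_edges(("A", "B"), ("C", "D"))
    comps = connected_components(net)
    assert len(comps) == 2
    assert sorted(frozenset(c.node_ids) for c in comps.values()) == [
        frozenset({"A", "B"}),
        frozenset({"C", "D"}),
    ]


def test_connected_components_single_piece(diamond):
    comps = connected_components(diamond)
    assert len(comps) == 1
    (only,) = comps.values()
    assert only.node_ids == diamond.node_ids
    assert only.number_of_edges() == diamond.number_of_edges()


def test_scc_dag_gives_singletons():
    net = net_from_edges(("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"))
    assert all(len(c) == 1 for c in strongly_connected_components(net))


def test_scc_three_cycle_is_one_component():
    net = net_from_edges(("A", "B"), ("B", "C"), ("C", "A"))
    assert strongly_connected_components(net) == [{"A", "B", "C"}]


@pytest.mark.parametrize("seed", range(12))
def test_scc_matches_reachability_oracle(seed):
    """SCC partition equals mutual-reachability classes on random digraphs."""
    net = fixtures.random_digraph(4 + seed % 9, 0.25, seed=seed)
    got = strongly_connected_components(net)
    expected = oracle_scc(simple_adjacency(net))
    assert got == expected
    # partition: disjoint and covering
    union = set().union(*got)
    assert union == net.node_ids
    assert sum(len(c) for c in got) == len(union)


# ---------------------------------------------------------------------------
# bow-tie
# ---------------------------------------------------------------------------

def test_bowtie_hand_example():
    """A feeds a 2-cycle {B, C} which drains to D."""
    net = net_from_edges(("A", "B"), ("B", "C"), ("C", "B"), ("B", "D"))
    part = bowtie_partition(net)
    assert part.input_part == {"A"}
    assert part.core == {"B", "C"}
    assert part.output_part == {"D"}
    assert part.other == set()


def test_bowtie_pure_dag_has_empty_core(diamond):
    part = bowtie_partition(diamond)
    assert part.core == set()
    assert part.other == diamond.node_ids


def test_bowtie_self_loop_counts_as_core():
    net = net_from_edges(("A", "A"), ("B", "A"))
    part = bowtie_partition(net)
    assert part.core == {"A"}
    assert part.input_part == {"B"}


@pytest.mark.parametrize("seed", range(12))
def test_bowtie_invariants_on_random_graphs(seed):
    """Parts are disjoint/covering and satisfy the reachability constraints."""
    net = fixtures.random_digraph(4 + seed % 9, 0.25, seed=seed + 100)
    part = bowtie_partition(net)
    parts = [part.input_part, part.core, part.output_part, part.other]
    assert set().union(*parts) == net.node_ids
    assert sum(len(p) for p in parts) == len(net.node_ids)
    adj = simple_adjacency(net)
    # core equals the union of oracle non-trivial SCCs
    expected_core = set()
    for comp in oracle_scc(adj):
        if len(comp) > 1 or next(iter(comp)) in adj[next(iter(comp))]:
            expected_core |= comp
    assert part.core == expected_core
    closure = {n: reachable_from(adj, n) for n in adj}
    for n in part.input_part:
        assert closure[n] & part.core, "input must reach the core"
        assert not any(n in closure[c] for c in part.core), "core must not reach input"
    for n in part.output_part:
        assert any(n in closure[c] for c in part.core), "output must be reachable"
        assert not closure[n] & part.core, "output must not reach the core"


# ---------------------------------------------------------------------------
# material components
# ---------------------------------------------------------------------------

def test_material_components_complex_membership():
    """A protein belongs to its free forms and to every complex containing it."""
    net = Network("mat")
    for nid in ("A@c", "A:B@n", "B@c"):
        net.add_node(nid, kind="species")
    net.add_edge("A@c", "A:B@n", interaction="activates", sign=+1)
    net.add_edge("B@c", "A:B@n", interaction="activates", sign=+1)
    comps = material_components(net)
    assert set(comps) == {"A", "B"}
    assert comps["A"].node_ids == {"A@c", "A:B@n"}
    assert comps["B"].node_ids == {"A:B@n", "B@c"}
    # overlap on the shared complex is expected
    assert comps["A"].node_ids & comps["B"].node_ids == {"A:B@n"}


def test_material_components_group_modification_states():
    net = Network("mods")
    for nid in ("Cdc25", "Cdc25|Pho", "Cdc25|Pho@nucleus", "Wee1"):
        net.add_node(nid, kind="species")
    comps = material_components(net)
    assert comps["Cdc25"].node_ids == {"Cdc25", "Cdc25|Pho", "Cdc25|Pho@nucleus"}
    assert comps["Wee1"].node_ids == {"Wee1"}


def test_material_components_pull_adjacent_reactions():
    net = Network("rx")
    net.add_node("A", kind="species")
    net.add_node("B", kind="species")
    net.add_node("R1", kind="reaction")
    net.add_edge("A", "R1", interaction="reactant")
    net.add_edge("R1", "B", interaction="product")
    comps = material_components(net)
    assert comps["A"].node_ids == {"A", "R1"}
    assert comps["B"].node_ids == {"B", "R1"}


def test_material_components_membership_matches_name_scan():
    """Membership equals a direct brute-force scan of parsed member names."""
    from pathdissect import parse_entity_name

    net = Network("scan")
    names = ["X@c", "X:Y@c", "Y|p", "Z", "X:Z|p@n", "Y:Z"]
    for nid in names:
        net.add_node(nid, kind="species")
    comps = material_components(net)
    for base in ("X", "Y", "Z"):
        expected = {n for n in names if base in parse_entity_name(n).base_names}
        assert comps[base].node_ids == expected


def test_material_components_report_unparseable_ids():
    net = Network("bad")
    net.add_node("ok", kind="species")
    net.add_node("A::B", kind="species")
    with pytest.raises(MalformedNameError, match="A::B"):
        material_components(net)


# ---------------------------------------------------------------------------
# cycles
# ---------------------------------------------------------------------------

def test_triangle_has_exactly_one_cycle():
    net = net_from_edges(("A", "B"), ("B", "C"), ("C", "A"))
    cycles = enumerate_cycles(net)
    assert len(cycles) == 1
    assert cycles[0].nodes == ("A", "B", "C")  # canonical rotation


def test_two_disjoint_triangles_give_two_cycles():
    net = net_from_edges(
        ("A", "B"), ("B", "C"), ("C", "A"), ("X", "Y"), ("Y", "Z"), ("Z", "X")
    )
    assert len(enumerate_cycles(net)) == 2


def test_max_len_bounds_cycle_length():
    net = net_from_edges(("A", "B"), ("B", "A"), ("A", "C"), ("C", "D"), ("D", "A"))
    assert {c.nodes for c in enumerate_cycles(net, max_len=2)} == {("A", "B")}
    assert len(enumerate_cycles(net)) == 2


def test_cycle_cap_truncates_with_warning():
    net = fixtures.random_digraph(8, 0.5, seed=7)
    with pytest.warns(RuntimeWarning, match="truncated"):
        cycles = enumerate_cycles(net, cap=3)
    assert len(cycles) == 3


@pytest.mark.parametrize("seed", range(10))
def test_cycles_match_brute_force(seed):
    """Enumeration equals exhaustive DFS circuit search on small digraphs."""
    net = fixtures.random_digraph(3 + seed % 6, 0.3, seed=seed + 50)
    got = {c.nodes for c in enumerate_cycles(net)}
    assert got == oracle_cycles(simple_adjacency(net))
    # every reported cycle closes: each consecutive edge exists, incl. the wrap
    for cyc in enumerate_cycles(net):
        for u, v in cyc.edges:
            assert net.graph.has_edge(u, v)
        assert len(set(cyc.nodes)) == len(cyc.nodes)


def test_filter_hubs_drops_high_degree_nodes():
    net = net_from_edges(("H", "A"), ("H", "B"), ("H", "C"), ("A", "B"))
    filtered = filter_hubs(net, max_degree=2)
    assert "H" not in filtered.node_ids
    assert {"A", "B", "C"} <= filtered.node_ids


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def subnet(*node_ids, name="s"):
    net = Network(name)
    for nid in node_ids:
        net.add_node(nid)
    return net


def test_cluster_merges_on_intersection_ratio():
    """{A,B,C,D} and {C,D,E,F} share 2 of 4 nodes: 50% >= threshold 25."""
    subnets = SubnetworkSet(
        {"s1": subnet("A", "B", "C", "D"), "s2": subnet("C", "D", "E", "F")}
    )
    out = cluster_subnetworks(subnets, threshold_percent=25)
    assert set(out) == {"s1+s2"}
    assert out["s1+s2"].node_ids == {"A", "B", "C", "D", "E", "F"}
    # at threshold above 50% the pair stays apart
    assert set(cluster_subnetworks(subnets, 60)) == {"s1", "s2"}


def test_cluster_threshold_100_requires_containment():
    subnets = SubnetworkSet(
        {
            "s1": subnet("A", "B", "C"),
            "s2": subnet("B", "C", "D"),  # overlaps but neither contains the other
            "s3": subnet("A", "B"),  # contained in s1 -> 100%
        }
    )
    out = cluster_subnetworks(subnets, 100)
    assert "s1+s3" in out
    assert "s2" in out


def test_cluster_disjoint_inputs_unchanged_at_any_threshold():
    subnets = SubnetworkSet({"s1": subnet("A"), "s2": subnet("B"), "s3": subnet("C")})
    for threshold in (0, 50, 100):
        out = cluster_subnetworks(subnets, threshold)
        assert set(out) == {"s1", "s2", "s3"}


def test_cluster_output_count_never_exceeds_input():
    mats = material_components(fixturize_material())
    for threshold in (0, 25, 50, 100):
        assert len(cluster_subnetworks(mats, threshold)) <= len(mats)


def fixturize_material():
    net = Network("m")
    for nid in ("A", "A:B", "B:C", "C", "D"):
        net.add_node(nid, kind="species")
    return net
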