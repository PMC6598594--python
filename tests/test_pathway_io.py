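"""KGML parsing, Boolean conversion, merging, components."""

import pytest

from phenoflow import synthetic
from phenoflow.network import AND, MAJ, BooleanNetwork
from phenoflow.pathway_io import (
    KGMLParseError,
    KGMLStructureError,
    KNOWN_TYPES,
    connected_components,
    largest_component,
    merge_networks,
    parse_kgml,
    pathway_to_boolean,
    filter_pathways,
)

from oracles import ref_components

MINIMAL_KGML = """<?xml version="1.0"?>
<pathway name="path:test1">
  <entry id="1" name="hsa:10" type="gene"><graphics name="A"/></entry>
  <entry id="2" name="hsa:20" type="gene"><graphics name="B"/></entry>
  <entry id="3" name="hsa:30" type="gene"><graphics name="C"/></entry>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="2" entry2="3" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""


class TestParseKGML:
    def test_entries_and_relations_captured(self):
        p = parse_kgml(MINIMAL_KGML)
        assert len(p.nodes) == 3
        assert len(p.edges) == 2
        assert all(e.kegg_type == "activation" for e in p.edges)

    def test_group_entry_becomes_complex_with_member_genes(self):
        xml = MINIMAL_KGML.replace(
            "</pathway>",
            '<entry id="9" type="group"><component id="1"/><component id="2"/>'
            "</entry></pathway>",
        )
        p = parse_kgml(xml)
        complexes = [n for n in p.nodes if n.node_class == "complex"]
        assert len(complexes) == 1
        assert set(complexes[0].gene_ids) == {"hsa:10", "hsa:20"}

    def test_unknown_subtype_preserved_and_flagged(self):
        xml = MINIMAL_KGML.replace('name="activation"', 'name="state change"', 1)
        p = parse_kgml(xml)
        assert "state change" not in KNOWN_TYPES
        assert p.unmapped_types() == {"state change": 1}

    def test_malformed_xml_names_line(self):
        with pytest.raises(KGMLParseError, match="line"):
            parse_kgml("<pathway><entry></pathway>")

    def test_relation_to_missing_entry_is_structural_error(self):
        xml = MINIMAL_KGML.replace('entry2="3"', 'entry2="99"')
        with pytest.raises(KGMLStructureError):
            parse_kgml(xml)


class TestPathwayToBoolean:
    def _single_relation(self, subtype):
        xml = MINIMAL_KGML.replace("activation", subtype)
        return pathway_to_boolean(parse_kgml(xml))

    def test_activation_is_plus_edge_into_maj(self):
        net = self._single_relation("activation")
        assert net.nodes["hsa:20"].rule == MAJ
        assert any(e == ("hsa:10", "hsa:20", 1) for e in
                   [(e.src, e.dst, e.sign) for e in net.edges])

    def test_inhibition_is_minus_edge_into_maj(self):
        net = self._single_relation("inhibition")
        signs = {(e.src, e.dst): e.sign for e in net.edges}
        assert signs[("hsa:10", "hsa:20")] == -1
        assert net.nodes["hsa:20"].rule == MAJ

    def test_binding_creates_and_complex_with_positive_inputs(self):
        net = self._single_relation("binding/association")
        complexes = [nid for nid, s in net.nodes.items() if s.rule == AND]
        assert len(complexes) == 2  # (10,20) and (20,30)
        for cid in complexes:
            members = cid.split("+")
            incoming = [e for e in net.edges if e.dst == cid]
            assert {e.src for e in incoming} == set(members)
            assert all(e.sign == 1 for e in incoming)

    def test_skipped_types_produce_no_edges(self):
        for st in ("missing interaction", "remove"):
            net = self._single_relation(st)
            assert net.n_edges == 0
            assert net.meta["skipped"] == 2

    def test_never_minus_edge_into_and_node(self):
        # exercised via the toy generator, which targets a group with inhibition
        net = pathway_to_boolean(parse_kgml(synthetic.toy_kgml()))
        for e in net.edges:
            if net.nodes[e.dst].rule == AND:
                assert e.sign == 1

    def test_unmapped_subtype_counted(self):
        net = pathway_to_boolean(
            parse_kgml(synthetic.toy_kgml(include_unmapped=True))
        )
        assert net.meta["unmapped"] == {"state change": 1}


class TestMergeNetworks:
    def test_disjoint_union(self):
        a = BooleanNetwork()
        a.add_node("A"), a.add_node("B"), a.add_edge("A", "B", 1)
        b = BooleanNetwork()
        b.add_node("C"), b.add_node("D"), b.add_edge("C", "D", 1)
        m = merge_networks([a, b])
        assert m.n_nodes == 4 and m.n_edges == 2

    def test_duplicate_edges_collapse(self):
        a = BooleanNetwork()
        a.add_node("A"), a.add_node("B"), a.add_edge("A", "B", 1)
        m = merge_networks([a, a])
        assert m.n_nodes == 2 and m.n_edges == 1

    def test_rule_conflict_resolves_to_and_with_both_edge_sets(self):
        a = BooleanNetwork()
        a.add_node("X", MAJ), a.add_node("R", MAJ), a.add_edge("R", "X", 1)
        b = BooleanNetwork()
        b.add_node("X", AND), b.add_node("P", MAJ), b.add_edge("P", "X", 1)
        m = merge_networks([a, b])
        assert m.nodes["X"].rule == AND
        assert {(e.src, e.dst) for e in m.edges} == {("R", "X"), ("P", "X")}

    def test_counts_bounded_by_sums(self, rng):
        nets = [
            synthetic.random_boolean_network(
                synthetic.FixtureSpec(n_nodes=8, edge_density=0.2, seed=s)
            )
            for s in range(3)
        ]
        m = merge_networks(nets)
        assert m.n_nodes <= sum(n.n_nodes for n in nets)
        assert m.n_edges <= sum(n.n_edges for n in nets)


class TestComponents:
    def test_path_plus_isolated(self, path_net):
        comps = connected_components(path_net)
        assert [c.n_nodes for c in comps] == [3, 1]
        assert largest_component(path_net).n_nodes == 3

    def test_partition_is_disjoint_and_exhaustive(self):
        net = synthetic.random_boolean_network(
            synthetic.FixtureSpec(n_nodes=50, edge_density=0.02, seed=3)
        )
        comps = connected_components(net)
        all_nodes = [n for c in comps for n in c.nodes]
        assert sorted(all_nodes) == sorted(net.nodes)
        assert sum(c.n_edges for c in comps) == net.n_edges

    def test_matches_union_find_oracle(self):
        net = synthetic.random_boolean_network(
            synthetic.FixtureSpec(n_nodes=50, edge_density=0.02, seed=9)
        )
        ours = {frozenset(c.nodes) for c in connected_components(net)}
        assert ours == set(ref_components(net))

    def test_tie_broken_by_smallest_node_id_set(self):
        net = BooleanNetwork()
        for n in ("b1", "b2", "a1", "a2"):
            net.add_node(n)
        net.add_edge("b1", "b2", 1)
        net.add_edge("a1", "a2", 1)
        assert set(largest_component(net).nodes) == {"a1", "a2"}

    def test_single_node_is_its_own_component(self):
        net = BooleanNetwork()
        net.add_node("solo")
        assert largest_component(net).n_nodes == 1

    def test_empty_network_raises(self):
        with pytest.raises(Exception):
            largest_component(BooleanNetwork())


class TestSerialization:
    def test_round_trip(self):
        net = synthetic.random_boolean_network(
            synthetic.FixtureSpec(n_nodes=15, edge_density=0.15, n_complexes=2, seed=4)
        )
        assert BooleanNetwork.from_json(net.to_json()) == net

    def test_round_trip_of_converted_pathway(self):
        net = pathway_to_boolean(parse_kgml(synthetic.toy_kgml()))
        assert BooleanNetwork.from_json(net.to_json()) == net


def test_filter_pathways_marker_threshold():
    p = parse_kgml(synthetic.toy_kgml())
    markers = [f"syn:G{i}" for i in range(1, 7)]
    assert filter_pathways([p], markers, min_count=6) == [p]
    assert filter_pathways([p], markers[:3], min_count=6) == []
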