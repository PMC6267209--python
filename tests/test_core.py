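"""Container semantics: layers, nodes, edges, queries, joint invariants."""

import random

import pytest

import multilayer as ml
from conftest import apply_random_mutations, assert_integrity


class TestGraphCreation:
    def test_empty_construction(self):
        g = ml.create_graph("demo", directed=False)
        assert g.get_layers() == []
        assert g.get_nodes() == []
        assert g.get_edges() == []
        assert g.get_history() == []

    def test_directed_flag_round_trip(self):
        assert ml.create_graph("g", directed=True).directed is True
        assert ml.create_graph("g", directed=False).directed is False

    def test_empty_name_rejected(self):
        with pytest.raises(ml.ValidationError):
            ml.create_graph("", directed=False)


class TestLayers:
    def test_sequential_ids(self):
        g = ml.create_graph("g")
        g.add_layer("gene")
        assert [(l.id, l.name) for l in g.get_layers()] == [(1, "gene")]
        g.add_layer("drug").add_layer("disease")
        assert [l.id for l in g.get_layers()] == [1, 2, 3]

    def test_case_insensitive_uniqueness_preserves_spelling(self):
        g = ml.create_graph("g").add_layer("gene")
        with pytest.raises(ml.DuplicateLayerError):
            g.add_layer("Gene")
        assert g.get_layers()[0].name == "gene"
        assert g.layer("GENE").name == "gene"  # lookup forgiving, storage exact

    def test_empty_layer_name_rejected(self):
        with pytest.raises(ml.ValidationError):
            ml.create_graph("g").add_layer("")

    def test_remove_empty_middle_layer_compacts_ids(self):
        g = ml.create_graph("g")
        for name in ("A", "B", "C"):
            g.add_layer(name)
        g.add_node("x", "A").add_node("y", "C")
        g.remove_layer("B")
        assert [(l.id, l.name) for l in g.get_layers()] == [(1, "A"), (2, "C")]
        assert {n.name for n in g.get_nodes()} == {"x", "y"}
        assert g.get_layer_of("y") == "C"

    def test_remove_unknown_layer(self):
        with pytest.raises(ml.NotFoundError):
            ml.create_graph("g").remove_layer("nope")

    def test_remove_last_layer_yields_empty_graph(self):
        g = ml.create_graph("g").add_layer("only")
        g.add_node("x", "only")
        g.remove_layer("only")
        assert g.get_layers() == [] and g.get_nodes() == []

    def test_remove_layer_transitive_bridges_through_layer(self):
        g = ml.create_graph("g", directed=True)
        for layer, node in zip(("L1", "L2", "L3"), ("a", "b", "c")):
            g.add_layer(layer)
            g.add_node(node, layer)
        g.add_edge("a", "b").add_edge("b", "c")
        g.remove_layer("L2", trans=True)
        assert [(e.source, e.target) for e in g.get_edges()] == [("a", "c")]

    def test_remove_layer_plain_drops_routes(self):
        g = ml.create_graph("g", directed=True)
        for layer, node in zip(("L1", "L2", "L3"), ("a", "b", "c")):
            g.add_layer(layer)
            g.add_node(node, layer)
        g.add_edge("a", "b").add_edge("b", "c")
        g.remove_layer("L2", trans=False)
        assert g.get_edges() == []


class TestNodes:
    def test_round_trip(self):
        g = ml.create_graph("g").add_layer("gene")
        g.add_node("TP53", "gene", {"type": "protein"})
        assert g.get_layer_of("TP53") == "gene"
        assert g.get_node_attributes("TP53") == {"type": "protein"}

    def test_graph_wide_uniqueness(self):
        g = ml.create_graph("g").add_layer("gene").add_layer("drug")
        g.add_node("TP53", "gene")
        with pytest.raises(ml.DuplicateNodeError):
            g.add_node("TP53", "drug")

    def test_unknown_layer(self):
        with pytest.raises(ml.NotFoundError):
            ml.create_graph("g").add_node("x", "nope")

    def test_non_scalar_attribute_rejected(self):
        g = ml.create_graph("g").add_layer("L")
        with pytest.raises(ml.ValidationError):
            g.add_node("x", "L", {"nested": {"a": 1}})

    def test_reserved_attribute_key_rejected(self):
        g = ml.create_graph("g").add_layer("L")
        with pytest.raises(ml.ValidationError):
            g.add_node("x", "L", {"layer": "oops"})

    def test_remove_isolated_node_keeps_edges(self, demo):
        before = len(demo.get_edges())
        demo.add_node("loner", "gene")
        demo.remove_node("loner", trans=True)
        assert len(demo.get_edges()) == before
        with pytest.raises(ml.NotFoundError):
            demo.get_layer_of("loner")


class TestEdges:
    @pytest.fixture
    def g(self):
        g = ml.create_graph("g").add_layer("A").add_layer("B")
        g.add_node("a1", "A").add_node("a2", "A").add_node("b1", "B")
        return g

    def test_intra_layer_edge_legal(self, g):
        g.add_edge("a1", "a2")
        assert len(g.get_edges(between=("A", "A"))) == 1

    def test_parallel_edges_require_distinct_attributes(self, g):
        g.add_edge("a1", "b1", {"w": 1})
        g.add_edge("a1", "b1", {"w": 2})
        assert len(g.get_edges()) == 2
        with pytest.raises(ml.DuplicateEdgeError):
            g.add_edge("a1", "b1", {"w": 2})

    def test_undirected_orientation_is_one_edge(self, g):
        g.add_edge("a1", "b1")
        with pytest.raises(ml.DuplicateEdgeError):
            g.add_edge("b1", "a1")

    def test_directed_reverse_is_distinct(self):
        g = ml.create_graph("g", directed=True).add_layer("A")
        g.add_node("x", "A").add_node("y", "A")
        g.add_edge("x", "y").add_edge("y", "x")
        assert len(g.get_edges()) == 2

    def test_self_loop_rejected(self, g):
        with pytest.raises(ml.ValidationError):
            g.add_edge("a1", "a1")

    def test_missing_endpoint(self, g):
        with pytest.raises(ml.NotFoundError):
            g.add_edge("a1", "zzz")

    def test_remove_unique_edge(self, g):
        g.add_edge("a1", "b1")
        g.remove_edge("a1", "b1")
        assert g.get_edges() == []

    def test_remove_multi_removes_all_parallel(self, g):
        g.add_edge("a1", "b1", {"w": 1}).add_edge("a1", "b1", {"w": 2})
        g.remove_edge("a1", "b1", multi=True)
        assert g.get_edges() == []

    def test_remove_ambiguous_without_multi(self, g):
        g.add_edge("a1", "b1", {"w": 1}).add_edge("a1", "b1", {"w": 2})
        with pytest.raises(ml.AmbiguousEdgeError):
            g.remove_edge("a1", "b1")
        g.remove_edge("a1", "b1", {"w": 1})  # attribute filter disambiguates
        assert len(g.get_edges()) == 1

    def test_remove_no_match(self, g):
        with pytest.raises(ml.NotFoundError):
            g.remove_edge("a1", "b1")


class TestQueries:
    def test_layer_filter(self, demo):
        genes = {n.name for n in demo.get_nodes("gene")}
        assert genes == {"ADRB2", "IL13", "TNF"}

    def test_edges_between_layers(self, demo):
        pairs = {(e.source, e.target) for e in demo.get_edges(between=("drug", "gene"))}
        assert pairs == {("salbutamol", "ADRB2")}

    def test_undirected_between_symmetry(self, demo):
        ab = demo.get_edges(between=("disease", "gene"))
        ba = demo.get_edges(between=("gene", "disease"))
        assert [(e.edge_id, e.source, e.target) for e in ab] == [
            (e.edge_id, e.source, e.target) for e in ba
        ]

    def test_edges_incident_to_node(self, demo):
        incident = demo.get_edges(node="asthma")
        assert len(incident) == 3
        assert all("asthma" in (e.source, e.target) for e in incident)

    def test_empty_graph_edges(self):
        assert ml.create_graph("g").get_edges() == []

    def test_queries_are_pure(self, demo):
        snapshot = demo.copy()
        demo.get_layers()
        demo.get_nodes("drug")
        demo.get_edges(between=("drug", "gene"))
        demo.get_edges(node="TNF")
        demo.get_node_attributes("asthma")
        demo.summary()
        demo.get_history()
        assert ml.graphs_equal(demo, snapshot)

    def test_returned_records_are_copies(self, demo):
        demo.get_nodes()[0].attributes["hacked"] = True
        demo.get_edges()[0].attributes["hacked"] = True
        assert "hacked" not in demo.get_node_attributes("asthma")
        assert all("hacked" not in e.attributes for e in demo.get_edges())

    def test_summary_reports_counts(self, demo):
        text = demo.summary()
        assert "undirected" in text
        assert "'gene': 3 node(s)" in text
        assert "6 edge(s)" in text


@pytest.mark.parametrize("seed", range(10))
def test_random_op_sequences_preserve_invariants(seed):
    """Layer-disjointness and referential integrity hold after every mutation."""
    rng = random.Random(seed)
    g = ml.random_multilayer(3, 4, 0.2, directed=bool(seed % 2), seed=seed)
    for _ in range(15):
        apply_random_mutations(g, 1, rng)
        assert_integrity(g)


def test_to_networkx_mirrors_structure(demo):
    nxg = demo.to_networkx()
    assert set(nxg.nodes) == {n.name for n in demo.get_nodes()}
    assert nxg.number_of_edges() == len(demo.get_edges())
    assert nxg.nodes["TNF"]["layer"] == "gene"
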