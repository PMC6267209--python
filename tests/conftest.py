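"""Shared fixtures and independent oracles.

The reachability oracle deliberately goes through networkx (transitive
closure by BFS from every node) and never through the package's own
transitive-planning code, so it can adjudicate the shortcut algorithm.
"""

from __future__ import annotations

import random

import networkx as nx
import pytest

import multilayer as ml


def reachability(g: ml.MultilayerGraph) -> dict[str, frozenset]:
    """Boolean reachability relation: node -> set of nodes reachable from it."""
    nxg = nx.DiGraph() if g.directed else nx.Graph()
    nxg.add_nodes_from(n.name for n in g.get_nodes())
    nxg.add_edges_from((e.source, e.target) for e in g.get_edges())
    return {u: frozenset(nx.descendants(nxg, u)) for u in nxg.nodes}


def restrict(reach: dict[str, frozenset], survivors: set[str]) -> dict[str, frozenset]:
    return {u: reach[u] & survivors for u in reach if u in survivors}


def apply_random_mutations(g: ml.MultilayerGraph, k: int, rng: random.Random) -> int:
    """Apply ``k`` valid mutations drawn at random; returns the number applied."""
    applied = 0
    while applied < k:
        counter = rng.getrandbits(48)  # unique across repeated calls
        nodes = [n.name for n in g.get_nodes()]
        edges = g.get_edges()
        layers = g.get_layers()
        ops = ["add_layer"]
        if layers:
            ops.append("add_node")
        if len(nodes) >= 2:
            ops.append("add_edge")
        if nodes:
            ops.append("remove_node")
        if edges:
            ops.append("remove_edge")
        if layers and rng.random() < 0.05:
            ops.append("remove_layer")
        op = rng.choice(ops)
        if op == "add_layer":
            g.add_layer(f"layer{counter}")
        elif op == "add_node":
            g.add_node(f"node{counter}", rng.choice(layers).name)
        elif op == "add_edge":
            u, w = rng.sample(nodes, 2)
            try:
                g.add_edge(u, w, {"tag": counter})
            except ml.DuplicateEdgeError:  # pragma: no cover - tags are unique
                continue
        elif op == "remove_node":
            g.remove_node(rng.choice(nodes), trans=rng.random() < 0.5)
        elif op == "remove_edge":
            e = rng.choice(edges)
            g.remove_edge(e.source, e.target, e.attributes, multi=False)
        elif op == "remove_layer":
            g.remove_layer(rng.choice(layers).name, trans=rng.random() < 0.5)
        applied += 1
    return applied


def assert_integrity(g: ml.MultilayerGraph) -> None:
    """Joint layer-disjointness + referential-integrity assertion."""
    layer_ids = [l.id for l in g.get_layers()]
    assert layer_ids == list(range(1, len(layer_ids) + 1))
    names = [n.name for n in g.get_nodes()]
    assert len(names) == len(set(names)), "node names must be unique graph-wide"
    for n in g.get_nodes():
        assert n.layer_id in layer_ids, f"node {n.name} references dead layer"
    node_set = set(names)
    for e in g.get_edges():
        assert e.source in node_set and e.target in node_set


@pytest.fixture
def demo():
    return ml.demo_graph()


@pytest.fixture
def path_graph():
    """Directed path a -> v -> b across three layers."""
    g = ml.create_graph("path", directed=True)
    for layer, node in zip(("L1", "L2", "L3"), ("a", "v", "b")):
        g.add_layer(layer)
        g.add_node(node, layer)
    g.add_edge("a", "v")
    g.add_edge("v", "b")
    return g
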