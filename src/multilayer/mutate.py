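"""Transitivity-preserving deletion and layer-based merging.

Transitive deletion: when a node ``v`` is removed, every route that passed
through ``v`` is preserved by first inserting shortcut ("transitive") edges
between v's neighbours — ``u -> w`` for every in-neighbour ``u`` and
out-neighbour ``w`` in the directed case, a clique on the neighbours in the
undirected case.  Since every through-path of length two is replaced, the
reachability relation on the surviving nodes is unchanged, and by induction
stays unchanged under sequential removals (deleting a whole layer, say).

Layer-based merge: two graphs are combined into one valid multilayer graph
by matching layers by name, nodes by name, and edges by (endpoints,
attributes), so content shared between the inputs — replicated data from
multiple sources — appears once in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import IncompatibleGraphsError, LayerConflictError
from .model import MultilayerGraph, attributes_equal


@dataclass
class TransitivePlan:
    """The edges to insert and drop when removing one node transitively.

    ``new_edges`` are ``(source, target, attributes)`` triples; each carries
    the provenance attribute ``{"via": removed_node}``.  The plan never
    contains a self-loop, and never an edge between endpoints that are
    already connected.
    """

    removed_node: str
    new_edges: list[tuple[str, str, dict]] = field(default_factory=list)
    dropped_edges: list[int] = field(default_factory=list)


def add_transitive_edges(g: MultilayerGraph, node_name: str) -> TransitivePlan:
    """Plan the shortcut edges that preserve routes through ``node_name``.

    Directed: for every in-neighbour ``u`` and out-neighbour ``w`` of ``v``
    with ``u != w``, plan ``u -> w`` unless some edge ``u -> w`` already
    exists.  Undirected: for every unordered pair of distinct neighbours,
    plan ``u - w`` unless some edge joins them already.  Planned edges carry
    the single attribute ``{"via": v}``.

    The plan is not applied here; :meth:`MultilayerGraph.remove_node` with
    ``trans=True`` (or :func:`remove_node_transitive`) applies it and then
    removes the node as one atomic step.
    """
    g.node(node_name)
    plan = TransitivePlan(removed_node=node_name)
    incident = g.get_edges(node=node_name)
    plan.dropped_edges = [e.edge_id for e in incident]

    def _uniq(names):
        seen = []
        for n in names:
            if n != node_name and n not in seen:
                seen.append(n)
        return seen

    if g.directed:
        sources = _uniq(e.source for e in incident if e.target == node_name)
        targets = _uniq(e.target for e in incident if e.source == node_name)
        for u in sources:
            for w in targets:
                if u == w:
                    continue
                if g.edges_between(u, w):
                    continue
                plan.new_edges.append((u, w, {"via": node_name}))
    else:
        neighbours = _uniq(
            e.target if e.source == node_name else e.source for e in incident
        )
        for i, u in enumerate(neighbours):
            for w in neighbours[i + 1 :]:
                if g.edges_between(u, w):
                    continue
                plan.new_edges.append((u, w, {"via": node_name}))
    return plan


def remove_node_transitive(g: MultilayerGraph, node_name: str) -> MultilayerGraph:
    """Insert the transitive shortcuts, then remove the node — one undo step."""
    return g.remove_node(node_name, trans=True)


def merge(g1: MultilayerGraph, g2: MultilayerGraph) -> MultilayerGraph:
    """Combine two graphs layer-by-layer into a new, deduplicated graph.

    The result takes ``g1``'s layers followed by ``g2``'s layers that are
    new by (case-insensitive) name, with ids recompacted; nodes are matched
    by name — a shared node keeps the union of its attributes with ``g1``
    winning conflicts — and an edge of ``g2`` is copied only if no edge with
    the same endpoints and attributes is already present.

    Raises
    ------
    IncompatibleGraphsError
        If one graph is directed and the other is not.
    LayerConflictError
        If a node name sits on differently named layers in the two inputs;
        silent reassignment would corrupt layer-disjointness.

    The returned graph starts a fresh history whose first record documents
    the merge; that record cannot be undone into the parents.
    """
    if g1.directed != g2.directed:
        raise IncompatibleGraphsError("cannot merge a directed with an undirected graph")

    layer_of_1 = {n.name: g1.get_layer_of(n.name) for n in g1.get_nodes()}
    layer_of_2 = {n.name: g2.get_layer_of(n.name) for n in g2.get_nodes()}
    for name in layer_of_1.keys() & layer_of_2.keys():
        if layer_of_1[name].lower() != layer_of_2[name].lower():
            raise LayerConflictError(
                f"node {name!r} lies on layer {layer_of_1[name]!r} in the first graph "
                f"but on {layer_of_2[name]!r} in the second"
            )

    out = MultilayerGraph(f"{g1.name}+{g2.name}", g1.directed)
    with out._history_suspended():
        for layer in g1.get_layers():
            out.add_layer(layer.name)
        for layer in g2.get_layers():
            if out._find_layer(layer.name) is None:
                out.add_layer(layer.name)

        for node in g1.get_nodes():
            attrs = dict(node.attributes)
            twin = layer_of_2.get(node.name)
            if twin is not None:
                # attribute union; first argument wins conflicts
                merged = dict(g2.get_node_attributes(node.name))
                merged.update(attrs)
                attrs = merged
            out.add_node(node.name, layer_of_1[node.name], attrs)
        for node in g2.get_nodes():
            if node.name not in layer_of_1:
                out.add_node(node.name, layer_of_2[node.name], dict(node.attributes))

        for edge in g1.get_edges():
            out.add_edge(edge.source, edge.target, dict(edge.attributes))
        for edge in g2.get_edges():
            if any(
                attributes_equal(e.attributes, edge.attributes)
                for e in out.edges_between(edge.source, edge.target)
            ):
                continue
            out.add_edge(edge.source, edge.target, dict(edge.attributes))

    from . import history

    out._history.append(
        history.make_record(
            out,
            "merge",
            f"merge of {g1.name!r} and {g2.name!r} (layer-based, first-argument precedence)",
            None,
        )
    )
    return out
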