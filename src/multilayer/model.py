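"""Core container: the layered-disjoint node-colored multilayer graph.

A :class:`MultilayerGraph` partitions its nodes into named *layers* (the
"colours" of a node-colored graph): every node belongs to exactly one layer,
and edges may run within a layer (intra-layer) or between layers
(inter-layer).  The graph is either directed or undirected as a whole, node
names are unique graph-wide, and parallel edges between the same endpoints
are allowed as long as their attribute maps differ.

Every mutating operation records an invertible :class:`~multilayer.history.ChangeRecord`
so the graph can be rolled back with :meth:`MultilayerGraph.undo`; queries
never touch the history.
"""

from __future__ import annotations

import copy
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Iterator

from .errors import (
    AmbiguousEdgeError,
    DuplicateEdgeError,
    DuplicateLayerError,
    DuplicateNodeError,
    NotFoundError,
    ValidationError,
)

#: attribute keys reserved by the CSV schema and therefore forbidden on entities
RESERVED_NODE_KEYS = frozenset({"name", "layer"})
RESERVED_EDGE_KEYS = frozenset({"source", "target"})

Scalar = str | int | float | bool


@dataclass
class Layer:
    """A named node partition class; ``id`` is the 1-based assignment order."""

    id: int
    name: str


@dataclass
class NodeRecord:
    """An attributed vertex bound to exactly one layer."""

    name: str
    layer_id: int
    attributes: dict[str, Scalar] = field(default_factory=dict)


@dataclass
class EdgeRecord:
    """An attributed edge; ``edge_id`` is unique within its graph.

    In an undirected graph ``(source, target)`` and ``(target, source)``
    denote the same edge; the stored orientation is the insertion one.
    """

    edge_id: int
    source: str
    target: str
    attributes: dict[str, Scalar] = field(default_factory=dict)


def _validate_attributes(attributes: dict | None, reserved: frozenset[str]) -> dict[str, Scalar]:
    if attributes is None:
        return {}
    if not isinstance(attributes, dict):
        raise ValidationError("attributes must be a mapping of string -> scalar")
    out: dict[str, Scalar] = {}
    for key, value in attributes.items():
        if not isinstance(key, str) or not key:
            raise ValidationError(f"attribute key must be a non-empty string, got {key!r}")
        if key in reserved:
            raise ValidationError(f"attribute key {key!r} is reserved by the CSV schema")
        if not isinstance(value, (str, int, float, bool)):
            raise ValidationError(
                f"attribute {key!r} must be a scalar (string/number/boolean), got {type(value).__name__}"
            )
        out[key] = value
    return out


def attributes_equal(a: dict, b: dict) -> bool:
    """Edge/node attribute-map identity: same key set, values equal.

    Numbers compare exactly (``1 == 1.0`` holds, as in Python); booleans are
    distinguished from the integers 0/1.
    """
    if a.keys() != b.keys():
        return False
    for k, va in a.items():
        vb = b[k]
        if isinstance(va, bool) != isinstance(vb, bool):
            return False
        if va != vb:
            return False
    return True


class MultilayerGraph:
    """A layered-disjoint node-colored multilayer graph.

    Parameters
    ----------
    name:
        Non-empty graph name.
    directed:
        Whether edges are directed.  Fixed at construction.

    Notes
    -----
    Mutating methods operate in place and return ``self`` so call chains and
    the functional wrappers in :mod:`multilayer` both work; callers must
    treat the returned value as the current graph.
    """

    def __init__(self, name: str, directed: bool = False):
        if not isinstance(name, str) or not name:
            raise ValidationError("graph name must be a non-empty string")
        self.name = name
        self.directed = bool(directed)
        self._layers: list[Layer] = []
        self._nodes: dict[str, NodeRecord] = {}
        self._edges: dict[int, EdgeRecord] = {}
        self._next_edge_id = 1
        self._history: list = []  # list[history.ChangeRecord]
        self._recording = True

    # ------------------------------------------------------------------ utils

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "directed" if self.directed else "undirected"
        return (
            f"<MultilayerGraph {self.name!r} ({kind}): "
            f"{len(self._layers)} layers, {len(self._nodes)} nodes, {len(self._edges)} edges>"
        )

    def copy(self) -> "MultilayerGraph":
        """Deep, independent copy (including history)."""
        g = MultilayerGraph(self.name, self.directed)
        g._layers = copy.deepcopy(self._layers)
        g._nodes = copy.deepcopy(self._nodes)
        g._edges = copy.deepcopy(self._edges)
        g._next_edge_id = self._next_edge_id
        g._history = copy.deepcopy(self._history)
        return g

    @contextmanager
    def _history_suspended(self) -> Iterator[None]:
        """Internal: run a block without creating ChangeRecords."""
        prev, self._recording = self._recording, False
        try:
            yield
        finally:
            self._recording = prev

    def _record(self, op_tag: str, description: str, pre_state) -> None:
        if not self._recording:
            return
        from . import history

        self._history.append(history.make_record(self, op_tag, description, pre_state))

    def _pre_state(self):
        if not self._recording:
            return None
        from . import history

        return history.capture_state(self)

    # ----------------------------------------------------------------- layers

    def _find_layer(self, layer_name: str) -> Layer | None:
        if not isinstance(layer_name, str):
            raise ValidationError("layer name must be a string")
        low = layer_name.lower()
        for layer in self._layers:
            if layer.name.lower() == low:
                return layer
        return None

    def layer(self, layer_name: str) -> Layer:
        """Resolve a layer by name (case-insensitive) or raise ``NotFoundError``."""
        found = self._find_layer(layer_name)
        if found is None:
            raise NotFoundError(f"layer {layer_name!r} does not exist")
        return found

    def add_layer(self, layer_name: str) -> "MultilayerGraph":
        """Append a new layer; its id is the previous layer count + 1."""
        if not isinstance(layer_name, str) or not layer_name:
            raise ValidationError("layer name must be a non-empty string")
        if self._find_layer(layer_name) is not None:
            raise DuplicateLayerError(f"layer {layer_name!r} already exists (case-insensitive)")
        pre = self._pre_state()
        self._layers.append(Layer(len(self._layers) + 1, layer_name))
        self._record("add_layer", f"add layer {layer_name!r}", pre)
        return self

    def remove_layer(self, layer_name: str, trans: bool = False) -> "MultilayerGraph":
        """Remove a layer, its nodes and their incident edges as one atomic step.

        Nodes are removed in insertion order via the same mechanics as
        :meth:`remove_node`; with ``trans=True`` each removal first inserts
        the transitive shortcut edges so routes through the deleted layer
        survive.  Remaining layer ids are compacted to ``1..k-1`` preserving
        relative order.
        """
        target = self.layer(layer_name)
        pre = self._pre_state()
        with self._history_suspended():
            for node_name in [n.name for n in self._nodes.values() if n.layer_id == target.id]:
                self.remove_node(node_name, trans=trans)
            self._layers.remove(target)
            remap = {layer.id: i + 1 for i, layer in enumerate(self._layers)}
            for layer in self._layers:
                layer.id = remap[layer.id]
            for node in self._nodes.values():
                node.layer_id = remap[node.layer_id]
        self._record(
            "remove_layer",
            f"remove layer {target.name!r} (trans={bool(trans)})",
            pre,
        )
        return self

    def get_layers(self) -> list[Layer]:
        """Ordered list of layers (copies; mutating them does not touch the graph)."""
        return copy.deepcopy(self._layers)

    # ------------------------------------------------------------------ nodes

    def node(self, node_name: str) -> NodeRecord:
        try:
            return self._nodes[node_name]
        except KeyError:
            raise NotFoundError(f"node {node_name!r} does not exist") from None

    def add_node(
        self, node_name: str, layer_name: str, attributes: dict | None = None
    ) -> "MultilayerGraph":
        """Add a node bound to an existing layer; names are unique graph-wide."""
        if not isinstance(node_name, str) or not node_name:
            raise ValidationError("node name must be a non-empty string")
        attrs = _validate_attributes(attributes, RESERVED_NODE_KEYS)
        target = self.layer(layer_name)
        if node_name in self._nodes:
            raise DuplicateNodeError(f"node {node_name!r} already exists in the graph")
        pre = self._pre_state()
        self._nodes[node_name] = NodeRecord(node_name, target.id, attrs)
        self._record("add_node", f"add node {node_name!r} to layer {target.name!r}", pre)
        return self

    def remove_node(self, node_name: str, trans: bool = False) -> "MultilayerGraph":
        """Remove a node and its incident edges.

        With ``trans=True`` the transitive shortcut edges are inserted first
        (see :func:`multilayer.mutate.add_transitive_edges`), so reachability
        among the surviving nodes is unchanged; the whole thing is a single
        undoable step.
        """
        self.node(node_name)
        pre = self._pre_state()
        with self._history_suspended():
            if trans:
                from .mutate import add_transitive_edges

                plan = add_transitive_edges(self, node_name)
                for src, dst, attrs in plan.new_edges:
                    self.add_edge(src, dst, attrs)
            incident = [
                e.edge_id
                for e in self._edges.values()
                if node_name in (e.source, e.target)
            ]
            for edge_id in incident:
                del self._edges[edge_id]
            del self._nodes[node_name]
        self._record(
            "remove_node_transitive" if trans else "remove_node",
            f"remove node {node_name!r} (trans={bool(trans)})",
            pre,
        )
        return self

    def get_nodes(self, layer_name: str | None = None) -> list[NodeRecord]:
        """All nodes in insertion order, optionally restricted to one layer."""
        if layer_name is None:
            return copy.deepcopy(list(self._nodes.values()))
        target = self.layer(layer_name)
        return copy.deepcopy([n for n in self._nodes.values() if n.layer_id == target.id])

    def get_node_attributes(self, node_name: str) -> dict[str, Scalar]:
        return dict(self.node(node_name).attributes)

    def get_layer_of(self, node_name: str) -> str:
        """Name of the layer the node lives on."""
        layer_id = self.node(node_name).layer_id
        for layer in self._layers:
            if layer.id == layer_id:
                return layer.name
        raise NotFoundError(f"layer id {layer_id} of node {node_name!r} is dangling")

    # ------------------------------------------------------------------ edges

    def _same_endpoints(self, edge: EdgeRecord, source: str, target: str) -> bool:
        if edge.source == source and edge.target == target:
            return True
        if not self.directed and edge.source == target and edge.target == source:
            return True
        return False

    def edges_between(self, source: str, target: str) -> list[EdgeRecord]:
        """Live edge records joining two named nodes (orientation-insensitive
        when the graph is undirected).  Internal records, not copies."""
        return [e for e in self._edges.values() if self._same_endpoints(e, source, target)]

    def add_edge(
        self, source: str, target: str, attributes: dict | None = None
    ) -> "MultilayerGraph":
        """Insert an edge; parallel edges must differ in their attribute maps."""
        attrs = _validate_attributes(attributes, RESERVED_EDGE_KEYS)
        self.node(source)
        self.node(target)
        if source == target:
            raise ValidationError("self-loops are not allowed")
        for other in self.edges_between(source, target):
            if attributes_equal(other.attributes, attrs):
                raise DuplicateEdgeError(
                    f"edge {source!r}->{target!r} with identical attributes already exists"
                )
        pre = self._pre_state()
        edge_id = self._next_edge_id
        self._next_edge_id += 1
        self._edges[edge_id] = EdgeRecord(edge_id, source, target, attrs)
        self._record("add_edge", f"add edge {source!r}->{target!r}", pre)
        return self

    def remove_edge(
        self,
        source: str,
        target: str,
        attributes: dict | None = None,
        multi: bool = False,
    ) -> "MultilayerGraph":
        """Remove matching edge(s).

        A match shares the endpoints (either orientation when undirected)
        and, if ``attributes`` is given, the exact attribute map.  With
        ``multi=True`` every match is removed; otherwise the match must be
        unique.
        """
        self.node(source)
        self.node(target)
        matches = self.edges_between(source, target)
        if attributes is not None:
            wanted = _validate_attributes(attributes, RESERVED_EDGE_KEYS)
            matches = [e for e in matches if attributes_equal(e.attributes, wanted)]
        if not matches:
            raise NotFoundError(f"no edge matches {source!r}-{target!r}")
        if len(matches) > 1 and not multi:
            raise AmbiguousEdgeError(
                f"{len(matches)} parallel edges match {source!r}-{target!r}; "
                "pass attributes to disambiguate or multi=True to remove all"
            )
        pre = self._pre_state()
        for edge in matches:
            del self._edges[edge.edge_id]
        self._record(
            "remove_edge",
            f"remove {len(matches)} edge(s) {source!r}-{target!r}",
            pre,
        )
        return self

    def get_edges(
        self,
        between: tuple[str, str] | None = None,
        node: str | None = None,
    ) -> list[EdgeRecord]:
        """Edges in insertion order, optionally filtered.

        ``between=(layer_a, layer_b)`` keeps edges with one endpoint on each
        of the two layers (in either role); ``node=name`` keeps edges
        incident to that node.  The two filters are mutually exclusive.
        """
        if between is not None and node is not None:
            raise ValidationError("pass either 'between' or 'node', not both")
        edges = list(self._edges.values())
        if node is not None:
            self.node(node)
            edges = [e for e in edges if node in (e.source, e.target)]
        elif between is not None:
            layer_a = self.layer(between[0]).id
            layer_b = self.layer(between[1]).id
            def _pair(e: EdgeRecord) -> bool:
                ls = self._nodes[e.source].layer_id
                lt = self._nodes[e.target].layer_id
                return {ls, lt} == {layer_a, layer_b} or (
                    layer_a == layer_b and ls == lt == layer_a
                )
            edges = [e for e in edges if _pair(e)]
        return copy.deepcopy(edges)

    # ---------------------------------------------------------------- reports

    def summary(self) -> str:
        """Human-readable report: directedness, per-layer node counts, edge count."""
        kind = "directed" if self.directed else "undirected"
        lines = [f"{self.name}: {kind} multilayer graph with {len(self._layers)} layer(s)"]
        for layer in self._layers:
            count = sum(1 for n in self._nodes.values() if n.layer_id == layer.id)
            lines.append(f"  layer {layer.id} {layer.name!r}: {count} node(s)")
        lines.append(f"  {len(self._edges)} edge(s) total")
        return "\n".join(lines)

    # ---------------------------------------------------------------- history

    def undo(self, steps: int = 1) -> "MultilayerGraph":
        """Revert the last ``steps`` mutations (see :mod:`multilayer.history`)."""
        from . import history

        return history.undo(self, steps)

    def get_history(self) -> list[tuple[int, str, str]]:
        from . import history

        return history.get_history(self)

    # ------------------------------------------------------------- converters

    def to_networkx(self):
        """Export to a :class:`networkx.MultiDiGraph`/``MultiGraph``.

        Node data carries ``layer`` (name) plus user attributes; edge keys
        are the edge ids.  Purely a view for interoperability — the returned
        object is detached from this graph.
        """
        import networkx as nx

        nxg = nx.MultiDiGraph() if self.directed else nx.MultiGraph()
        nxg.graph["name"] = self.name
        names = {layer.id: layer.name for layer in self._layers}
        for node in self._nodes.values():
            nxg.add_node(node.name, layer=names[node.layer_id], **node.attributes)
        for edge in self._edges.values():
            nxg.add_edge(edge.source, edge.target, key=edge.edge_id, **edge.attributes)
        return nxg


def graphs_equal(
    a: MultilayerGraph, b: MultilayerGraph, include_edge_ids: bool = True
) -> bool:
    """Deep structural equality, ignoring history.

    Compares name, directedness, the ordered layer list, the ordered node
    records and the ordered edge records.  ``include_edge_ids=False`` drops
    the edge ids from the comparison — the right notion after a CSV
    round-trip, where ids are reassigned in insertion order.
    """
    if a.name != b.name or a.directed != b.directed:
        return False
    if [(l.id, l.name) for l in a._layers] != [(l.id, l.name) for l in b._layers]:
        return False
    na, nb = list(a._nodes.values()), list(b._nodes.values())
    if len(na) != len(nb):
        return False
    for x, y in zip(na, nb):
        if x.name != y.name or x.layer_id != y.layer_id:
            return False
        if not attributes_equal(x.attributes, y.attributes):
            return False
    ea, eb = list(a._edges.values()), list(b._edges.values())
    if len(ea) != len(eb):
        return False
    for x, y in zip(ea, eb):
        if include_edge_ids and x.edge_id != y.edge_id:
            return False
        if (x.source, x.target) != (y.source, y.target):
            return False
        if not attributes_equal(x.attributes, y.attributes):
            return False
    return True
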