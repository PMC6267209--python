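"""Layered-disjoint node-colored multilayer graphs.

The package models networks whose vertices are partitioned into named
layers (disease, drug, gene, ...) with edges both within and between
layers, and provides the operations such integrated networks need:
transitivity-preserving deletion, layer-based merging with deduplication,
an undo history that documents every modification, layer-banded 2D/3D
layouts, and CSV / Cytoscape-CX serialization.

The object API lives on :class:`MultilayerGraph`; the module-level
functions below are thin functional wrappers over it.
"""

from .errors import (
    AmbiguousEdgeError,
    DuplicateEdgeError,
    DuplicateLayerError,
    DuplicateNodeError,
    EmptyLayoutError,
    HistoryUnderflowError,
    IncompatibleGraphsError,
    LayerConflictError,
    LayoutCapacityError,
    MultilayerError,
    NotFoundError,
    SchemaError,
    ValidationError,
)
from .history import ChangeRecord, export_history_log, get_history, undo
from .io import (
    build_cx,
    demo_graph,
    export_csv,
    export_cx,
    import_csv,
    random_multilayer,
    validate_cx,
)
from .layout import LayoutResult, layout_random, layout_scaled, render
from .model import EdgeRecord, Layer, MultilayerGraph, NodeRecord, graphs_equal
from .mutate import TransitivePlan, add_transitive_edges, merge, remove_node_transitive

__version__ = "0.1.0"


def create_graph(name: str, directed: bool = False) -> MultilayerGraph:
    """Create an empty multilayer graph."""
    return MultilayerGraph(name, directed)


def add_layer(g: MultilayerGraph, layer_name: str) -> MultilayerGraph:
    return g.add_layer(layer_name)


def remove_layer(g: MultilayerGraph, layer_name: str, trans: bool = False) -> MultilayerGraph:
    return g.remove_layer(layer_name, trans=trans)


def add_node(g: MultilayerGraph, node_name: str, layer_name: str, attributes=None) -> MultilayerGraph:
    return g.add_node(node_name, layer_name, attributes)


def remove_node(g: MultilayerGraph, node_name: str, trans: bool = False) -> MultilayerGraph:
    return g.remove_node(node_name, trans=trans)


def add_edge(g: MultilayerGraph, source: str, target: str, attributes=None) -> MultilayerGraph:
    return g.add_edge(source, target, attributes)


def remove_edge(g: MultilayerGraph, source: str, target: str, attributes=None, multi: bool = False) -> MultilayerGraph:
    return g.remove_edge(source, target, attributes, multi=multi)


def get_layers(g: MultilayerGraph):
    return g.get_layers()


def get_nodes(g: MultilayerGraph, layer_name: str | None = None):
    return g.get_nodes(layer_name)


def get_node_attributes(g: MultilayerGraph, node_name: str):
    return g.get_node_attributes(node_name)


def get_edges(g: MultilayerGraph, between=None, node=None):
    return g.get_edges(between=between, node=node)


def get_layer_of(g: MultilayerGraph, node_name: str) -> str:
    return g.get_layer_of(node_name)


def summary(g: MultilayerGraph) -> str:
    return g.summary()


__all__ = [
    "MultilayerGraph",
    "Layer",
    "NodeRecord",
    "EdgeRecord",
    "ChangeRecord",
    "TransitivePlan",
    "LayoutResult",
    "create_graph",
    "add_layer",
    "remove_layer",
    "add_node",
    "remove_node",
    "add_edge",
    "remove_edge",
    "get_layers",
    "get_nodes",
    "get_node_attributes",
    "get_edges",
    "get_layer_of",
    "summary",
    "graphs_equal",
    "add_transitive_edges",
    "remove_node_transitive",
    "merge",
    "undo",
    "get_history",
    "export_history_log",
    "layout_scaled",
    "layout_random",
    "render",
    "export_csv",
    "import_csv",
    "export_cx",
    "build_cx",
    "validate_cx",
    "demo_graph",
    "random_multilayer",
    "MultilayerError",
    "ValidationError",
    "NotFoundError",
    "DuplicateLayerError",
    "DuplicateNodeError",
    "DuplicateEdgeError",
    "AmbiguousEdgeError",
    "LayerConflictError",
    "IncompatibleGraphsError",
    "HistoryUnderflowError",
    "EmptyLayoutError",
    "LayoutCapacityError",
    "SchemaError",
]
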