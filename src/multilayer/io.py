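"""Serialization, fixtures and the demo graph.

Three-file CSV schema
---------------------
A graph serializes to ``<base>_layers.csv`` (``id,name``),
``<base>_nodes.csv`` (``name,layer,<attribute columns>``) and
``<base>_edges.csv`` (``source,target,<attribute columns>``).  Attribute
columns are the sorted union of the attribute keys over all rows; an empty
cell means the attribute is absent on that row (never the empty string).
Files are UTF-8, RFC 4180-quoted, header row always present, rows in
insertion order — so exporting the same graph twice is byte-identical.
Directedness has no slot in the schema and is supplied on import.

CX export
---------
:func:`export_cx` writes the Cytoscape/NDEx CX interchange document: one
JSON array of aspect objects (``metaData``, ``networkAttributes``,
``nodes``, ``edges``, ``nodeAttributes``, ``edgeAttributes``, an optional
``cartesianLayout`` and ``status``).  The layer is stored as a ``layer``
node attribute.  Export only, as CX import is out of scope.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import numpy as np

from .errors import MultilayerError, SchemaError, ValidationError
from .layout import LayoutResult
from .model import MultilayerGraph

_INT_RE = re.compile(r"^[+-]?\d+$")
_FLOAT_RE = re.compile(r"^[+-]?(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?$")


def _format_cell(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _parse_cell(text: str):
    """Invert :func:`_format_cell`: bool, then int, then float, else string."""
    if text == "true":
        return True
    if text == "false":
        return False
    if _INT_RE.match(text):
        return int(text)
    if _FLOAT_RE.match(text):
        return float(text)
    return text


def _write_csv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def export_csv(g: MultilayerGraph, base_path: str | Path) -> tuple[str, str, str]:
    """Write the three CSV files; returns ``(nodes, edges, layers)`` paths."""
    base = Path(base_path)
    layers_path = base.with_name(base.name + "_layers.csv")
    nodes_path = base.with_name(base.name + "_nodes.csv")
    edges_path = base.with_name(base.name + "_edges.csv")

    _write_csv(
        layers_path,
        ["id", "name"],
        [[str(l.id), l.name] for l in g.get_layers()],
    )

    nodes = g.get_nodes()
    node_keys = sorted({k for n in nodes for k in n.attributes})
    layer_name = {l.id: l.name for l in g.get_layers()}
    _write_csv(
        nodes_path,
        ["name", "layer"] + node_keys,
        [
            [n.name, layer_name[n.layer_id]]
            + [_format_cell(n.attributes[k]) if k in n.attributes else "" for k in node_keys]
            for n in nodes
        ],
    )

    edges = g.get_edges()
    edge_keys = sorted({k for e in edges for k in e.attributes})
    _write_csv(
        edges_path,
        ["source", "target"] + edge_keys,
        [
            [e.source, e.target]
            + [_format_cell(e.attributes[k]) if k in e.attributes else "" for k in edge_keys]
            for e in edges
        ],
    )
    return str(nodes_path), str(edges_path), str(layers_path)


def _read_csv(path: str | Path, required: list[str]) -> tuple[list[str], list[dict]]:
    try:
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise SchemaError(f"{path}: missing header row") from None
            rows = [dict(zip(header, row)) for row in reader]
    except OSError as exc:
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    for col in required:
        if col not in header:
            raise SchemaError(f"{path}: required column {col!r} missing")
    return header, rows


def import_csv(
    nodes_path: str | Path,
    edges_path: str | Path,
    layers_path: str | Path,
    name: str,
    directed: bool = False,
) -> MultilayerGraph:
    """Reconstruct a graph from its three CSV files.

    ``import_csv(*export_csv(g))`` is deep-equal to ``g`` up to history
    (history is runtime-only) and up to edge ids, which are reassigned in
    row order.  Referential problems — a node on an unknown layer, an edge
    citing an unknown node, duplicate names, exact duplicate edges — raise
    :class:`SchemaError`.
    """
    _, layer_rows = _read_csv(layers_path, ["id", "name"])
    ids = []
    for row in layer_rows:
        if not _INT_RE.match(row.get("id", "")):
            raise SchemaError(f"{layers_path}: bad layer id {row.get('id')!r}")
        ids.append(int(row["id"]))
    if sorted(ids) != list(range(1, len(ids) + 1)):
        raise SchemaError(f"{layers_path}: layer ids must be exactly 1..{len(ids)}")

    g = MultilayerGraph(name, directed)
    with g._history_suspended():
        for row in sorted(layer_rows, key=lambda r: int(r["id"])):
            try:
                g.add_layer(row["name"])
            except MultilayerError as exc:
                raise SchemaError(f"{layers_path}: {exc}") from exc

        node_header, node_rows = _read_csv(nodes_path, ["name", "layer"])
        attr_cols = [c for c in node_header if c not in ("name", "layer")]
        for row in node_rows:
            attrs = {c: _parse_cell(row[c]) for c in attr_cols if row.get(c, "") != ""}
            try:
                g.add_node(row["name"], row["layer"], attrs)
            except MultilayerError as exc:
                raise SchemaError(f"{nodes_path}: {exc}") from exc

        edge_header, edge_rows = _read_csv(edges_path, ["source", "target"])
        attr_cols = [c for c in edge_header if c not in ("source", "target")]
        for row in edge_rows:
            attrs = {c: _parse_cell(row[c]) for c in attr_cols if row.get(c, "") != ""}
            try:
                g.add_edge(row["source"], row["target"], attrs)
            except MultilayerError as exc:
                raise SchemaError(f"{edges_path}: {exc}") from exc
    return g


# --------------------------------------------------------------------- CX ---

def _cx_value(value):
    if isinstance(value, bool):
        return ("boolean", "true" if value else "false")
    if isinstance(value, int):
        return ("integer", str(value))
    if isinstance(value, float):
        return ("double", repr(value))
    return ("string", value)


def build_cx(g: MultilayerGraph, layout: LayoutResult | None = None) -> list[dict]:
    """Assemble the CX document (a list of single-aspect objects) in memory."""
    node_id = {n.name: i for i, n in enumerate(g.get_nodes())}
    layer_name = {l.id: l.name for l in g.get_layers()}

    nodes_aspect = [{"@id": i, "n": name} for name, i in node_id.items()]
    edges_aspect = [
        {"@id": i, "s": node_id[e.source], "t": node_id[e.target]}
        for i, e in enumerate(g.get_edges())
    ]

    node_attrs = []
    for n in g.get_nodes():
        node_attrs.append({"po": node_id[n.name], "n": "layer", "v": layer_name[n.layer_id]})
        for key, value in n.attributes.items():
            dtype, text = _cx_value(value)
            node_attrs.append({"po": node_id[n.name], "n": key, "v": text, "d": dtype})

    edge_attrs = []
    for i, e in enumerate(g.get_edges()):
        for key, value in e.attributes.items():
            dtype, text = _cx_value(value)
            edge_attrs.append({"po": i, "n": key, "v": text, "d": dtype})

    network_attrs = [
        {"n": "name", "v": g.name},
        {"n": "directed", "v": "true" if g.directed else "false", "d": "boolean"},
    ]

    aspects: list[tuple[str, list]] = [
        ("networkAttributes", network_attrs),
        ("nodes", nodes_aspect),
        ("edges", edges_aspect),
        ("nodeAttributes", node_attrs),
        ("edgeAttributes", edge_attrs),
    ]
    if layout is not None:
        cart = []
        for name, i in node_id.items():
            if name not in layout.coords:
                raise ValidationError(f"layout does not cover node {name!r}")
            c = layout.coords[name]
            entry = {"node": i, "x": float(c[0]), "y": float(c[1])}
            if len(c) == 3:
                entry["z"] = float(c[2])
            cart.append(entry)
        aspects.append(("cartesianLayout", cart))

    meta = [{"name": name, "elementCount": len(elems)} for name, elems in aspects]
    doc: list[dict] = [{"metaData": meta}]
    doc += [{name: elems} for name, elems in aspects]
    doc.append({"status": [{"error": "", "success": True}]})
    return doc


def export_cx(
    g: MultilayerGraph, path: str | Path, layout: LayoutResult | None = None
) -> str:
    """Write the CX JSON document; include coordinates if a layout is given."""
    doc = build_cx(g, layout)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
    return str(path)


def validate_cx(doc) -> list[str]:
    """Internal-consistency check of a CX document; returns a list of problems.

    Verifies the document shape, that ``metaData`` element counts match the
    actual aspect lengths, that every edge references declared node ids, and
    that every node carries exactly one ``layer`` node attribute.
    """
    problems: list[str] = []
    if not isinstance(doc, list) or not all(isinstance(a, dict) for a in doc):
        return ["document is not a JSON array of aspect objects"]
    aspects: dict[str, list] = {}
    for obj in doc:
        for key, val in obj.items():
            aspects.setdefault(key, []).extend(val)

    for entry in aspects.get("metaData", []):
        name, declared = entry.get("name"), entry.get("elementCount")
        actual = len(aspects.get(name, []))
        if declared != actual:
            problems.append(f"metaData declares {declared} {name} elements, found {actual}")

    node_ids = {n.get("@id") for n in aspects.get("nodes", [])}
    for e in aspects.get("edges", []):
        for end in ("s", "t"):
            if e.get(end) not in node_ids:
                problems.append(f"edge {e.get('@id')} references undeclared node {e.get(end)}")

    layer_count: dict = {i: 0 for i in node_ids}
    for a in aspects.get("nodeAttributes", []):
        if a.get("n") == "layer":
            layer_count[a.get("po")] = layer_count.get(a.get("po"), 0) + 1
    for nid, count in layer_count.items():
        if count != 1:
            problems.append(f"node {nid} has {count} 'layer' attributes (expected 1)")

    status = aspects.get("status", [])
    if not status or not status[0].get("success", False):
        problems.append("missing or unsuccessful status aspect")
    return problems


# ---------------------------------------------------------------- fixtures ---

def demo_graph() -> MultilayerGraph:
    """The canonical three-layer example: diseases, drugs and genes.

    An undirected graph with disease-gene associations, drug targets, one
    drug indication and one intra-layer gene-gene interaction.  Built
    deterministically with an empty history, like an imported graph.
    """
    g = MultilayerGraph("demo", directed=False)
    with g._history_suspended():
        for layer in ("disease", "drug", "gene"):
            g.add_layer(layer)
        g.add_node("asthma", "disease", {"type": "chronic"})
        g.add_node("influenza", "disease")
        g.add_node("salbutamol", "drug", {"group": "SABA"})
        g.add_node("oseltamivir", "drug")
        g.add_node("ADRB2", "gene")
        g.add_node("IL13", "gene")
        g.add_node("TNF", "gene")
        g.add_edge("asthma", "ADRB2")
        g.add_edge("asthma", "IL13", {"evidence": "GWAS"})
        g.add_edge("influenza", "TNF")
        g.add_edge("salbutamol", "ADRB2", {"mechanism": "agonist"})
        g.add_edge("salbutamol", "asthma", {"indication": True})
        g.add_edge("IL13", "TNF")  # intra-layer interaction
    return g


def random_multilayer(
    n_layers: int,
    nodes_per_layer: int,
    edge_prob: float,
    directed: bool = False,
    seed: int = 0,
) -> MultilayerGraph:
    """Seeded Erdős–Rényi-style multilayer fixture.

    Layers ``L1..Lk`` each get ``nodes_per_layer`` nodes; every distinct
    node pair (ordered if directed) gains an edge independently with
    probability ``edge_prob``.  A quarter of the nodes and of the edges
    carry a small scalar attribute so serialization round-trips are
    exercised.  Reproducible by seed; history starts empty.
    """
    if not isinstance(n_layers, int) or n_layers < 1:
        raise ValidationError("n_layers must be a positive integer")
    if not isinstance(nodes_per_layer, int) or nodes_per_layer < 1:
        raise ValidationError("nodes_per_layer must be a positive integer")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValidationError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = MultilayerGraph(f"random-{seed}", directed)
    with g._history_suspended():
        names = []
        for i in range(1, n_layers + 1):
            g.add_layer(f"L{i}")
            for j in range(1, nodes_per_layer + 1):
                node = f"L{i}n{j}"
                attrs = {}
                if rng.random() < 0.25:
                    attrs["score"] = float(np.round(rng.random(), 6))
                g.add_node(node, f"L{i}", attrs)
                names.append(node)
        for a_i, u in enumerate(names):
            for w in (names if directed else names[a_i + 1 :]):
                if u == w:
                    continue
                if rng.random() < edge_prob:
                    attrs = {}
                    if rng.random() < 0.25:
                        attrs["weight"] = float(np.round(rng.random(), 6))
                    g.add_edge(u, w, attrs)
    return g
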