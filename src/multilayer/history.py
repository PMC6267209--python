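"""Modification history and undo.

Every mutating operation on a :class:`~multilayer.model.MultilayerGraph`
appends one :class:`ChangeRecord`.  A record stores a full snapshot of the
pre-operation state (layers, nodes, edges with their ids and attributes), so
compound operations — transitive node removal, layer removal — invert
atomically without re-deriving any plan, and ``undo(k)`` restores the state
from ``k`` steps ago exactly.  Graphs here are desk-scale, so full snapshots
trade memory for unconditional correctness.

The chronology doubles as the documentation of a *view*: the sequence of
modifications that produced the current graph from its origin, exportable as
a plain-text log.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from datetime import datetime, timezone

from .errors import HistoryUnderflowError, ValidationError

#: the only operations that enter history; queries never do
MUTATING_OPS = (
    "add_layer",
    "remove_layer",
    "add_node",
    "remove_node",
    "add_edge",
    "remove_edge",
    "remove_node_transitive",
    "merge",
)


@dataclass
class GraphState:
    """Full snapshot of a graph's entities (history excluded)."""

    name: str
    directed: bool
    layers: list
    nodes: dict
    edges: dict
    next_edge_id: int


@dataclass
class ChangeRecord:
    """One invertible mutation.

    ``inverse_payload`` is the pre-operation :class:`GraphState`, or ``None``
    for a merge origin, which cannot be undone into its parent graphs.
    """

    sequence_no: int
    op_tag: str
    timestamp: str
    description: str
    inverse_payload: GraphState | None


def capture_state(g) -> GraphState:
    """Deep-copy the graph's entities into a snapshot."""
    return GraphState(
        name=g.name,
        directed=g.directed,
        layers=copy.deepcopy(g._layers),
        nodes=copy.deepcopy(g._nodes),
        edges=copy.deepcopy(g._edges),
        next_edge_id=g._next_edge_id,
    )


def restore_state(g, state: GraphState) -> None:
    """Overwrite the graph's entities with (a copy of) the snapshot."""
    g.name = state.name
    g.directed = state.directed
    g._layers = copy.deepcopy(state.layers)
    g._nodes = copy.deepcopy(state.nodes)
    g._edges = copy.deepcopy(state.edges)
    g._next_edge_id = state.next_edge_id


def make_record(g, op_tag: str, description: str, pre_state: GraphState | None) -> ChangeRecord:
    if op_tag not in MUTATING_OPS:
        raise ValidationError(f"unknown operation tag {op_tag!r}")
    return ChangeRecord(
        sequence_no=(g._history[-1].sequence_no + 1) if g._history else 1,
        op_tag=op_tag,
        timestamp=datetime.now(timezone.utc).isoformat(),
        description=description,
        inverse_payload=pre_state,
    )


def undo(g, steps: int = 1):
    """Revert the last ``steps`` mutations, popping their records.

    Compound records (transitive removal, layer removal, and the merge-origin
    record) count as single steps; the merge origin itself is not invertible
    and undoing across it raises :class:`HistoryUnderflowError`.
    """
    if not isinstance(steps, int) or steps < 1:
        raise ValidationError("steps must be a positive integer")
    if steps > len(g._history):
        raise HistoryUnderflowError(
            f"cannot undo {steps} step(s): history depth is {len(g._history)}"
        )
    target = g._history[-steps]
    if target.inverse_payload is None:
        raise HistoryUnderflowError(
            "cannot undo across a merge origin: the merged graph has no parent state"
        )
    restore_state(g, target.inverse_payload)
    del g._history[-steps:]
    return g


def get_history(g) -> list[tuple[int, str, str]]:
    """Read-only chronology: ``(sequence_no, op_tag, description)`` per record."""
    return [(r.sequence_no, r.op_tag, r.description) for r in g._history]


def export_history_log(g, path) -> str:
    """Write the chronology as a plain-text log, one record per line."""
    lines = [
        f"{r.sequence_no}\t{r.timestamp}\t{r.op_tag}\t{r.description}"
        for r in g._history
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return str(path)
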