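"""Exception hierarchy for multilayer graphs.

Every error raised by the library derives from :class:`MultilayerError`,
so callers (and the CLI) can catch one base class.
"""


class MultilayerError(Exception):
    """Base class for all multilayer-graph errors."""


class ValidationError(MultilayerError):
    """A precondition on an argument was violated (empty name, bad type, ...)."""


class NotFoundError(MultilayerError):
    """A referenced layer, node or edge does not exist."""


class DuplicateLayerError(MultilayerError):
    """Layer name already present (case-insensitive comparison)."""


class DuplicateNodeError(MultilayerError):
    """Node name already present somewhere in the graph."""


class DuplicateEdgeError(MultilayerError):
    """An edge with identical endpoints and identical attributes exists."""


class AmbiguousEdgeError(MultilayerError):
    """An edge selector matched several parallel edges but multi=False."""


class LayerConflictError(MultilayerError):
    """The same node name sits on different layers in the two merge inputs."""


class IncompatibleGraphsError(MultilayerError):
    """Graphs cannot be combined (e.g. directed with undirected)."""


class HistoryUnderflowError(MultilayerError):
    """More undo steps requested than invertible history records exist."""


class EmptyLayoutError(MultilayerError):
    """Layout requested for a graph without any layer."""


class LayoutCapacityError(MultilayerError):
    """Random layout could not satisfy the minimum node separation.

    Raised after the per-layer resampling budget is exhausted; the scaled
    layout always succeeds and is the suggested fallback.
    """


class SchemaError(MultilayerError):
    """A CSV file violates the three-file schema (bad reference, duplicate, ...)."""
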