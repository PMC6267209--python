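# Methods

## Model and assumptions

The container is a layered-disjoint node-colored graph: a finite set of
named layers (1-based ids in assignment order), nodes each bound to
exactly one layer, and attributed edges within or between layers. The
whole graph is directed or undirected; this is fixed at construction.
Modelling choices that the container enforces:

* **Node identity is the name string, unique graph-wide** (not merely
  within a layer). Merging and CSV serialization index nodes by name, so
  per-layer duplicates would make both ill-defined.
* **Layer names are unique case-insensitively**; lookups are forgiving
  but the stored spelling is preserved. After a layer removal the
  surviving ids are compacted to `1..k` preserving relative order, so the
  layer enumeration stays contiguous for layouts and serialization.
* **Parallel edges are allowed iff their attribute maps differ.**
  Attribute-map identity is key-set plus exact value equality, with
  booleans distinguished from 0/1. This gives merge deduplication and
  `remove_edge` a well-defined edge identity.
* **Self-loops are rejected**: they are undefined under transitive
  deletion and add nothing to a layered model.
* **Attribute values are scalars** (string / number / boolean), never
  nested, so CSV and CX round-trips are lossless. The keys `name`,
  `layer`, `source`, `target` are reserved by the CSV schema and rejected
  on entities.
* Mutating methods work in place and return the graph; callers must treat
  the returned value as the current graph.

## Transitive deletion

When node *v* is removed with the transitive option, shortcuts are
planned from v's **direct** neighbours only: directed, `u → w` for every
in-neighbour *u* and out-neighbour *w* with `u ≠ w`; undirected, an edge
for every unordered pair of distinct neighbours. A shortcut is skipped
when *any* edge already joins its endpoints — an existing connection
already carries the route, and inserting a parallel provenance edge would
accumulate clutter under repeated deletions. Planned edges carry the
single attribute `{via: v}`; no attribute algebra merges the two parent
edges' maps, by design — provenance is deterministic and lossless.

One hop suffices: every through-path of length 2 is replaced before the
node disappears, so the reachability relation on the survivors is
unchanged, and by induction stays unchanged under sequential removals
(the whole-layer deletion case). The test suite verifies this against an
independent oracle — transitive closure by BFS from every node, computed
with networkx — on seeded random graphs, directed and undirected.

Plan application plus node removal is a single atomic history step.

## Merge

`merge(g1, g2)` requires equal directedness. Layers match by **name**
(ids are graph-local), nodes by name, edges by (endpoints, attributes).
Shared nodes keep the attribute union with **g1 winning conflicts** — a
deterministic, documented choice; order sensitivity is tested and stated.
A node name that sits on differently named layers in the two inputs is an
error, never a silent reassignment, since that would corrupt the
layer-disjointness audit trail. The result starts a fresh history whose
first record documents the merge; it cannot be undone into the parents.

## History and undo

Every mutating operation (eight tags: add/remove layer, node, edge,
transitive removal, merge) appends a change record holding a **full
snapshot of the pre-operation entities** — layers, nodes, edges, ids —
rather than operation parameters, so compound operations invert without
re-deriving plans. Graphs here are desk-scale (hundreds to thousands of
entities), so the memory cost is accepted for unconditional correctness.
Undo is a linear stack: no redo, no branching. Queries never enter
history. History is runtime-only; it is not serialized with the graph
(the three-file CSV schema has no slot for it) but can be exported as a
plain-text log, which together with the origin graph documents a *view*.

## Layouts

The geometry is this package's concrete choice of "each layer occupies
its own range": in 2D, layer *i* of *k* owns the horizontal band
`y ∈ [i−1+m, i−m]` with margin `m = 0.1` (unit-height bands, disjoint by
construction, stacked by layer id); in 3D, layer *i* is the plane
`z = i`. Within a band:

* **scaled** — node *j* of *nᵢ* (insertion order; stable under renames)
  gets `x = (j − 0.5)/nᵢ` at the band midpoint, or a centered square grid
  of side `⌈√nᵢ⌉` with unit spacing in 3D. Pure arithmetic, no RNG:
  repeated calls are bit-identical and vertices can never overlap.
* **random** — positions drawn uniformly inside the band from a
  caller-supplied seed (default 42), with rejection resampling until all
  within-layer pairs are ≥ ε = 0.05 apart, up to 1000 rejections per
  layer; exhaustion raises a capacity error that recommends the scaled
  layout rather than overlapping silently.

Rendering is strictly presentational (matplotlib; an `.html` target wraps
the SVG in a standalone page). It consumes precomputed coordinates and
computes none.

## Serialization

CSV: three files — `<base>_layers.csv` (`id,name`), `<base>_nodes.csv`
(`name,layer,…`), `<base>_edges.csv` (`source,target,…`) — UTF-8,
RFC 4180, header always present, rows in insertion order, attribute
columns the sorted union of keys, empty cell ⇔ attribute absent. Export
is byte-deterministic. Directedness is not representable in the schema
and is a required import parameter. Import re-assigns edge ids in row
order, so round-trip equality is defined modulo history and edge ids.
Typed values are recovered by inference (`true`/`false` → boolean, then
integer, then float, else string); consequently a *string* attribute that
itself spells a number or boolean would re-import as the parsed type —
the one known lossy corner, avoided by the fixtures and documented here.

CX: a JSON array of aspects — `metaData`, `networkAttributes`, `nodes`,
`edges`, `nodeAttributes`, `edgeAttributes`, optional `cartesianLayout`,
`status` — with numeric ids assigned in insertion order from 0 and the
layer stored as a `layer` node attribute. Export only. Internal
consistency (metaData counts, endpoint references, exactly one layer
attribute per node) is checked by `validate_cx`, a small purpose-built
validator. Cytoscape visual-style aspects are out of scope.

## Synthetic fixtures

`random_multilayer(n_layers, nodes_per_layer, edge_prob, directed, seed)`
is an Erdős–Rényi-style generator: every distinct node pair (ordered if
directed) gains an edge independently with probability `edge_prob`; a
quarter of nodes and edges carry a small scalar attribute so
serialization is exercised with sparse, typed columns. `demo_graph()` is
a fixed, documented disease/drug/gene example with intra- and inter-layer
and attributed edges. Both build with an empty history, like imported
graphs.

What these fixtures emulate is the *structure* of integrated pathway-style
networks — typed node classes, sparse within- and between-layer edges,
sparse scalar annotations. They do not emulate real pathway semantics:
degree heterogeneity, hub genes, curated edge directionality or database
identifier conventions. Passing tests therefore certify the graph
mechanics (reachability preservation, merge laws, round-trips), not any
biological conclusion drawn from a particular data source.

## Problem sizes and numerical choices

The verification suites use 3-layer × 10-node graphs at edge probability
0.15 (about 65–130 edges directed) for reachability checks — 100 graphs
with every node deleted in turn — 50 seeds for whole-layer deletion, 100
random mutation sequences of up to 20 operations for undo, and 100
graphs for serialization and layout checks; these sizes give thousands
of independent cases while the whole suite stays in the tens of seconds.
All comparisons are exact (set equality, deep equality, byte equality):
no tolerances are involved anywhere except the layout separation ε,
which is a constraint, not a comparison.

## Known limitations

* No redo or branching version trees; undo is strictly linear.
* Merge takes exactly two graphs; fold to combine more.
* No fuzzy/similarity-based node matching across sources — names must
  agree exactly.
* CX is export-only; GraphML/SIF/SBML and NDEx transfer are out of scope.
* Layouts are banded only; no force-directed or crossing-minimizing
  variant.
* Edge-colored multilayer semantics (nodes replicated across layers, one
  edge type per layer) are a different model and are not supported.
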