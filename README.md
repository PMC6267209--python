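# multilayer

Layered-disjoint, node-colored multilayer graphs for integrating
heterogeneous biomedical networks — diseases, drugs, genes, pathways —
into one structure, with the editing operations such integration needs:
**transitivity-preserving deletion**, **layer-based merging**, a
**documented undo history**, **layer-banded 2D/3D layouts**, and
**CSV / Cytoscape-CX serialization**.

## The model

A multilayer graph here is a node-colored graph (NCG): the vertex set *V*
is partitioned into *n* layers *V = V₁ ∪ … ∪ Vₙ* (each node belongs to
exactly one layer — "layer-disjoint"), and edges may connect nodes within
a layer (intra-layer) or across layers (inter-layer). The graph is
directed or undirected as a whole; parallel edges between the same
endpoints are allowed when their attribute maps differ.

Two operations carry the substance:

* **Transitive deletion.** Removing a node *v* would break every route
  that passes through it. With the transitive option, a shortcut edge
  *u → w* is first inserted for every in-neighbour *u* and out-neighbour
  *w* of *v* (a clique on the neighbours in the undirected case), each
  tagged `{via: v}`, unless the endpoints are already connected. Since
  every length-2 through-path is replaced, the reachability relation on
  the surviving nodes is exactly preserved — and stays preserved under
  sequential removals, e.g. deleting a whole layer.
* **Layer-based merge.** Two graphs combine by matching layers by name,
  nodes by name (attribute union, first argument wins conflicts) and
  edges by (endpoints, attributes), so content replicated across sources
  appears once in the result.

Every mutation is recorded as an invertible change record; `undo(k)`
restores the state from *k* steps ago, and the chronology documents the
*view* — the modification sequence that produced the current graph.

## Worked example

```python
import multilayer as ml

g = ml.demo_graph()              # 3 layers: disease, drug, gene
print(g.summary())

g.add_node("zanamivir", "drug")
g.add_edge("zanamivir", "influenza", {"indication": True})
ml.remove_node_transitive(g, "TNF")   # delete the gene, keep its routes
for e in g.get_edges(node="influenza"):
    print(e.source, "--", e.target, e.attributes)

for rec in g.get_history():
    print(rec)
g.undo(3)                        # back to the pristine demo graph
```

prints

```
demo: undirected multilayer graph with 3 layer(s)
  layer 1 'disease': 2 node(s)
  layer 2 'drug': 2 node(s)
  layer 3 'gene': 3 node(s)
  6 edge(s) total
zanamivir -- influenza {'indication': True}
influenza -- IL13 {'via': 'TNF'}
(1, 'add_node', "add node 'zanamivir' to layer 'drug'")
(2, 'add_edge', "add edge 'zanamivir'->'influenza'")
(3, 'remove_node_transitive', "remove node 'TNF' (trans=True)")
```

The `{'via': 'TNF'}` edge is the transitive shortcut: influenza was
associated with TNF, TNF interacted with IL13, so after deleting TNF the
influenza–IL13 route survives as a direct edge with its provenance
recorded. `undo(3)` restores the original 7-node, 6-edge demo graph.

A scaled 2D layout places each layer in its own horizontal band and
divides the band evenly among its nodes — e.g. `salbutamol`, first of two
drug-layer nodes, sits at `(0.25, 1.5)`, the midpoint of band 2:

```python
ml.render(g, ml.layout_scaled(g, dims=2), "demo.png")
```

## Command line

```bash
multilayer demo --out d                  # write d_{nodes,edges,layers}.csv
multilayer info --base d
multilayer random --layers 3 --nodes-per-layer 5 --p 0.2 --seed 1 --out r
multilayer merge --a d --b r --out m
multilayer layout --base d --kind scaled3d --out d.html
multilayer export-cx --base d --out d.cx --with-layout scaled2d
```

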