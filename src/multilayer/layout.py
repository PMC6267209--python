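"""Layer-banded layouts and rendering.

Each layer occupies its own horizontal band (2D) or horizontal plane (3D),
stacked by layer id, so nodes of one layer always sit in "a range of similar
numbers" and bands of distinct layers never overlap.  Two placement
variants exist inside a band:

* *scaled* — deterministic: the band is divided evenly among its nodes, so
  vertices can never overlap;
* *random* — seeded uniform positions with rejection resampling until every
  within-layer pair is at least ``epsilon`` apart.

Band geometry (2D): layer ``i`` of ``k`` owns ``y in [i-1+m, i-m]`` with
margin ``m = 0.1``; scaled x-positions are ``(j - 0.5)/n_i`` for the
``j``-th of ``n_i`` nodes in insertion order, at the band's midpoint.
Geometry (3D): layer ``i`` is the plane ``z = i``; scaled nodes sit on a
centered square grid of side ``ceil(sqrt(n_i))`` with unit spacing.

Rendering is purely presentational: it consumes a precomputed
:class:`LayoutResult` and writes an image (or, for ``.html`` paths, a
standalone page embedding the SVG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyLayoutError, LayoutCapacityError, ValidationError
from .model import MultilayerGraph

#: vertical margin between a band edge and the layer boundary
BAND_MARGIN = 0.1
#: minimum within-layer pairwise separation for random layouts (band-height units)
EPSILON = 0.05
#: per-layer resampling budget before a capacity error
MAX_RESAMPLES = 1000


@dataclass
class LayoutResult:
    """Per-node coordinates plus the band/plane each layer occupies.

    ``coords`` maps node name to ``(x, y)`` or ``(x, y, z)``;
    ``layer_bands`` maps layer id to the closed interval of the stacking
    axis (y in 2D, z in 3D — a degenerate ``(z, z)`` interval) it owns.
    """

    kind: str
    seed: int | None
    coords: dict[str, tuple] = field(default_factory=dict)
    layer_bands: dict[int, tuple] = field(default_factory=dict)

    @property
    def dims(self) -> int:
        return 3 if self.kind.endswith("3d") else 2


def _per_layer_nodes(g: MultilayerGraph) -> list[tuple[int, list[str]]]:
    if not g.get_layers():
        raise EmptyLayoutError("cannot lay out a graph without layers")
    layers = []
    for layer in g.get_layers():
        names = [n.name for n in g.get_nodes(layer.name)]
        layers.append((layer.id, names))
    return layers


def _check_dims(dims: int) -> None:
    if dims not in (2, 3):
        raise ValidationError("dims must be 2 or 3")


def layout_scaled(g: MultilayerGraph, dims: int = 2) -> LayoutResult:
    """Deterministic overlap-free layout dividing each band among its nodes."""
    _check_dims(dims)
    result = LayoutResult(kind=f"scaled{dims}d", seed=None)
    for lid, names in _per_layer_nodes(g):
        n = len(names)
        if dims == 2:
            result.layer_bands[lid] = (lid - 1 + BAND_MARGIN, lid - BAND_MARGIN)
            y_mid = lid - 0.5
            for j, name in enumerate(names, start=1):
                result.coords[name] = ((j - 0.5) / n if n else 0.0, y_mid)
        else:
            result.layer_bands[lid] = (float(lid), float(lid))
            side = max(1, math.ceil(math.sqrt(n))) if n else 1
            offset = (side - 1) / 2.0
            for j, name in enumerate(names):
                row, col = divmod(j, side)
                result.coords[name] = (col - offset, row - offset, float(lid))
    return result


def _sample_layer(rng, n: int, lows, highs) -> list[tuple]:
    """Uniform points in a box with pairwise separation >= EPSILON."""
    points: list[tuple] = []
    budget = MAX_RESAMPLES
    while len(points) < n:
        candidate = tuple(rng.uniform(lo, hi) for lo, hi in zip(lows, highs))
        if all(
            math.dist(candidate, p) >= EPSILON for p in points
        ):
            points.append(candidate)
        else:
            budget -= 1
            if budget <= 0:
                raise LayoutCapacityError(
                    f"could not place {n} nodes at separation {EPSILON} within the "
                    "layer band; use the scaled layout instead"
                )
    return points


def layout_random(g: MultilayerGraph, dims: int = 2, seed: int = 42) -> LayoutResult:
    """Seeded random placement inside the same bands/planes as the scaled layout.

    Positions are uniform within the band; candidates closer than ``EPSILON``
    to an already placed node of the same layer are resampled, up to
    ``MAX_RESAMPLES`` rejections per layer.
    """
    _check_dims(dims)
    rng = np.random.default_rng(seed)
    result = LayoutResult(kind=f"random{dims}d", seed=seed)
    for lid, names in _per_layer_nodes(g):
        n = len(names)
        if dims == 2:
            lo, hi = lid - 1 + BAND_MARGIN, lid - BAND_MARGIN
            result.layer_bands[lid] = (lo, hi)
            points = _sample_layer(rng, n, (0.0, lo), (1.0, hi))
            for name, (x, y) in zip(names, points):
                result.coords[name] = (x, y)
        else:
            result.layer_bands[lid] = (float(lid), float(lid))
            half = max(1, math.ceil(math.sqrt(n))) / 2.0
            points = _sample_layer(rng, n, (-half, -half), (half, half))
            for name, (x, y) in zip(names, points):
                result.coords[name] = (x, y, float(lid))
    return result


def _layer_colors(k: int):
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap("tab10")
    return {i + 1: cmap(i % 10) for i in range(k)}


def render(g: MultilayerGraph, layout: LayoutResult, path: str | Path) -> str:
    """Draw the graph at the given coordinates and write an image file.

    2D layouts become a static figure with shaded, labelled layer bands,
    edges as lines and nodes coloured by layer; 3D layouts become a static
    3D scene with one translucent plane per layer.  A path ending in
    ``.html`` yields a standalone page embedding the figure as SVG.  No
    coordinates are computed here.
    """
    missing = [n.name for n in g.get_nodes() if n.name not in layout.coords]
    if missing:
        raise ValidationError(f"layout does not cover node(s): {missing}")
    path = Path(path)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    layers = g.get_layers()
    colors = _layer_colors(len(layers))
    node_layer = {n.name: n.layer_id for n in g.get_nodes()}
    fig = plt.figure(figsize=(7, max(4, 1.8 * len(layers))))

    if layout.dims == 2:
        ax = fig.add_subplot(111)
        for layer in layers:
            lo, hi = layout.layer_bands[layer.id]
            ax.axhspan(lo, hi, color=colors[layer.id], alpha=0.12)
            ax.text(1.01, (lo + hi) / 2, layer.name, va="center", fontsize=9)
        for e in g.get_edges():
            x0, y0 = layout.coords[e.source][:2]
            x1, y1 = layout.coords[e.target][:2]
            ax.plot([x0, x1], [y0, y1], color="0.5", lw=0.8, zorder=1)
        for name, xy in layout.coords.items():
            ax.scatter(*xy[:2], color=colors[node_layer[name]], s=60, zorder=2)
            if len(layout.coords) <= 40:
                ax.annotate(name, xy[:2], fontsize=7, xytext=(2, 4),
                            textcoords="offset points")
        ax.set_xlim(-0.05, 1.15)
        ax.set_yticks([])
        ax.set_title(g.name)
    else:
        ax = fig.add_subplot(111, projection="3d")
        xs = [c[0] for c in layout.coords.values()] or [0]
        ys = [c[1] for c in layout.coords.values()] or [0]
        pad = 0.5
        x0, x1 = min(xs) - pad, max(xs) + pad
        y0, y1 = min(ys) - pad, max(ys) + pad
        for layer in layers:
            z = layout.layer_bands[layer.id][0]
            xx, yy = np.meshgrid([x0, x1], [y0, y1])
            ax.plot_surface(xx, yy, np.full_like(xx, z, dtype=float),
                            color=colors[layer.id], alpha=0.15)
            ax.text(x1, y1, z, layer.name, fontsize=9)
        for e in g.get_edges():
            a, b = layout.coords[e.source], layout.coords[e.target]
            ax.plot([a[0], b[0]], [a[1], b[1]], [a[2], b[2]], color="0.5", lw=0.8)
        for name, c in layout.coords.items():
            ax.scatter(c[0], c[1], c[2], color=colors[node_layer[name]], s=50)
        ax.set_zticks([layer.id for layer in layers])
        ax.set_title(g.name)

    if path.suffix.lower() == ".html":
        import io as _io

        buf = _io.StringIO()
        fig.savefig(buf, format="svg")
        html = (
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>{g.name}</title></head><body>\n{buf.getvalue()}\n</body></html>\n"
        )
        path.write_text(html, encoding="utf-8")
    else:
        fig.savefig(path)
    plt.close(fig)
    return str(path)
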