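"""Heat trees: quantitative tree visualization of per-taxon statistics.

A heat tree draws a taxonomic forest with up to four statistics mapped onto
node size, node color, edge size and edge color, with quantitative legends.
Raw statistics are translated automatically: an affine map onto a size range
chosen to keep node discs from overlapping, and piecewise-linear palette
interpolation for color.  Forests with several roots are drawn as one
sub-tree per root arranged on a near-square grid.

All geometry is computed in normalized [0,1] x [0,1] figure units (y up), so
the picture is identical at any output size.  SVG output is written directly
from the display list (deterministic byte-for-byte); PNG/PDF are drawn from
the same display list through matplotlib.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Taxmap, TaxmapError

DEFAULT_PALETTE = ("#440154", "#21918c", "#fde725")  # viridis-like anchors
DIVERGING_PALETTE = ("#1b7837", "#f7f7f7", "#8c510a")  # green .. brown
_FLAT_NODE = "#808080"
_FLAT_EDGE = "#b0b0b0"

_TRANSFORMS = {
    "identity": (lambda v: v, lambda v: v),
    "log10": (np.log10, lambda v: np.power(10.0, v)),
    "sqrt": (np.sqrt, np.square),
}


def _apply_transform(values: np.ndarray, transform: str, what: str) -> np.ndarray:
    if transform not in _TRANSFORMS:
        raise TaxmapError(f"unknown transform {transform!r}; expected one of {sorted(_TRANSFORMS)}")
    v = np.asarray(values, dtype=float)
    if transform == "log10" and np.any(v <= 0):
        bad = np.nonzero(v <= 0)[0]
        raise TaxmapError(f"log10 transform of non-positive {what} value(s) at rows {bad[:5].tolist()}")
    if transform == "sqrt" and np.any(v < 0):
        bad = np.nonzero(v < 0)[0]
        raise TaxmapError(f"sqrt transform of negative {what} value(s) at rows {bad[:5].tolist()}")
    out = _TRANSFORMS[transform][0](v)
    if np.any(~np.isfinite(out)):
        bad = np.nonzero(~np.isfinite(out))[0]
        raise TaxmapError(f"non-finite {what} value(s) after transform at rows {bad[:5].tolist()}")
    return out


def map_aesthetic(values, out_interval: Sequence[float], transform: str = "identity",
                  interval: Sequence[float] | None = None) -> np.ndarray:
    """Affine-map (transformed) values onto ``[lo, hi]``.

    The source range is the data range after ``transform``, or the explicit
    ``interval`` (given in raw value units); with an explicit interval,
    values outside it clamp to the endpoints.  A constant column maps to the
    interval midpoint.  The map is monotone non-decreasing.
    """
    lo, hi = float(out_interval[0]), float(out_interval[1])
    tv = _apply_transform(values, transform, "aesthetic")
    if interval is not None:
        dlo, dhi = _apply_transform(np.asarray(interval, dtype=float), transform, "interval")
        tv = np.clip(tv, dlo, dhi)
    else:
        dlo, dhi = float(np.min(tv)), float(np.max(tv))
    if dhi == dlo:
        return np.full(tv.shape, (lo + hi) / 2.0)
    return lo + (tv - dlo) * (hi - lo) / (dhi - dlo)


def _to_rgb(color) -> tuple[float, float, float]:
    from matplotlib.colors import to_rgb

    return to_rgb(color)


def _hex(rgb: Sequence[float]) -> str:
    r, g, b = (int(round(max(0.0, min(1.0, c)) * 255)) for c in rgb)
    return f"#{r:02x}{g:02x}{b:02x}"


def map_color(values, palette: Sequence = DEFAULT_PALETTE,
              interval: Sequence[float] | None = None,
              transform: str = "identity") -> list[str]:
    """Map values to hex colors by piecewise-linear palette interpolation.

    Palette anchors are spaced evenly over the value interval (data range by
    default); with an odd anchor count the middle anchor therefore sits at
    the interval midpoint, which is what a diverging palette wants.  Values
    outside an explicit ``interval`` clamp to the end colors.
    """
    if len(palette) < 2:
        raise TaxmapError("palette needs at least 2 colors")
    anchors = np.array([_to_rgb(c) for c in palette])
    pos = map_aesthetic(values, (0.0, 1.0), transform=transform, interval=interval)
    n_seg = len(anchors) - 1
    out = []
    for p in pos:
        x = min(max(p, 0.0), 1.0) * n_seg
        i = min(int(math.floor(x)), n_seg - 1)
        f = x - i
        rgb = anchors[i] * (1 - f) + anchors[i + 1] * f
        out.append(_hex(rgb))
    return out


# ---------------------------------------------------------------------- layout
@dataclass
class TreeLayout:
    """2-D coordinates for every taxon, one tree per root."""

    coords: dict[str, tuple[float, float]]
    edges: list[tuple[str, str]]  # (parent, child)
    roots: list[str]
    tree_of: dict[str, str]  # taxon -> its root
    bbox: dict[str, tuple[float, float, float, float]]  # root -> (xmin, ymin, xmax, ymax)


def layout_tree(tm: Taxmap, algorithm: str = "reingold-tilford", seed: int = 0) -> TreeLayout:
    """Compute per-root node coordinates.

    ``reingold-tilford``: deterministic layered layout — leaves get
    consecutive x slots (taxon-table row order), internal nodes sit at the
    mean x of their children, y is the negated depth.  Subtrees occupy
    disjoint leaf intervals, so subtree extents never overlap.

    ``fruchterman-reingold``: force-directed refinement (networkx
    spring_layout) seeded from the layered layout; deterministic given
    ``seed``.
    """
    if algorithm not in ("reingold-tilford", "fruchterman-reingold"):
        raise TaxmapError(f"unknown layout algorithm {algorithm!r}")
    idx = tm._index()
    coords: dict[str, tuple[float, float]] = {}
    edges: list[tuple[str, str]] = []
    roots = tm.roots()
    tree_of: dict[str, str] = {}
    bbox: dict[str, tuple[float, float, float, float]] = {}

    for root in roots:
        # iterative post-order so deep chains cannot hit the recursion limit
        depth = {root: 0}
        order: list[str] = []
        stack = [root]
        while stack:
            t = stack.pop()
            order.append(t)
            for c in reversed(idx.children[t]):
                depth[c] = depth[t] + 1
                stack.append(c)
        x: dict[str, float] = {}
        next_slot = 0
        for t in reversed(order):  # children are always resolved before parents
            kids = idx.children[t]
            if not kids:
                x[t] = float(next_slot)
                next_slot += 1
            else:
                x[t] = float(np.mean([x[c] for c in kids]))
        local = {t: (x[t], -float(depth[t])) for t in order}
        if algorithm == "fruchterman-reingold" and len(order) > 1:
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(order)
            g.add_edges_from((t, c) for t in order for c in idx.children[t])
            pos = nx.spring_layout(g, pos={t: np.array(local[t]) for t in order},
                                   seed=seed, iterations=50)
            local = {t: (float(p[0]), float(p[1])) for t, p in pos.items()}
        for t in order:
            coords[t] = local[t]
            tree_of[t] = root
            edges.extend((t, c) for c in idx.children[t])
        xs = [local[t][0] for t in order]
        ys = [local[t][1] for t in order]
        bbox[root] = (min(xs), min(ys), max(xs), max(ys))
    return TreeLayout(coords=coords, edges=edges, roots=roots, tree_of=tree_of, bbox=bbox)


# ------------------------------------------------------- size-range optimization
def _pairwise_overlap_fraction(points: np.ndarray, r: float) -> float:
    """Total pairwise intersection area of equal discs / total disc area."""
    n = len(points)
    if n < 2 or r <= 0:
        return 0.0
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    d = d[iu]
    close = d < 2 * r
    if not close.any():
        return 0.0
    dc = np.clip(d[close], 0.0, 2 * r)
    area = 2 * r * r * np.arccos(dc / (2 * r)) - (dc / 2) * np.sqrt(
        np.maximum(4 * r * r - dc * dc, 0.0))
    return float(area.sum() / (n * math.pi * r * r))


def optimize_size_range(layout, candidate_range: Sequence[float] = (0.005, 0.05),
                        lo_fraction: float = 0.25, overlap_tolerance: float = 0.01,
                        iterations: int = 20) -> tuple[float, float]:
    """Choose the node size range ``[lo, hi]`` (fractions of the unit figure).

    Picks the largest maximum radius ``hi`` within ``candidate_range`` such
    that, with every node drawn at radius ``hi``, total pairwise disc overlap
    stays below ``overlap_tolerance`` of total disc area (bisection); falls
    back to the smallest candidate if even that overlaps.  ``lo`` is a fixed
    fraction of ``hi``.
    """
    if isinstance(layout, TreeLayout):
        pts = np.array(list(layout.coords.values()), dtype=float)
        span = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1])) if len(pts) > 1 else 1.0
        pts = pts / (span if span > 0 else 1.0)
    else:
        pts = np.asarray(layout, dtype=float)
    lo_max, hi_max = float(candidate_range[0]), float(candidate_range[1])

    def ok(r: float) -> bool:
        return _pairwise_overlap_fraction(pts, r) <= overlap_tolerance

    if ok(hi_max):
        hi = hi_max
    elif not ok(lo_max):
        hi = lo_max
    else:
        good, bad = lo_max, hi_max
        for _ in range(iterations):
            mid = (good + bad) / 2.0
            if ok(mid):
                good = mid
            else:
                bad = mid
        hi = good
    return (lo_fraction * hi, hi)


# ------------------------------------------------------------------- rendering
@dataclass
class HeatTreeSpec:
    """Which statistics drive which aesthetics.

    Every mapping names a taxon-table column (user or computed) or is None
    for a constant aesthetic.  ``*_transform`` is one of identity/log10/sqrt.
    ``size_interval``/``color_interval`` override the data range (raw value
    units); values outside clamp to the endpoints.
    """

    node_size: str | None = "n_obs"
    node_color: str | None = None
    edge_size: str | None = None
    edge_color: str | None = None
    node_label: str | None = "name"
    node_size_transform: str = "identity"
    node_color_transform: str = "identity"
    edge_size_transform: str = "identity"
    edge_color_transform: str = "identity"
    palette: tuple = DEFAULT_PALETTE
    size_interval: tuple | None = None
    color_interval: tuple | None = None


@dataclass
class RenderResult:
    """Rendered output plus everything needed to verify it quantitatively."""

    path: str | None
    n_trees: int
    nodes: dict[str, dict]  # taxon_id -> {x, y, r, color}
    legend: dict  # mapping name -> {column, transform, interval, ticks, ...}
    primitives: list[dict]
    width_px: float
    height_px: float


def _resolve_column(frame: pd.DataFrame, column: str | None, what: str):
    if column is None:
        return None
    if column not in frame.columns:
        raise TaxmapError(f"unknown column for {what}: {column!r}")
    return frame[column]


def _ticks(values: np.ndarray, transform: str, interval) -> list[float]:
    tv = _apply_transform(values, transform, "tick")
    if interval is not None:
        lo, hi = _apply_transform(np.asarray(interval, dtype=float), transform, "interval")
    else:
        lo, hi = float(np.min(tv)), float(np.max(tv))
    inv = _TRANSFORMS[transform][1]
    return [float(inv(lo + f * (hi - lo))) for f in (0.0, 0.5, 1.0)]


def compute_heat_tree(tm: Taxmap, spec: HeatTreeSpec | None = None,
                      algorithm: str = "reingold-tilford", seed: int = 0,
                      size_candidates: Sequence[float] = (0.006, 0.045)) -> RenderResult:
    """Build the full display list for a heat tree (no file output).

    This is the deterministic geometry/aesthetics pipeline behind
    :func:`render`; everything is expressed in normalized [0,1] figure
    coordinates, y pointing up.
    """
    spec = spec or HeatTreeSpec()
    if len(tm.taxa) == 0:
        raise TaxmapError("cannot render an empty Taxmap")
    frame = tm.taxa_table()
    ids = tm.taxon_ids
    node_size_v = _resolve_column(frame, spec.node_size, "node_size")
    node_color_v = _resolve_column(frame, spec.node_color, "node_color")
    edge_size_v = _resolve_column(frame, spec.edge_size, "edge_size")
    edge_color_v = _resolve_column(frame, spec.edge_color, "edge_color")
    labels = _resolve_column(frame, spec.node_label, "node_label")

    layout = layout_tree(tm, algorithm=algorithm, seed=seed)
    n_trees = len(layout.roots)

    has_legend = any(v is not None for v in (node_size_v, node_color_v, edge_size_v,
                                             edge_color_v))
    plot_w = 0.84 if has_legend else 1.0
    ncols = math.ceil(math.sqrt(n_trees))
    nrows = math.ceil(n_trees / ncols)
    cell_w, cell_h = plot_w / ncols, 1.0 / nrows
    margin = 0.12

    placed: dict[str, tuple[float, float]] = {}
    for i, root in enumerate(layout.roots):
        col, row = i % ncols, i // ncols
        x0, y0 = col * cell_w, 1.0 - (row + 1) * cell_h
        xmin, ymin, xmax, ymax = layout.bbox[root]
        w = max(xmax - xmin, 1e-9)
        h = max(ymax - ymin, 1e-9)
        avail_w = cell_w * (1 - 2 * margin)
        avail_h = cell_h * (1 - 2 * margin)
        s = min(avail_w / w, avail_h / h)
        ox = x0 + cell_w / 2 - s * (xmin + xmax) / 2
        oy = y0 + cell_h / 2 - s * (ymin + ymax) / 2
        for t, r in layout.tree_of.items():
            if r == root:
                x, y = layout.coords[t]
                placed[t] = (ox + s * x, oy + s * y)

    pts = np.array([placed[t] for t in ids])
    lo, hi = optimize_size_range(pts, candidate_range=size_candidates)

    legend: dict[str, dict] = {}
    if node_size_v is not None:
        radii = map_aesthetic(node_size_v, (lo, hi), transform=spec.node_size_transform,
                              interval=spec.size_interval)
        ticks = _ticks(np.asarray(node_size_v, dtype=float), spec.node_size_transform,
                       spec.size_interval)
        legend["node_size"] = {
            "column": spec.node_size, "transform": spec.node_size_transform,
            "out_interval": [lo, hi],
            "value_interval": list(spec.size_interval) if spec.size_interval else
            [float(np.min(node_size_v)), float(np.max(node_size_v))],
            "ticks": ticks,
            "tick_sizes": [float(v) for v in map_aesthetic(
                ticks, (lo, hi), transform=spec.node_size_transform,
                interval=spec.size_interval if spec.size_interval else
                (float(np.min(node_size_v)), float(np.max(node_size_v))))],
        }
    else:
        radii = np.full(len(ids), (lo + hi) / 2.0)

    if node_color_v is not None:
        vi = spec.color_interval if spec.color_interval else \
            (float(np.min(node_color_v)), float(np.max(node_color_v)))
        colors = map_color(node_color_v, spec.palette, interval=vi,
                           transform=spec.node_color_transform)
        ticks = _ticks(np.asarray(node_color_v, dtype=float), spec.node_color_transform,
                       spec.color_interval)
        legend["node_color"] = {
            "column": spec.node_color, "transform": spec.node_color_transform,
            "palette": list(spec.palette), "value_interval": list(vi), "ticks": ticks,
            "tick_colors": map_color(ticks, spec.palette, interval=vi,
                                     transform=spec.node_color_transform),
        }
    else:
        colors = [_FLAT_NODE] * len(ids)

    if edge_size_v is not None:
        edge_r = map_aesthetic(edge_size_v, (lo * 0.5, hi * 0.5),
                               transform=spec.edge_size_transform)
        legend["edge_size"] = {
            "column": spec.edge_size, "transform": spec.edge_size_transform,
            "out_interval": [lo * 0.5, hi * 0.5],
            "value_interval": [float(np.min(edge_size_v)), float(np.max(edge_size_v))],
            "ticks": _ticks(np.asarray(edge_size_v, dtype=float),
                            spec.edge_size_transform, None),
        }
    else:
        edge_r = radii * 0.5
    if edge_color_v is not None:
        vi = (float(np.min(edge_color_v)), float(np.max(edge_color_v)))
        edge_colors = map_color(edge_color_v, spec.palette, interval=vi,
                                transform=spec.edge_color_transform)
        legend["edge_color"] = {
            "column": spec.edge_color, "transform": spec.edge_color_transform,
            "palette": list(spec.palette), "value_interval": list(vi),
            "ticks": _ticks(np.asarray(edge_color_v, dtype=float),
                            spec.edge_color_transform, None),
            "tick_colors": map_color(_ticks(np.asarray(edge_color_v, dtype=float),
                                            spec.edge_color_transform, None),
                                     spec.palette, interval=vi,
                                     transform=spec.edge_color_transform),
        }
    else:
        edge_colors = [_FLAT_EDGE] * len(ids)

    pos_of = {t: k for k, t in enumerate(ids)}
    prims: list[dict] = []
    # edges first (under the nodes), grouped per tree for sub-tree accounting
    for i, root in enumerate(layout.roots):
        grp = f"tree-{i}"
        for parent, child in layout.edges:
            if layout.tree_of[child] != root:
                continue
            (x1, y1), (x2, y2) = placed[parent], placed[child]
            dx, dy = x2 - x1, y2 - y1
            norm = math.hypot(dx, dy)
            if norm == 0:
                continue
            ux, uy = -dy / norm, dx / norm
            wp = float(edge_r[pos_of[parent]])
            wc = float(edge_r[pos_of[child]])
            prims.append({
                "kind": "polygon", "group": grp,
                "points": [(x1 + ux * wp, y1 + uy * wp), (x2 + ux * wc, y2 + uy * wc),
                           (x2 - ux * wc, y2 - uy * wc), (x1 - ux * wp, y1 - uy * wp)],
                "fill": edge_colors[pos_of[child]],
            })
        for t in ids:
            if layout.tree_of[t] != root:
                continue
            k = pos_of[t]
            prims.append({"kind": "circle", "group": grp, "x": placed[t][0],
                          "y": placed[t][1], "r": float(radii[k]), "fill": colors[k],
                          "taxon_id": t})
        if labels is not None:
            for t in ids:
                if layout.tree_of[t] != root:
                    continue
                k = pos_of[t]
                text = "" if pd.isna(labels.iloc[k]) else str(labels.iloc[k])
                if not text:
                    continue
                r = float(radii[k])
                fsize = max(min(r * 0.9, 0.02), 0.007)
                max_chars = max(int((4.0 * r) / (0.6 * fsize)), 1)
                if len(text) > max_chars:
                    text = text[: max(max_chars - 1, 1)] + "…"
                prims.append({"kind": "text", "group": grp, "x": placed[t][0],
                              "y": placed[t][1] - r - fsize * 0.8, "size": fsize,
                              "text": text, "fill": "#333333"})

    prims.extend(_legend_primitives(legend))

    nodes = {t: {"x": placed[t][0], "y": placed[t][1], "r": float(radii[pos_of[t]]),
                 "color": colors[pos_of[t]]} for t in ids}
    return RenderResult(path=None, n_trees=n_trees, nodes=nodes, legend=legend,
                        primitives=prims, width_px=0.0, height_px=0.0)


def _legend_primitives(legend: dict) -> list[dict]:
    prims: list[dict] = []
    if "node_color" in legend:
        meta = legend["node_color"]
        x0, y0, w, h = 0.88, 0.55, 0.03, 0.38
        n_strip = 24
        for i in range(n_strip):
            f0, f1 = i / n_strip, (i + 1) / n_strip
            lo_v, hi_v = meta["value_interval"]
            mid_raw = _TRANSFORMS[meta["transform"]][1](
                _TRANSFORMS[meta["transform"]][0](lo_v)
                + (f0 + f1) / 2 * (_TRANSFORMS[meta["transform"]][0](hi_v)
                                   - _TRANSFORMS[meta["transform"]][0](lo_v)))
            color = map_color([mid_raw], meta["palette"], interval=meta["value_interval"],
                              transform=meta["transform"])[0]
            prims.append({"kind": "rect", "group": "legend", "x": x0,
                          "y": y0 + f0 * h, "w": w, "h": h / n_strip + 1e-4,
                          "fill": color})
        for tick, f in zip(meta["ticks"], (0.0, 0.5, 1.0)):
            prims.append({"kind": "text", "group": "legend", "x": x0 + w + 0.012,
                          "y": y0 + f * h, "size": 0.014, "text": _fmt_tick(tick),
                          "fill": "#333333", "anchor": "start"})
        prims.append({"kind": "text", "group": "legend", "x": x0, "y": y0 + h + 0.03,
                      "size": 0.015, "text": str(meta["column"]), "fill": "#111111",
                      "anchor": "start"})
    if "node_size" in legend:
        meta = legend["node_size"]
        x0, y0 = 0.905, 0.12
        y = y0
        for tick, r in zip(meta["ticks"], meta["tick_sizes"]):
            prims.append({"kind": "circle", "group": "legend", "x": x0, "y": y + r,
                          "r": r, "fill": "#aaaaaa"})
            prims.append({"kind": "text", "group": "legend", "x": x0 + 0.05,
                          "y": y + r, "size": 0.014, "text": _fmt_tick(tick),
                          "fill": "#333333", "anchor": "start"})
            y += 2 * r + 0.02
        prims.append({"kind": "text", "group": "legend", "x": 0.88, "y": y + 0.01,
                      "size": 0.015, "text": str(meta["column"]), "fill": "#111111",
                      "anchor": "start"})
    return prims


def _fmt_tick(v: float) -> str:
    if v == 0:
        return "0"
    if abs(v) >= 1000 or abs(v) < 0.01:
        return f"{v:.2e}"
    return f"{v:.3g}"


def _f(x: float) -> str:
    return f"{x:.5f}".rstrip("0").rstrip(".")


def write_svg(result: RenderResult, path: str, width_px: float = 800.0,
              height_px: float = 800.0) -> None:
    """Serialize a display list to SVG (deterministic byte-for-byte)."""
    W, H = float(width_px), float(height_px)
    unit = min(W, H)

    def X(x):
        return _f(x * W)

    def Y(y):
        return _f((1.0 - y) * H)

    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(W)}" height="{_f(H)}" '
        f'viewBox="0 0 {_f(W)} {_f(H)}">',
        '<rect width="100%" height="100%" fill="#ffffff"/>',
    ]
    current_group = None
    for p in result.primitives:
        grp = p.get("group")
        if grp != current_group:
            if current_group is not None:
                lines.append("</g>")
            lines.append(f'<g id="{grp}">')
            current_group = grp
        if p["kind"] == "circle":
            extra = f' data-taxon="{p["taxon_id"]}"' if "taxon_id" in p else ""
            lines.append(f'<circle cx="{X(p["x"])}" cy="{Y(p["y"])}" r="{_f(p["r"] * unit)}" '
                         f'fill="{p["fill"]}"{extra}/>')
        elif p["kind"] == "polygon":
            pts = " ".join(f"{X(x)},{Y(y)}" for x, y in p["points"])
            lines.append(f'<polygon points="{pts}" fill="{p["fill"]}"/>')
        elif p["kind"] == "rect":
            lines.append(f'<rect x="{X(p["x"])}" y="{Y(p["y"] + p["h"])}" '
                         f'width="{_f(p["w"] * W)}" height="{_f(p["h"] * H)}" '
                         f'fill="{p["fill"]}"/>')
        elif p["kind"] == "text":
            anchor = p.get("anchor", "middle")
            text = (p["text"].replace("&", "&amp;").replace("<", "&lt;")
                    .replace(">", "&gt;"))
            lines.append(f'<text x="{X(p["x"])}" y="{Y(p["y"])}" '
                         f'font-size="{_f(p["size"] * unit)}" text-anchor="{anchor}" '
                         f'font-family="sans-serif" fill="{p["fill"]}">{text}</text>')
    if current_group is not None:
        lines.append("</g>")
    lines.append("</svg>")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _draw_matplotlib(result: RenderResult, path: str, width_px: float, height_px: float,
                     fmt: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, Polygon, Rectangle

    dpi = 100.0
    fig = plt.figure(figsize=(width_px / dpi, height_px / dpi), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")
    unit_pt = min(width_px, height_px) / dpi * 72.0
    for p in result.primitives:
        if p["kind"] == "polygon":
            ax.add_patch(Polygon(p["points"], closed=True, facecolor=p["fill"],
                                 edgecolor="none"))
        elif p["kind"] == "circle":
            ax.add_patch(Circle((p["x"], p["y"]), p["r"], facecolor=p["fill"],
                                edgecolor="none"))
        elif p["kind"] == "rect":
            ax.add_patch(Rectangle((p["x"], p["y"]), p["w"], p["h"],
                                   facecolor=p["fill"], edgecolor="none"))
        elif p["kind"] == "text":
            ha = {"start": "left", "middle": "center"}.get(p.get("anchor", "middle"),
                                                           "center")
            ax.text(p["x"], p["y"], p["text"], fontsize=p["size"] * unit_pt, ha=ha,
                    va="center", color=p["fill"])
    meta = {"CreationDate": None} if fmt == "pdf" else None
    fig.savefig(path, format=fmt, metadata=meta)
    plt.close(fig)


def render(tm: Taxmap, spec: HeatTreeSpec | None = None, output: str | None = None,
           format: str | None = None, *, algorithm: str = "reingold-tilford",
           seed: int = 0, width_px: float = 800.0, height_px: float = 800.0,
           write_legend_json: bool = True) -> RenderResult:
    """Render a Taxmap as a heat tree.

    One sub-tree per root, arranged on a near-square grid; quantitative
    legends for the node color/size mappings; legend metadata (tick values
    and their mapped aesthetics) written as ``<output>.legend.json`` for
    programmatic checks.  Output is deterministic given (input, spec, seed)
    and scale-independent: all geometry lives in normalized figure units.
    """
    result = compute_heat_tree(tm, spec, algorithm=algorithm, seed=seed)
    result.width_px, result.height_px = float(width_px), float(height_px)
    if output is not None:
        fmt = (format or os.path.splitext(output)[1].lstrip(".") or "svg").lower()
        if fmt not in ("svg", "pdf", "png"):
            raise TaxmapError(f"unsupported output format {fmt!r}")
        if fmt == "svg":
            write_svg(result, output, width_px, height_px)
        else:
            _draw_matplotlib(result, output, width_px, height_px, fmt)
        result.path = output
        if write_legend_json:
            with open(output + ".legend.json", "w") as fh:
                json.dump({"n_trees": result.n_trees, "legend": result.legend,
                           "nodes": result.nodes}, fh, indent=2, sort_keys=True)
    return result
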