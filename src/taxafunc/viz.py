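"""Static SVG exports: stacked abundance bars and the bipartite legend panel.

Rendering is a pure function of (data, configuration): the same inputs
and seed always produce byte-identical SVG text.  Each export parses as
a standalone SVG 1.1 document, so bar plots and the bipartite panel can
be used independently (e.g. the panel as a color legend).
"""

from __future__ import annotations

import colorsys
import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .attribution import EdgeWeightTable, is_relative
from .errors import InputFormatError
from .hierarchy import Frontier, HierarchyTree, leaf_order
from .io_formats import MatrixTable, SampleGroupMap

SVG_NS = "http://www.w3.org/2000/svg"
MAX_PALETTE = 256


@dataclass
class ColorAssignment:
    """Deterministic frontier-node -> hex color mapping."""

    colors: dict[str, str]
    scheme: str
    seed: int

    def __getitem__(self, node_id: str) -> str:
        return self.colors[node_id]


@dataclass
class RenderConfig:
    """Canvas geometry and display thresholds (pixels)."""

    bar_width: float = 24.0
    bar_gap: float = 6.0
    group_gap: float = 18.0
    bar_height: float = 300.0
    margin_left: float = 60.0
    margin_top: float = 24.0
    margin_bottom: float = 48.0
    font_size: float = 9.0
    edge_min: float = 0.01  # minimum mean share for a drawn edge (strict >)
    max_edge_width: float = 8.0
    node_bar_max: float = 80.0
    node_bar_height: float = 10.0
    node_gap: float = 6.0
    panel_span: float = 260.0  # horizontal distance between the two columns


@dataclass
class FigureDocument:
    """An SVG document plus its logical size."""

    svg: str
    width: float
    height: float

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.svg)


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _hex(rgb: tuple[float, float, float]) -> str:
    return "#{:02x}{:02x}{:02x}".format(
        *(max(0, min(255, round(c * 255))) for c in rgb)
    )


def _hls_hex(h: float, l: float, s: float) -> str:
    return _hex(colorsys.hls_to_rgb(h % 1.0, l, s))


def assign_colors(
    tree: HierarchyTree,
    frontier: Frontier,
    scheme: str = "hierarchical",
    seed: int = 0,
) -> ColorAssignment:
    """Color every frontier node deterministically.

    ``hierarchical``: nodes sharing a top-level ancestor share a hue
    band, with lightness varied in leaf order inside the band.
    ``random``: a seeded shuffle of an evenly spaced max-contrast
    palette.  Distinct nodes always receive distinct colors.
    """
    order = leaf_order(tree, frontier)
    if len(order) > MAX_PALETTE:
        raise InputFormatError(
            f"frontier has {len(order)} nodes (> {MAX_PALETTE}); "
            "collapse to a coarser frontier"
        )
    colors: dict[str, str] = {}
    if scheme == "hierarchical":
        bands: dict[str, list[str]] = {}
        for n in order:
            bands.setdefault(tree.top_ancestor(n), []).append(n)
        band_keys = list(bands)
        for bi, key in enumerate(band_keys):
            hue = bi / max(1, len(band_keys))
            members = bands[key]
            for mi, n in enumerate(members):
                light = 0.35 + 0.4 * (mi / max(1, len(members) - 1))
                colors[n] = _hls_hex(hue, light, 0.65)
    elif scheme == "random":
        n = len(order)
        lightness = (0.40, 0.55, 0.70)
        palette = [
            _hls_hex(k / n, lightness[k % len(lightness)], 0.65) for k in range(n)
        ]
        rng = random.Random(seed)
        rng.shuffle(palette)
        colors = dict(zip(order, palette))
    else:
        raise InputFormatError(f"unknown color scheme {scheme!r}")
    # resolve rare quantization collisions deterministically
    used: set[str] = set()
    for nid in order:
        c = colors[nid]
        bump = 0
        while c in used:
            bump += 1
            h, l, s = _parse_hls(c)
            c = _hls_hex(h, min(0.95, l + 0.02 * bump), s)
        colors[nid] = c
        used.add(c)
    return ColorAssignment(colors, scheme, seed)


def _parse_hls(hexcolor: str) -> tuple[float, float, float]:
    r = int(hexcolor[1:3], 16) / 255
    g = int(hexcolor[3:5], 16) / 255
    b = int(hexcolor[5:7], 16) / 255
    return colorsys.rgb_to_hls(r, g, b)


# ---------------------------------------------------------------------------
# SVG helpers
# ---------------------------------------------------------------------------


def _svg_root(width: float, height: float) -> ET.Element:
    return ET.Element(
        "svg",
        {
            "xmlns": SVG_NS,
            "version": "1.1",
            "width": _fmt(width),
            "height": _fmt(height),
            "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}",
        },
    )


def _text(parent: ET.Element, x: float, y: float, s: str, size: float, anchor="middle"):
    el = ET.SubElement(
        parent,
        "text",
        {
            "x": _fmt(x),
            "y": _fmt(y),
            "font-size": _fmt(size),
            "font-family": "sans-serif",
            "text-anchor": anchor,
        },
    )
    el.text = s
    return el


def _serialize(root: ET.Element) -> str:
    body = ET.tostring(root, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"


def _sample_clusters(
    col_ids: list[str], groups: SampleGroupMap | None
) -> list[tuple[str | None, list[str]]]:
    """Samples clustered by group (first-appearance order), or one cluster."""
    if groups is None:
        return [(None, list(col_ids))]
    clusters: dict[str, list[str]] = {}
    order: list[str] = []
    for s in col_ids:
        g = groups.groups.get(s, "(unlabeled)")
        if g not in clusters:
            clusters[g] = []
            order.append(g)
        clusters[g].append(s)
    return [(g, clusters[g]) for g in order]


# ---------------------------------------------------------------------------
# Renderers
# ---------------------------------------------------------------------------


def render_stacked_bars(
    table: MatrixTable,
    colors: ColorAssignment,
    groups: SampleGroupMap | None = None,
    config: RenderConfig | None = None,
    companion: MatrixTable | None = None,
) -> FigureDocument:
    """One stacked bar per sample; segments bottom-up in table row order.

    The table must be relative; every row needs a color.  With
    ``groups``, samples are clustered per group with a labeled gap.
    With ``companion`` (a second relative table on the same grid, e.g. a
    measured shotgun profile), each sample gets two adjacent bars
    labeled ``(T)`` and ``(M)``.
    """
    cfg = config or RenderConfig()
    if not is_relative(table):
        raise InputFormatError("stacked bars require a relative table")
    for r in table.row_ids:
        if r not in colors.colors:
            raise InputFormatError(f"no color assigned for row {r!r}")
    if companion is not None:
        if companion.row_ids != table.row_ids or companion.col_ids != table.col_ids:
            raise InputFormatError("companion table must share the table's grid")
        if not is_relative(companion):
            raise InputFormatError("companion table must be relative")

    clusters = _sample_clusters(table.col_ids, groups)
    per_sample = 2 if companion is not None else 1
    slot = per_sample * cfg.bar_width + (per_sample - 1) * 2.0
    n_samples = len(table.col_ids)
    width = (
        cfg.margin_left
        + sum(len(ss) for _, ss in clusters) * (slot + cfg.bar_gap)
        + (len(clusters) - 1) * cfg.group_gap
        + cfg.bar_gap
    )
    height = cfg.margin_top + cfg.bar_height + cfg.margin_bottom
    root = _svg_root(width, height)
    c_idx = table.col_index()

    def draw_bar(parent: ET.Element, x: float, col: int, tab: MatrixTable) -> None:
        y = cfg.margin_top + cfg.bar_height
        for i, rid in enumerate(tab.row_ids):
            v = tab.values[i, col]
            if v == 0:
                continue
            h = v * cfg.bar_height
            y -= h
            ET.SubElement(
                parent,
                "rect",
                {
                    "x": _fmt(x),
                    "y": _fmt(y),
                    "width": _fmt(cfg.bar_width),
                    "height": _fmt(h),
                    "fill": colors[rid],
                },
            )

    x = cfg.margin_left
    for gi, (glabel, samples) in enumerate(clusters):
        if gi > 0:
            x += cfg.group_gap
        gx0 = x
        for s in samples:
            col = c_idx[s]
            g = ET.SubElement(root, "g", {"class": "sample", "data-sample": s})
            draw_bar(g, x, col, table)
            label = f"{s} (T)" if companion is not None else s
            _text(
                g,
                x + cfg.bar_width / 2,
                cfg.margin_top + cfg.bar_height + 12,
                label,
                cfg.font_size,
            )
            if companion is not None:
                x2 = x + cfg.bar_width + 2.0
                draw_bar(g, x2, col, companion)
                _text(
                    g,
                    x2 + cfg.bar_width / 2,
                    cfg.margin_top + cfg.bar_height + 24,
                    f"{s} (M)",
                    cfg.font_size,
                )
            x += slot + cfg.bar_gap
        if glabel is not None:
            _text(
                root,
                (gx0 + x - cfg.bar_gap) / 2,
                cfg.margin_top - 8,
                glabel,
                cfg.font_size + 2,
            )
    return FigureDocument(_serialize(root), width, height)


def render_bipartite_panel(
    edges: EdgeWeightTable,
    taxa_means: dict[str, float],
    func_means: dict[str, float],
    colors: ColorAssignment,
    config: RenderConfig | None = None,
) -> FigureDocument:
    """Taxa (left) and functions (right) as bars scaled by mean abundance,
    joined by edges whose stroke width is linear in the mean attributed
    share w(t, f).  Edges with w <= ``edge_min`` are suppressed to avoid
    hairline clutter.

    ``taxa_means``/``func_means`` are ordered mappings (display order =
    insertion order), typically frontier nodes with their
    :func:`~taxafunc.hierarchy.node_mean_abundance` values.
    """
    cfg = config or RenderConfig()
    taxa = list(taxa_means)
    funcs = list(func_means)
    for nid in taxa + funcs:
        if nid not in colors.colors:
            raise InputFormatError(f"no color assigned for node {nid!r}")
    rows = max(len(taxa), len(funcs))
    height = (
        cfg.margin_top
        + rows * (cfg.node_bar_height + cfg.node_gap)
        + cfg.margin_bottom
    )
    width = cfg.margin_left * 2 + cfg.node_bar_max * 2 + cfg.panel_span
    root = _svg_root(width, height)

    left_x = cfg.margin_left + cfg.node_bar_max  # bars grow leftwards
    right_x = left_x + cfg.panel_span

    def y_center(i: int) -> float:
        return cfg.margin_top + i * (cfg.node_bar_height + cfg.node_gap) + cfg.node_bar_height / 2

    t_pos = {t: y_center(i) for i, t in enumerate(taxa)}
    f_pos = {f: y_center(i) for i, f in enumerate(funcs)}

    edge_group = ET.SubElement(root, "g", {"class": "edges"})
    for t in taxa:
        for f in funcs:
            w = edges.weights.get((t, f), 0.0)
            if w <= cfg.edge_min:
                continue
            ET.SubElement(
                edge_group,
                "line",
                {
                    "x1": _fmt(left_x),
                    "y1": _fmt(t_pos[t]),
                    "x2": _fmt(right_x),
                    "y2": _fmt(f_pos[f]),
                    "stroke": "#888888",
                    "stroke-width": _fmt(w * cfg.max_edge_width),
                    "class": "edge",
                    "data-taxon": t,
                    "data-function": f,
                },
            )

    for side, ids, means, x_edge, grow in (
        ("taxa", taxa, taxa_means, left_x, -1),
        ("functions", funcs, func_means, right_x, +1),
    ):
        g = ET.SubElement(root, "g", {"class": side})
        pos = t_pos if side == "taxa" else f_pos
        for nid in ids:
            length = max(0.0, float(means[nid])) * cfg.node_bar_max
            x0 = x_edge - length if grow < 0 else x_edge
            ET.SubElement(
                g,
                "rect",
                {
                    "x": _fmt(x0),
                    "y": _fmt(pos[nid] - cfg.node_bar_height / 2),
                    "width": _fmt(length),
                    "height": _fmt(cfg.node_bar_height),
                    "fill": colors[nid],
                    "data-node": nid,
                },
            )
            lx = x_edge - cfg.node_bar_max - 4 if grow < 0 else x_edge + cfg.node_bar_max + 4
            _text(
                g,
                lx,
                pos[nid] + cfg.node_bar_height / 2 - 1,
                nid,
                cfg.font_size,
                anchor="end" if grow < 0 else "start",
            )
    return FigureDocument(_serialize(root), width, height)


def rasterize(figure: FigureDocument, path, dpi: int = 150) -> None:
    """Best-effort PNG export of an SVG figure.

    Requires an SVG rasterizer (``cairosvg``) at run time; SVG remains
    the contract format.
    """
    try:
        import cairosvg  # type: ignore
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise RuntimeError(
            "PNG export needs the optional 'cairosvg' package; "
            "use the SVG output instead"
        ) from exc
    cairosvg.svg2png(  # pragma: no cover
        bytestring=figure.svg.encode(), write_to=str(path), dpi=dpi
    )
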