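"""Deterministic static SVG rendering of tree layouts.

The renderer is a pure function of (layout, node colors, collapsed clades,
barplot layers, style): identical inputs produce byte-identical SVG 1.1,
which keeps outputs diffable and golden-testable. Barplot layers are drawn
innermost-first in list order as tip-aligned columns (rectangular layout)
or rings (circular); the unrooted layout has no tip alignment and rejects
barplot requests. Collapsed clades are drawn as single wedges/triangles
labeled with their shared value and tip count, and every layer contributes
a legend block listing exactly the categories it draws.

Color handling: an ordered discrete palette (capped, with least-frequent
categories pooled into "Other"), and monotone continuous maps taken from
matplotlib's perceptually uniform colormaps — sequential for unsigned
quantities, diverging (with a defined midpoint) for signed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bptree import BalancedParenTree
from .community import BarplotLayer, CollapsedClade
from .layout import LayoutResult

__all__ = ["StyleSpec", "render_svg", "categorical_color_map",
           "continuous_color", "pool_rare_categories"]

# colorblind-safe 12-color discrete palette (Paul Tol "muted" + extras)
_DEFAULT_PALETTE = (
    "#332288", "#88ccee", "#44aa99", "#117733", "#999933", "#ddcc77",
    "#cc6677", "#882255", "#aa4499", "#dddddd", "#6699cc", "#661100",
)


@dataclass
class StyleSpec:
    """Palette, continuous maps, and bar scaling for one rendering."""

    discrete_palette: tuple[str, ...] = _DEFAULT_PALETTE
    sequential_cmap: str = "viridis"
    diverging_cmap: str = "RdBu_r"
    diverging_midpoint: float | None = None  # None: midpoint of data range
    missing_color: str = "#c0c0c0"
    bar_band: float = 36.0     # max bar length, px
    bar_min_len: float = 2.0   # min bar length for the smallest value, px
    max_categories: int = 12
    other_label: str = "Other"


def pool_rare_categories(values: dict, cap: int,
                         other_label: str = "Other") -> dict:
    """Map values so at most ``cap`` categories survive; rest pool to Other."""
    freq: dict[str, int] = {}
    for v in values.values():
        if v is not None:
            freq[v] = freq.get(v, 0) + 1
    if len(freq) <= cap:
        return dict(values)
    keep = {c for c, _ in sorted(freq.items(),
                                 key=lambda cv: (-cv[1], cv[0]))[:cap - 1]}
    return {k: (v if v is None or v in keep else other_label)
            for k, v in values.items()}


def categorical_color_map(categories, style: StyleSpec | None = None,
                          ) -> dict[str, str]:
    """Assign palette colors to categories in the given order (cycled)."""
    style = style or StyleSpec()
    pal = style.discrete_palette
    return {c: pal[i % len(pal)] for i, c in enumerate(categories)}


def continuous_color(value: float, vmin: float, vmax: float,
                     style: StyleSpec | None = None,
                     diverging: bool = False) -> str:
    """Hex color for a value under the monotone continuous map.

    A degenerate scale (vmin == vmax) maps everything to the midpoint.
    """
    import matplotlib

    style = style or StyleSpec()
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return style.missing_color
    if diverging:
        mid = style.diverging_midpoint
        if mid is None:
            mid = 0.5 * (vmin + vmax)
        half = max(vmax - mid, mid - vmin)
        if half <= 0:
            t = 0.5
        else:
            t = 0.5 + (value - mid) / (2.0 * half)
    else:
        t = 0.5 if vmax <= vmin else (value - vmin) / (vmax - vmin)
    t = min(1.0, max(0.0, t))
    name = style.diverging_cmap if diverging else style.sequential_cmap
    rgba = matplotlib.colormaps[name](t)
    return "#{:02x}{:02x}{:02x}".format(*(int(round(255 * c))
                                          for c in rgba[:3]))


def _f(v: float) -> str:
    return f"{v:.4f}".rstrip("0").rstrip(".")


class _Svg:
    def __init__(self) -> None:
        self.parts: list[str] = []

    def add(self, s: str) -> None:
        self.parts.append(s)

    def line(self, x1, y1, x2, y2, stroke="#555555", width=1.0, cls="") -> None:
        c = f' class="{cls}"' if cls else ""
        self.add(f'<line{c} x1="{_f(x1)}" y1="{_f(y1)}" x2="{_f(x2)}" '
                 f'y2="{_f(y2)}" stroke="{stroke}" '
                 f'stroke-width="{_f(width)}"/>')

    def circle(self, cx, cy, r, fill) -> None:
        self.add(f'<circle cx="{_f(cx)}" cy="{_f(cy)}" r="{_f(r)}" '
                 f'fill="{fill}"/>')

    def rect(self, x, y, w, h, fill) -> None:
        self.add(f'<rect x="{_f(x)}" y="{_f(y)}" width="{_f(w)}" '
                 f'height="{_f(h)}" fill="{fill}"/>')

    def polygon(self, pts, fill, opacity=0.65) -> None:
        p = " ".join(f"{_f(x)},{_f(y)}" for x, y in pts)
        self.add(f'<polygon points="{p}" fill="{fill}" '
                 f'fill-opacity="{_f(opacity)}"/>')

    def path(self, d, fill="none", stroke="#555555", width=1.0) -> None:
        self.add(f'<path d="{d}" fill="{fill}" stroke="{stroke}" '
                 f'stroke-width="{_f(width)}"/>')

    def text(self, x, y, s, size=10, anchor="start") -> None:
        s = (s.replace("&", "&amp;").replace("<", "&lt;")
             .replace(">", "&gt;"))
        self.add(f'<text x="{_f(x)}" y="{_f(y)}" font-size="{_f(size)}" '
                 f'font-family="sans-serif" text-anchor="{anchor}">{s}</text>')


def render_svg(tree: BalancedParenTree, layout: LayoutResult, out_path,
               *, node_colors: dict[int, str] | None = None,
               collapsed: list[CollapsedClade] | None = None,
               barplot_layers: list[BarplotLayer] | None = None,
               style: StyleSpec | None = None) -> None:
    """Write a deterministic SVG figure for one laid-out tree.

    ``node_colors`` maps preorder rank -> hex fill; ``collapsed`` clades are
    keyed by opening position (as produced by
    :func:`~treescape.community.collapse_uniform_clades`); each barplot
    layer's payload is keyed by tip name.
    """
    barplot_layers = list(barplot_layers or [])
    style = style or StyleSpec()
    if layout.kind == "unrooted" and barplot_layers:
        raise ValueError("barplot layers require tip alignment; the unrooted "
                         "layout does not provide it")
    n = layout.n_nodes
    tip_ranks = layout.tip_ranks
    n_tips = tip_ranks.size
    rank_of_pos = {int(p): r for r, p in enumerate(layout.positions)}
    tip_name_of_rank = {int(r): tree.name(int(layout.positions[r]))
                        for r in tip_ranks}

    margin = 40.0
    legend_w = 170.0 * max(1, len(barplot_layers)) if barplot_layers else 170.0
    bars_extent = sum(style.bar_band + 6.0 for _ in barplot_layers)

    s = None      # pixel scale (circular/unrooted)
    row_h = None  # per-tip row height (rectangular)
    if layout.kind == "rectangular":
        tree_w, row_h = 520.0, max(4.0, min(16.0, 640.0 / max(n_tips, 1)))
        xmax = float(layout.x.max()) or 1.0
        sx = tree_w / xmax
        def TX(x): return margin + x * sx
        def TY(y): return margin + y * row_h
        width = margin * 2 + tree_w + bars_extent + legend_w
        height = margin * 2 + row_h * max(n_tips - 1, 1) + 20.0
    elif layout.kind == "circular":
        rmax = float(layout.radius.max()) or 1.0
        half = 300.0
        s = (half - bars_extent - 10.0) / rmax if bars_extent else half / rmax
        s = max(s, 1e-6)
        cx = margin + half
        cy = margin + half
        def TX(x): return cx + x * s
        def TY(y): return cy - y * s
        width = margin * 2 + 2 * half + legend_w
        height = margin * 2 + 2 * half
    else:
        span = max(float(np.ptp(layout.x)), float(np.ptp(layout.y)), 1e-9)
        s = 560.0 / span
        x0, y0 = float(layout.x.min()), float(layout.y.max())
        def TX(x): return margin + (x - x0) * s
        def TY(y): return margin + (y0 - y) * s
        width = margin * 2 + 560.0 + legend_w
        height = margin * 2 + 560.0

    svg = _Svg()
    parent_rank = np.full(n, -1, dtype=np.int64)
    for r, p in enumerate(layout.positions):
        par = tree.parent(int(p))
        if par != -1:
            parent_rank[r] = rank_of_pos[par]

    # ---- edges ----
    if layout.kind == "rectangular":
        for r in range(1, n):
            pr = parent_rank[r]
            svg.line(TX(layout.x[pr]), TY(layout.y[r]),
                     TX(layout.x[r]), TY(layout.y[r]), cls="edge")
        for r, (vx, ylo, yhi) in sorted(layout.vlines.items()):
            svg.line(TX(vx), TY(ylo), TX(vx), TY(yhi), cls="connector")
    elif layout.kind == "circular":
        for r in range(1, n):
            pr = parent_rank[r]
            a = float(layout.angle[r])
            r0, r1 = float(layout.radius[pr]), float(layout.radius[r])
            svg.line(TX(r0 * np.cos(a)), TY(r0 * np.sin(a)),
                     TX(r1 * np.cos(a)), TY(r1 * np.sin(a)), cls="edge")
        for r, (rad, a0, a1) in sorted(layout.arcs.items()):
            if rad <= 0 or a1 <= a0:
                continue
            p0 = (TX(rad * np.cos(a0)), TY(rad * np.sin(a0)))
            p1 = (TX(rad * np.cos(a1)), TY(rad * np.sin(a1)))
            large = 1 if (a1 - a0) > np.pi else 0
            svg.path(f"M {_f(p0[0])} {_f(p0[1])} A {_f(rad * s)} "
                     f"{_f(rad * s)} 0 {large} 0 {_f(p1[0])} {_f(p1[1])}")
    else:
        for r in range(1, n):
            pr = parent_rank[r]
            svg.line(TX(layout.x[pr]), TY(layout.y[pr]),
                     TX(layout.x[r]), TY(layout.y[r]), cls="edge")

    # ---- collapsed clade wedges ----
    for cc in sorted(collapsed or [], key=lambda c: c.position):
        r = rank_of_pos[cc.position]
        tip_pos = tree.descendant_tip_positions(cc.position)
        trs = [rank_of_pos[int(p)] for p in tip_pos]
        if layout.kind == "rectangular":
            far = max(float(layout.x[t]) for t in trs)
            ylo = min(float(layout.y[t]) for t in trs)
            yhi = max(float(layout.y[t]) for t in trs)
            pts = [(TX(layout.x[r]), TY(layout.y[r])),
                   (TX(far), TY(ylo)), (TX(far), TY(yhi))]
            lx, ly = TX(far) + 4, TY(layout.y[r]) + 3
        elif layout.kind == "circular":
            far = max(float(layout.radius[t]) for t in trs)
            alo = min(float(layout.angle[t]) for t in trs)
            ahi = max(float(layout.angle[t]) for t in trs)
            pts = [(TX(layout.x[r]), TY(layout.y[r])),
                   (TX(far * np.cos(alo)), TY(far * np.sin(alo))),
                   (TX(far * np.cos(ahi)), TY(far * np.sin(ahi)))]
            lx, ly = pts[1][0] + 4, pts[1][1]
        else:
            far = max(np.hypot(float(layout.x[t]), float(layout.y[t]))
                      for t in trs)
            pts = [(TX(layout.x[r]), TY(layout.y[r]))] + \
                  [(TX(layout.x[t]), TY(layout.y[t])) for t in trs[:2]]
            lx, ly = pts[0][0] + 4, pts[0][1]
        svg.add('<g class="collapsed-clade">')
        svg.polygon(pts, fill="#888888")
        svg.text(lx, ly, f"{cc.value} ({cc.tip_count} tips)", size=9)
        svg.add("</g>")

    # ---- node color dots ----
    for r in sorted((node_colors or {})):
        svg.circle(TX(layout.x[r]), TY(layout.y[r]), 2.5, node_colors[r])

    # ---- barplot layers ----
    legends: list[tuple[str, list[tuple[str, str]]]] = []
    for li, layer in enumerate(barplot_layers):
        offset = 10.0 + li * (style.bar_band + 6.0)
        entries = _draw_layer(svg, layer, layout, tree, style, offset,
                              tip_ranks, tip_name_of_rank, TX, TY, s, row_h)
        legends.append((layer.field_name, entries))

    # ---- legends ----
    lx0 = width - legend_w + 10.0
    ly0 = margin
    for name, entries in legends:
        svg.add('<g class="legend">')
        svg.text(lx0, ly0, name, size=11)
        yy = ly0 + 14.0
        for label, color in entries:
            svg.rect(lx0, yy - 8, 10, 10, color)
            svg.text(lx0 + 14, yy, label, size=9)
            yy += 13.0
        svg.add("</g>")
        ly0 = yy + 16.0

    doc = ['<?xml version="1.0" encoding="UTF-8"?>',
           f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
           f'width="{_f(width)}" height="{_f(height)}" '
           f'viewBox="0 0 {_f(width)} {_f(height)}">',
           '<rect width="100%" height="100%" fill="#ffffff"/>']
    doc.extend(svg.parts)
    doc.append("</svg>")
    with open(out_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(doc) + "\n")


def _draw_layer(svg, layer, layout, tree, style, offset, tip_ranks,
                tip_name_of_rank, TX, TY, s, row_h):
    """Draw one barplot layer; returns its legend entries."""
    band = style.bar_band
    entries: list[tuple[str, str]] = []
    if layer.kind == "categorical_stacked":
        pooled = {}
        for tip, pay in layer.payload.items():
            for c in (pay or {}):
                pooled[c] = pooled.get(c, 0) + 1
        cats = sorted(pooled)
        cmap = categorical_color_map(cats, style)
        entries = [(c, cmap[c]) for c in cats]
    else:
        vals = [v for v in layer.payload.values()
                if v is not None and not (isinstance(v, float) and np.isnan(v))]
        vmin = min(vals) if vals else 0.0
        vmax = max(vals) if vals else 1.0
        for frac, label in ((0.0, f"min = {_f(vmin)}"),
                            (0.5, "mid"), (1.0, f"max = {_f(vmax)}")):
            v = vmin + frac * (vmax - vmin)
            entries.append((label, continuous_color(
                v, vmin, vmax, style, diverging=layer.diverging)))

    if layout.kind == "rectangular":
        base_x = TX(float(layout.x.max())) + offset
        half_h = max(1.5, (row_h or 10.0) * 0.4)
        for r in tip_ranks:
            tip = tip_name_of_rank[int(r)]
            pay = layer.payload.get(tip)
            if pay is None or pay == {}:
                continue
            yc = TY(layout.y[int(r)])
            svg.add(f'<g class="bar-group" data-tip="{tip}">')
            if layer.kind == "categorical_stacked":
                xx = base_x
                for c in sorted(pay):
                    w = band * pay[c]
                    svg.rect(xx, yc - half_h, w, 2 * half_h,
                             dict(entries)[c])
                    xx += w
            else:
                _numeric_bar(svg, layer, style, pay, vmin, vmax,
                             base_x, yc - half_h, band, 2 * half_h)
            svg.add("</g>")
    else:  # circular rings
        base_r = float(layout.radius.max()) + (offset + 2.0) / (s or 1.0)
        band_r = band / (s or 1.0)
        n_tips = tip_ranks.size
        dwedge = (2.0 * np.pi / max(n_tips, 1)) * 0.9
        for r in tip_ranks:
            tip = tip_name_of_rank[int(r)]
            pay = layer.payload.get(tip)
            if pay is None or pay == {}:
                continue
            a = float(layout.angle[int(r)])
            a0, a1 = a - dwedge / 2.0, a + dwedge / 2.0
            svg.add(f'<g class="bar-group" data-tip="{tip}">')
            if layer.kind == "categorical_stacked":
                rr = base_r
                for c in sorted(pay):
                    dr = band_r * pay[c]
                    _ring_wedge(svg, TX, TY, rr, rr + dr, a0, a1,
                                dict(entries)[c])
                    rr += dr
            else:
                v = pay
                t = 0.5 if vmax <= vmin else (v - vmin) / (vmax - vmin)
                ln = band_r if layer.numeric_encoding == "color" else \
                    band_r * (0.05 + 0.95 * t)
                col = continuous_color(v, vmin, vmax, style,
                                       diverging=layer.diverging) \
                    if layer.numeric_encoding in ("color", "both") \
                    else "#888888"
                _ring_wedge(svg, TX, TY, base_r, base_r + ln, a0, a1, col)
            svg.add("</g>")
    return entries


def _numeric_bar(svg, layer, style, value, vmin, vmax, x, y, band, h):
    t = 0.5 if vmax <= vmin else (value - vmin) / (vmax - vmin)
    t = min(1.0, max(0.0, t))
    length = band if layer.numeric_encoding == "color" else \
        style.bar_min_len + (band - style.bar_min_len) * t
    color = continuous_color(value, vmin, vmax, style,
                             diverging=layer.diverging) \
        if layer.numeric_encoding in ("color", "both") else "#888888"
    svg.rect(x, y, length, h, color)


def _ring_wedge(svg, TX, TY, r0, r1, a0, a1, color):
    p00 = (TX(r0 * np.cos(a0)), TY(r0 * np.sin(a0)))
    p01 = (TX(r0 * np.cos(a1)), TY(r0 * np.sin(a1)))
    p10 = (TX(r1 * np.cos(a0)), TY(r1 * np.sin(a0)))
    p11 = (TX(r1 * np.cos(a1)), TY(r1 * np.sin(a1)))
    rs0 = np.hypot(p00[0] - TX(0), p00[1] - TY(0))
    rs1 = np.hypot(p10[0] - TX(0), p10[1] - TY(0))
    d = (f"M {_f(p00[0])} {_f(p00[1])} "
         f"A {_f(rs0)} {_f(rs0)} 0 0 0 {_f(p01[0])} {_f(p01[1])} "
         f"L {_f(p11[0])} {_f(p11[1])} "
         f"A {_f(rs1)} {_f(rs1)} 0 0 1 {_f(p10[0])} {_f(p10[1])} Z")
    svg.path(d, fill=color, stroke="none")
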