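"""SVG rendering: synteny map with dot plots, gene arrows, and guide tree.

The figure is a stack of horizontal sequence tracks in layout order. Each
HSP surviving the display filter becomes a shaded ribbon joining its query
interval on the upper track to its subject interval on the lower track
(crossed when the strands oppose after the layout transforms) and a segment
in the pair's square dot-plot panel (ascending = forward, descending =
reverse). Gene features are drawn as strand-oriented arrows with embedded
``<title>`` labels. Output is standalone SVG 1.1, byte-deterministic for
identical inputs and options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

from .layout import Layout
from .pairalign import HitSet, Hsp
from .similarity import GuideTree, TreeNode

import math


@dataclass
class DisplayFilter:
    """Thresholds on identity, bit score, and hit length; defaults show all."""

    min_identity_pct: float = 0.0
    min_bit_score: float = 0.0
    min_hit_length: int = 0


def filter_hits(hsps: list[Hsp], f: DisplayFilter) -> list[Hsp]:
    """HSPs passing all three thresholds (conjunction)."""
    return [
        h
        for h in hsps
        if h.identity_pct >= f.min_identity_pct
        and h.bit_score >= f.min_bit_score
        and h.length >= f.min_hit_length
    ]


@dataclass
class RenderOptions:
    px_per_kb: float = 20.0
    track_height: int = 10
    track_gap: int = 70
    margin: int = 20
    dotplot_size: int = 100
    show_dotplots: bool = True
    show_genes: bool = True
    color_scheme: str = "identity"  # or "uniform"
    uniform_color: str = "#9ecae1"
    font_size: int = 10


def _identity_color(identity_pct: float) -> str:
    """Linear light->dark blue gradient over identity 0..100."""
    lo = (0xDE, 0xEB, 0xF7)
    hi = (0x08, 0x30, 0x6B)
    t = min(1.0, max(0.0, identity_pct / 100.0))
    rgb = tuple(round(l + t * (h - l)) for l, h in zip(lo, hi))
    return "#%02x%02x%02x" % rgb


def ribbon_color(identity_pct: float, options: RenderOptions) -> str:
    if options.color_scheme == "uniform":
        return options.uniform_color
    return _identity_color(identity_pct)


@dataclass
class Ribbon:
    pair_index: int
    hsp: Hsp
    upper: tuple[int, int]  # display bp interval on the upper track
    lower: tuple[int, int]
    crossed: bool  # strands oppose after transforms


@dataclass
class DotSegment:
    pair_index: int
    x: tuple[int, int]  # display bp on upper sequence
    y: tuple[int, int]  # display bp on lower sequence
    reversed_: bool


@dataclass
class GeneArrow:
    track_index: int
    start: int  # display bp
    end: int
    forward: bool  # display direction after inversion
    label: str | None
    color: str


@dataclass
class SyntenyFigure:
    layout: Layout
    ribbons: list[Ribbon] = field(default_factory=list)
    dot_segments: list[DotSegment] = field(default_factory=list)
    gene_arrows: list[GeneArrow] = field(default_factory=list)
    options: RenderOptions = field(default_factory=RenderOptions)


def build_figure(
    layout: Layout,
    hits: HitSet,
    display_filter: DisplayFilter | None = None,
    options: RenderOptions | None = None,
) -> SyntenyFigure:
    """Assemble the renderable scene in display-bp coordinates."""
    f = display_filter or DisplayFilter()
    opts = options or RenderOptions()
    fig = SyntenyFigure(layout=layout, options=opts)
    items = layout.items
    for i in range(len(items) - 1):
        (up_rec, up_t), (lo_rec, lo_t) = items[i], items[i + 1]
        for h in filter_hits(hits.get(up_rec.id, lo_rec.id), f):
            crossed = h.subject_reversed ^ up_t.inverted ^ lo_t.inverted
            upper = up_t.map_interval(h.qstart, h.qend)
            lower = lo_t.map_interval(h.sstart, h.send)
            fig.ribbons.append(
                Ribbon(pair_index=i, hsp=h, upper=upper, lower=lower, crossed=crossed)
            )
            fig.dot_segments.append(
                DotSegment(pair_index=i, x=upper, y=lower, reversed_=crossed)
            )
    if opts.show_genes:
        for i, (rec, t) in enumerate(items):
            for g in rec.genes:
                a, b = t.map_interval(g.start, g.end)
                forward = (g.strand == "+") ^ t.inverted
                fig.gene_arrows.append(
                    GeneArrow(
                        track_index=i,
                        start=a,
                        end=b,
                        forward=forward,
                        label=g.label,
                        color=g.color or "#808080",
                    )
                )
    # strongest hits drawn last (on top)
    fig.ribbons.sort(key=lambda r: (r.hsp.identity_pct, r.pair_index,
                                    r.upper[0], r.lower[0]))
    return fig


def _f(x: float) -> str:
    return f"{x:.2f}"


def write_svg(fig: SyntenyFigure, path: str | Path) -> None:
    """Write the synteny figure as standalone, deterministic SVG 1.1."""
    opts = fig.options
    items = fig.layout.items
    scale = opts.px_per_kb / 1000.0
    minx = min(t.offset for _, t in items)
    maxx = max(t.offset + t.length for _, t in items)
    left = opts.margin + (opts.dotplot_size + 2 * opts.margin if opts.show_dotplots else 0)

    def px(bp: float) -> float:
        return left + (bp - minx) * scale

    def track_y(i: int) -> float:
        return opts.margin + 14 + i * (opts.track_height + opts.track_gap)

    width = px(maxx) + opts.margin + 120
    height = track_y(len(items) - 1) + opts.track_height + opts.margin + 30
    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(width)}" height="{_f(height)}">'
    )
    out.append('<rect width="100%" height="100%" fill="#ffffff"/>')

    # ribbons first (under the tracks)
    for k, r in enumerate(fig.ribbons):
        ty = track_y(r.pair_index) + opts.track_height
        by = track_y(r.pair_index + 1)
        qa, qb = px(r.upper[0]), px(r.upper[1])
        sa, sb = px(r.lower[0]), px(r.lower[1])
        if r.crossed:
            sa, sb = sb, sa
        color = ribbon_color(r.hsp.identity_pct, opts)
        out.append(
            f'<path id="ribbon{k}" class="ribbon" d="M {_f(qa)} {_f(ty)} '
            f'L {_f(qb)} {_f(ty)} L {_f(sb)} {_f(by)} L {_f(sa)} {_f(by)} Z" '
            f'fill="{color}" fill-opacity="0.65" stroke="none"/>'
        )

    # tracks and labels
    for i, (rec, t) in enumerate(items):
        y = track_y(i)
        x0, x1 = px(t.offset), px(t.offset + t.length)
        out.append(
            f'<rect class="track" x="{_f(x0)}" y="{_f(y)}" '
            f'width="{_f(x1 - x0)}" height="{opts.track_height}" '
            f'fill="#d9d9d9" stroke="#555555" stroke-width="0.5"/>'
        )
        lbl = escape(rec.id) + (" (inverted)" if t.inverted else "")
        out.append(
            f'<text class="tracklabel" x="{_f(x0)}" y="{_f(y - 3)}" '
            f'font-family="sans-serif" font-size="{opts.font_size}">{lbl}</text>'
        )

    # gene arrows
    if opts.show_genes:
        for k, g in enumerate(fig.gene_arrows):
            y = track_y(g.track_index)
            h = opts.track_height
            a, b = px(g.start), px(g.end)
            head = min(6.0, (b - a) / 3.0)
            if g.forward:
                pts = [(a, y), (b - head, y), (b, y + h / 2), (b - head, y + h), (a, y + h)]
            else:
                pts = [(b, y), (a + head, y), (a, y + h / 2), (a + head, y + h), (b, y + h)]
            pstr = " ".join(f"{_f(x)},{_f(yy)}" for x, yy in pts)
            title = f"<title>{escape(g.label)}</title>" if g.label else ""
            out.append(
                f'<polygon id="gene{k}" class="gene" points="{pstr}" '
                f'fill="{g.color}" stroke="#333333" stroke-width="0.5">'
                f"{title}</polygon>"
            )

    # dot plots, one square panel per consecutive pair, on the left
    if opts.show_dotplots:
        D = opts.dotplot_size
        for i in range(len(items) - 1):
            y0 = (track_y(i) + track_y(i + 1) + opts.track_height) / 2 - D / 2
            x0 = opts.margin
            out.append(
                f'<rect class="dotpanel" x="{_f(x0)}" y="{_f(y0)}" width="{D}" '
                f'height="{D}" fill="none" stroke="#888888" stroke-width="0.5"/>'
            )
            (up_rec, up_t), (lo_rec, lo_t) = items[i], items[i + 1]
            ux0, uspan = up_t.offset, up_rec.length
            ly0, lspan = lo_t.offset, lo_rec.length
            for seg in fig.dot_segments:
                if seg.pair_index != i:
                    continue
                xa = x0 + (seg.x[0] - ux0) / uspan * D
                xb = x0 + (seg.x[1] - ux0) / uspan * D
                if seg.reversed_:
                    ya = y0 + (seg.y[1] - ly0) / lspan * D
                    yb = y0 + (seg.y[0] - ly0) / lspan * D
                else:
                    ya = y0 + (seg.y[0] - ly0) / lspan * D
                    yb = y0 + (seg.y[1] - ly0) / lspan * D
                out.append(
                    f'<line class="dotseg" x1="{_f(xa)}" y1="{_f(ya)}" '
                    f'x2="{_f(xb)}" y2="{_f(yb)}" stroke="#1f4e79" stroke-width="1"/>'
                )

    # identity legend
    if opts.color_scheme == "identity":
        lx = width - 110
        ly = height - 26
        for j in range(10):
            c = _identity_color((j + 0.5) * 10)
            out.append(
                f'<rect class="legend" x="{_f(lx + j * 9)}" y="{_f(ly)}" '
                f'width="9" height="8" fill="{c}"/>'
            )
        out.append(
            f'<text class="legendlabel" x="{_f(lx)}" y="{_f(ly - 3)}" '
            f'font-family="sans-serif" font-size="8">% identity 0-100</text>'
        )

    out.append("</svg>")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# guide-tree figures

def _node_depths(node: TreeNode, root_height: float) -> float:
    return root_height - node.height


def _rect_positions(
    node: TreeNode, root_height: float, counter: list[int], scale: float, dy: float
) -> tuple[dict, float]:
    """Assign (x, y) per node; returns ({id(node): (x, y)}, node_y)."""
    pos: dict[int, tuple[float, float]] = {}
    x = _node_depths(node, root_height) * scale
    if node.is_leaf:
        y = counter[0] * dy
        counter[0] += 1
        pos[id(node)] = (x, y)
        return pos, y
    ys = []
    for c in node.children:
        sub, cy = _rect_positions(c, root_height, counter, scale, dy)
        pos.update(sub)
        ys.append(cy)
    y = sum(ys) / len(ys)
    pos[id(node)] = (x, y)
    return pos, y


def write_tree_svg(
    tree: GuideTree, path: str | Path, layout: str = "rectangular",
    options: RenderOptions | None = None,
) -> None:
    """Render the guide tree as SVG in rectangular or circular layout."""
    if layout not in ("rectangular", "circular"):
        raise ValueError(f"unknown tree layout {layout!r}")
    opts = options or RenderOptions()
    root = tree.root
    leaves = tree.leaf_order
    n = len(leaves)
    out: list[str] = ['<?xml version="1.0" encoding="UTF-8"?>']
    if layout == "rectangular":
        dy, xspan, margin = 18.0, 260.0, 20.0
        scale = xspan / max(root.height, 1e-9)
        pos, _ = _rect_positions(root, root.height, [0], scale, dy)
        width = xspan + 200
        height = (n - 1) * dy + 2 * margin + 20
        out.append(
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_f(width)}" height="{_f(height)}">'
        )
        out.append('<rect width="100%" height="100%" fill="#ffffff"/>')

        def draw(node: TreeNode) -> None:
            x, y = pos[id(node)]
            if node.is_leaf:
                out.append(
                    f'<text class="leaf" x="{_f(x + margin + 4)}" '
                    f'y="{_f(y + margin + 3)}" font-family="sans-serif" '
                    f'font-size="{opts.font_size}">{escape(node.name)}</text>'
                )
                return
            ys = [pos[id(c)][1] for c in node.children]
            out.append(
                f'<line class="edge" x1="{_f(x + margin)}" y1="{_f(min(ys) + margin)}" '
                f'x2="{_f(x + margin)}" y2="{_f(max(ys) + margin)}" '
                f'stroke="#333333" stroke-width="1"/>'
            )
            for c in node.children:
                cx, cy = pos[id(c)]
                out.append(
                    f'<line class="edge" x1="{_f(x + margin)}" y1="{_f(cy + margin)}" '
                    f'x2="{_f(cx + margin)}" y2="{_f(cy + margin)}" '
                    f'stroke="#333333" stroke-width="1"/>'
                )
                draw(c)

        draw(root)
    else:  # circular
        R, margin = 150.0, 90.0
        cx0 = cy0 = R + margin
        width = height = 2 * (R + margin)
        scale = R / max(root.height, 1e-9)
        angle = {leaf: 2 * math.pi * i / n for i, leaf in enumerate(leaves)}
        out.append(
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_f(width)}" height="{_f(height)}">'
        )
        out.append('<rect width="100%" height="100%" fill="#ffffff"/>')

        def node_angle(node: TreeNode) -> float:
            ls = node.leaves()
            return sum(angle[l] for l in ls) / len(ls)

        def polar(r: float, a: float) -> tuple[float, float]:
            return cx0 + r * math.cos(a), cy0 + r * math.sin(a)

        def draw_c(node: TreeNode) -> None:
            r = _node_depths(node, root.height) * scale
            a = node_angle(node)
            if node.is_leaf:
                tx, ty = polar(R + 6, a)
                out.append(
                    f'<text class="leaf" x="{_f(tx)}" y="{_f(ty)}" '
                    f'font-family="sans-serif" font-size="{opts.font_size}">'
                    f"{escape(node.name)}</text>"
                )
                return
            angles = [node_angle(c) for c in node.children]
            a0, a1 = min(angles), max(angles)
            p0, p1 = polar(r, a0), polar(r, a1)
            large = 1 if (a1 - a0) > math.pi else 0
            if r > 0:
                out.append(
                    f'<path class="edge" d="M {_f(p0[0])} {_f(p0[1])} '
                    f'A {_f(r)} {_f(r)} 0 {large} 1 {_f(p1[0])} {_f(p1[1])}" '
                    f'fill="none" stroke="#333333" stroke-width="1"/>'
                )
            for c in node.children:
                ca = node_angle(c)
                cr = _node_depths(c, root.height) * scale
                q0, q1 = polar(r, ca), polar(cr, ca)
                out.append(
                    f'<line class="edge" x1="{_f(q0[0])}" y1="{_f(q0[1])}" '
                    f'x2="{_f(q1[0])}" y2="{_f(q1[1])}" '
                    f'stroke="#333333" stroke-width="1"/>'
                )
                draw_c(c)

        draw_c(root)
    out.append("</svg>")
    Path(path).write_text("\n".join(out) + "\n")
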