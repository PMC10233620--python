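"""SNFG (3rd edition) diagram rendering with validation highlights.

Each monosaccharide is drawn as its standard SNFG glyph (GlcNAc blue
square, mannose green circle, galactose yellow circle, fucose red
triangle, sialic acid purple diamond) with the asparagine root at the
right and the tree growing leftwards.  Rounded orange backing rectangles
are drawn behind standout linkages (Z-score below the outlier threshold)
and behind rings in a non-minimal conformation; grey backings mark
linkages that could not be validated for lack of data.  Output is plain
SVG 1.1 text, byte-identical across runs for identical reports.
"""

from __future__ import annotations

import math
from typing import Optional

from .chem import MONOSACCHARIDES

__all__ = ["layout_tree", "render_svg"]

NODE = 36          # glyph edge / diameter, px
DX = 110           # horizontal spacing per tree depth
DY = 70            # vertical spacing per leaf slot
MARGIN = 50

ORANGE = "#F47B20"
GREY = "#B8B8B8"

_ANOMER_SYMBOL = {"alpha": "α", "beta": "β"}


def layout_tree(tree) -> dict:
    """Deterministic layered layout: residue key -> (x, y) in px.

    The root is placed at the right, depth grows leftward; sibling
    branches are stacked by acceptor position, higher positions on top
    (so a 1,3 arm sits below a 1,6 arm, following SNFG convention).
    """
    depth: dict = {tree.root.key: 0}
    for link in tree.edges:  # BFS order guarantees acceptor seen first
        depth[link.donor.key] = depth[link.acceptor.key] + 1
    max_depth = max(depth.values()) if depth else 0

    def ordered_children(residue):
        pairs = [(e.acceptor_position, e.donor) for e in tree.edges if e.acceptor is residue]
        pairs.sort(key=lambda p: (-p[0], p[1].chain_id, p[1].seq_num))
        return [d for _, d in pairs]

    y: dict = {}
    slot = [0]

    def assign(residue):
        children = ordered_children(residue)
        if not children:
            y[residue.key] = slot[0] * DY
            slot[0] += 1
            return y[residue.key]
        ys = [assign(c) for c in children]
        y[residue.key] = sum(ys) / len(ys)
        return y[residue.key]

    assign(tree.root)
    positions = {}
    for key, d in depth.items():
        positions[key] = (MARGIN + (max_depth - d) * DX, MARGIN + y[key])
    return positions


def _fmt(v: float) -> str:
    return f"{v:.1f}"


def _glyph(shape: str, color: str, x: float, y: float) -> str:
    cls = ' class="glyph"'
    h = NODE / 2
    style = f'fill="{color}" stroke="black" stroke-width="1.5"'
    if shape == "square":
        return (f'<rect{cls} x="{_fmt(x - h)}" y="{_fmt(y - h)}" '
                f'width="{NODE}" height="{NODE}" {style}/>')
    if shape == "circle":
        return f'<circle{cls} cx="{_fmt(x)}" cy="{_fmt(y)}" r="{_fmt(h)}" {style}/>'
    if shape == "triangle":
        pts = f"{_fmt(x)},{_fmt(y - h)} {_fmt(x - h)},{_fmt(y + h)} {_fmt(x + h)},{_fmt(y + h)}"
        return f'<polygon{cls} points="{pts}" {style}/>'
    if shape == "diamond":
        pts = (f"{_fmt(x)},{_fmt(y - h)} {_fmt(x + h)},{_fmt(y)} "
               f"{_fmt(x)},{_fmt(y + h)} {_fmt(x - h)},{_fmt(y)}")
        return f'<polygon{cls} points="{pts}" {style}/>'
    raise ValueError(f"unknown SNFG shape {shape!r}")


def _edge_backing(x1, y1, x2, y2, color: str, kind: str) -> str:
    cx, cy = (x1 + x2) / 2.0, (y1 + y2) / 2.0
    length = math.hypot(x2 - x1, y2 - y1) + 24
    angle = math.degrees(math.atan2(y2 - y1, x2 - x1))
    return (
        f'<rect class="linkage-backing-{kind}" x="{_fmt(cx - length / 2)}" '
        f'y="{_fmt(cy - 14)}" width="{_fmt(length)}" height="28" rx="10" '
        f'fill="{color}" transform="rotate({_fmt(angle)} {_fmt(cx)} {_fmt(cy)})"/>'
    )


def _edge_label(link) -> str:
    chem = MONOSACCHARIDES[link.donor.ccd_code]
    sym = _ANOMER_SYMBOL[chem.anomer]
    if link.acceptor.ccd_code == "ASN":
        return f"{sym}{chem.anomeric_position}"
    return f"{sym}{chem.anomeric_position},{link.acceptor_position}"


def render_svg(report) -> str:
    """Render one glycan report as a standalone SVG document."""
    tree = report.tree
    pos = layout_tree(tree)
    z_by_donor = {rec.source[1]: z for rec, z in report.linkage_results if rec.source}
    ring_by_key = {r.key: d for r, d in report.ring_diagnostics}

    xs = [p[0] for p in pos.values()]
    ys = [p[1] for p in pos.values()]
    width = max(xs) + MARGIN + NODE
    height = max(ys) + MARGIN

    backings, edges, glyphs, labels = [], [], [], []
    for link in tree.edges:
        x1, y1 = pos[link.donor.key]
        x2, y2 = pos[link.acceptor.key]
        donor_src = (link.donor.chain_id, link.donor.seq_num)
        z = z_by_donor.get(donor_src)
        if z is not None and z.flagged:
            backings.append(_edge_backing(x1, y1, x2, y2, ORANGE, "orange"))
        elif z is not None and not z.validated:
            backings.append(_edge_backing(x1, y1, x2, y2, GREY, "grey"))
        edges.append(
            f'<line class="linkage" x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
            f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" stroke="black" stroke-width="2"/>'
        )
        lx, ly = (x1 + x2) / 2.0, (y1 + y2) / 2.0 - 8
        labels.append(
            f'<text class="linkage-label" x="{_fmt(lx)}" y="{_fmt(ly)}" '
            f'font-size="13" text-anchor="middle">{_edge_label(link)}</text>'
        )

    for residue in tree.nodes:
        x, y = pos[residue.key]
        chem = MONOSACCHARIDES[residue.ccd_code]
        diag = ring_by_key.get(residue.key)
        if diag is not None and diag.conformer is not None \
                and diag.conformer.code != chem.minimal_conformer:
            pad = NODE / 2 + 8
            backings.append(
                f'<rect class="ring-backing-orange" x="{_fmt(x - pad)}" '
                f'y="{_fmt(y - pad)}" width="{_fmt(2 * pad)}" height="{_fmt(2 * pad)}" '
                f'rx="10" fill="{ORANGE}"/>'
            )
        glyphs.append(_glyph(chem.snfg_shape, chem.snfg_color, x, y))

    rx, ry = pos[tree.root.key]
    labels.append(
        f'<text class="root-label" x="{_fmt(rx)}" y="{_fmt(ry + 5)}" '
        f'font-size="15" text-anchor="middle" font-family="sans-serif">Asn</text>'
    )

    body = "\n".join(backings + edges + glyphs + labels)
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
        f"{body}\n</svg>\n"
    )
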