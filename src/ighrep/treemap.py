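"""Nested CDR3 treemaps.

The canvas is divided hierarchically — first by V gene, each V rectangle
by J, and each V-J rectangle into one leaf per distinct V-J-CDR3
nucleotide sequence — with every area proportional to read frequency, so
a clonally expanded repertoire shows as a few large contiguous blocks
and a diverse one as dust. Rectangles are packed with the squarified
heuristic and ordered by area from largest at the bottom right to
smallest at the top left; leaf colors are drawn from a seeded generator,
so maps are deterministic per seed but colors do not match across maps.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clonotype import ClonotypeTable


@dataclass
class Rect:
    level: str  # V | VJ | VJCDR3
    label: str
    x: float
    y: float
    w: float
    h: float
    color: str = ""


@dataclass
class TreemapLayout:
    canvas: tuple[float, float]
    rectangles: list[Rect] = field(default_factory=list)

    def leaves(self) -> list[Rect]:
        return [r for r in self.rectangles if r.level == "VJCDR3"]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "level": r.level,
                    "label": r.label,
                    "x": r.x,
                    "y": r.y,
                    "w": r.w,
                    "h": r.h,
                    "color": r.color,
                }
                for r in self.rectangles
            ]
        )


def _worst(row: list[float], side: float) -> float:
    s = sum(row)
    return max(
        max(side * side * r / (s * s), s * s / (side * side * r)) for r in row
    )


def _squarify(
    areas: list[float], x: float, y: float, w: float, h: float
) -> list[tuple[float, float, float, float]]:
    """Squarified packing of pre-scaled areas (sum == w*h), largest first."""
    out: list[tuple[float, float, float, float]] = []
    remaining = list(areas)
    while remaining:
        side = min(w, h)
        row = [remaining.pop(0)]
        while remaining and _worst(row + [remaining[0]], side) <= _worst(row, side):
            row.append(remaining.pop(0))
        s = sum(row)
        if w >= h:
            sw = s / h if h > 0 else 0.0
            yy = y
            for r in row:
                rh = r / sw if sw > 0 else 0.0
                out.append((x, yy, sw, rh))
                yy += rh
            x += sw
            w -= sw
        else:
            sh = s / w if w > 0 else 0.0
            xx = x
            for r in row:
                rw = r / sh if sh > 0 else 0.0
                out.append((xx, y, rw, sh))
                xx += rw
            y += sh
            h -= sh
    return out


def _grouped(records, key) -> list[tuple[tuple, int]]:
    totals: dict[tuple, int] = {}
    for r in records:
        k = key(r)
        totals[k] = totals.get(k, 0) + r.copies
    return sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))


def layout_treemap(
    table: ClonotypeTable,
    canvas: tuple[float, float] = (1000.0, 600.0),
    seed: int = 0,
) -> TreemapLayout:
    """Three-level nested layout (V -> V-J -> V-J-CDR3) of one sample.

    Deterministic for a fixed seed; the seed only affects colors.
    """
    W, H = canvas
    if W <= 0 or H <= 0:
        raise ValueError("zero-area canvas")
    if not table.records:
        raise ValueError("cannot lay out an empty table")
    total = float(table.total_copies)
    layout = TreemapLayout((W, H))
    rng = np.random.default_rng(seed)

    def scale(items, area):
        s = sum(n for _, n in items)
        return [n / s * area for _, n in items]

    v_groups = _grouped(table.records, lambda r: (r.v_call,))
    v_rects = _squarify(scale(v_groups, W * H), 0.0, 0.0, W, H)
    for (vk, _), (vx, vy, vw, vh) in zip(v_groups, v_rects):
        layout.rectangles.append(Rect("V", vk[0], vx, vy, vw, vh))
        vj_records = [r for r in table.records if r.v_call == vk[0]]
        vj_groups = _grouped(vj_records, lambda r: (r.v_call, r.j_call))
        vj_rects = _squarify(scale(vj_groups, vw * vh), vx, vy, vw, vh)
        for (vjk, _), (jx, jy, jw, jh) in zip(vj_groups, vj_rects):
            layout.rectangles.append(Rect("VJ", f"{vjk[0]}|{vjk[1]}", jx, jy, jw, jh))
            leaf_records = [r for r in vj_records if r.j_call == vjk[1]]
            leaf_groups = _grouped(
                leaf_records, lambda r: (r.v_call, r.j_call, r.cdr3_nt)
            )
            leaf_rects = _squarify(scale(leaf_groups, jw * jh), jx, jy, jw, jh)
            for (lk, _), (lx, ly, lw, lh) in zip(leaf_groups, leaf_rects):
                layout.rectangles.append(
                    Rect("VJCDR3", f"{lk[0]}|{lk[1]}|{lk[2]}", lx, ly, lw, lh)
                )

    # largest-first packing starts at the top left; reflect both axes so the
    # largest rectangle sits at the bottom right
    for r in layout.rectangles:
        r.x = W - r.x - r.w
        r.y = H - r.y - r.h

    for r in layout.rectangles:
        if r.level == "VJCDR3":
            rgb = colorsys.hsv_to_rgb(
                rng.random(), 0.35 + 0.45 * rng.random(), 0.65 + 0.3 * rng.random()
            )
            r.color = "#%02x%02x%02x" % tuple(int(255 * c) for c in rgb)
    return layout


def render_svg(layout: TreemapLayout, corner_radius: float = 3.0) -> str:
    """Serialize a layout as an SVG document (rounded, labeled leaves)."""
    W, H = layout.canvas
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{W:.0f}" height="{H:.0f}" '
        f'viewBox="0 0 {W:.0f} {H:.0f}">'
    ]
    for r in layout.leaves():
        parts.append(
            f'<rect x="{r.x:.4f}" y="{r.y:.4f}" width="{r.w:.4f}" height="{r.h:.4f}" '
            f'rx="{corner_radius:.2f}" fill="{r.color}" stroke="white" '
            f'stroke-width="0.5"><title>{r.label}</title></rect>'
        )
    for r in layout.rectangles:
        if r.level == "V":
            parts.append(
                f'<rect x="{r.x:.4f}" y="{r.y:.4f}" width="{r.w:.4f}" '
                f'height="{r.h:.4f}" fill="none" stroke="black" stroke-width="1.2"/>'
            )
    parts.append("</svg>")
    return "\n".join(parts)


def write_svg(
    layout: TreemapLayout, path: str | Path, corner_radius: float = 3.0
) -> None:
    Path(path).write_text(render_svg(layout, corner_radius))
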