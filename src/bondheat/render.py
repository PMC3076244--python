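"""Deterministic SVG depictions with heat-colored bonds.

Pure view layer: scores and colors come in via BondColoring and are never
modified here. Each bond is one ``<line>`` element whose stroke is the
bond's heat color; atoms other than carbon carry an element-colored label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chem_io import Molecule, compute_coords2d
from .coloring import BondColoring, DEFAULT_GRADIENT, Gradient, score_to_color


class RenderError(Exception):
    pass


#: CPK-like label palette; carbon is implicit (no label)
DEFAULT_PALETTE = {
    "N": "#0000ff",
    "O": "#ff0000",
    "S": "#b8860b",
    "P": "#ff8000",
    "F": "#00a000",
    "Cl": "#00a000",
    "Br": "#a52a2a",
    "I": "#940094",
}


@dataclass
class DepictionStyle:
    size: int = 300
    stroke_width: float = 3.0
    palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    background: str = "#ffffff"
    legend: bool = False
    font_size: int = 14

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("image size must be positive")


def _fitted_coords(
    molecule: Molecule, size: int, margin: float = 30.0
) -> list[tuple[float, float]]:
    coords = molecule.coords2d or compute_coords2d(molecule)
    xs = [x for x, _ in coords]
    ys = [y for _, y in coords]
    span = max(max(xs) - min(xs), max(ys) - min(ys), 1e-9)
    scale = (size - 2 * margin) / span
    cx, cy = (min(xs) + max(xs)) / 2, (min(ys) + max(ys)) / 2
    out = []
    for x, y in coords:
        px = size / 2 + (x - cx) * scale
        py = size / 2 - (y - cy) * scale  # flip y: SVG grows downward
        out.append((px, py))
    return out


def _panel_elements(
    coloring: BondColoring, style: DepictionStyle, ox: float = 0.0, oy: float = 0.0
) -> list[str]:
    mol = coloring.molecule
    pts = _fitted_coords(mol, style.size)
    parts = []
    for bond in mol.bonds:
        a, b = bond.atoms
        x1, y1 = pts[a]
        x2, y2 = pts[b]
        entry = coloring.entries.get(bond.index)
        color = entry.hex if entry is not None else "#000000"
        dash = ' stroke-dasharray="6,3"' if bond.order == "aromatic" else ""
        parts.append(
            f'<line id="bond-{bond.index}" class="bond" '
            f'x1="{ox + x1:.2f}" y1="{oy + y1:.2f}" '
            f'x2="{ox + x2:.2f}" y2="{oy + y2:.2f}" '
            f'stroke="{color}" stroke-width="{style.stroke_width}" '
            f'stroke-linecap="round"{dash}/>'
        )
        if bond.order in ("double", "triple"):
            # offset parallel stroke(s) to hint at bond multiplicity
            dx, dy = x2 - x1, y2 - y1
            norm = math.hypot(dx, dy) or 1.0
            px, py = -dy / norm * 3.0, dx / norm * 3.0
            reps = 1 if bond.order == "double" else 2
            for r in range(1, reps + 1):
                parts.append(
                    f'<line class="bond-multiplicity" '
                    f'x1="{ox + x1 + r * px:.2f}" y1="{oy + y1 + r * py:.2f}" '
                    f'x2="{ox + x2 + r * px:.2f}" y2="{oy + y2 + r * py:.2f}" '
                    f'stroke="{color}" stroke-width="{style.stroke_width * 0.6}"/>'
                )
    for idx, atom in enumerate(mol.atoms):
        if atom.element == "C" and atom.formal_charge == 0:
            continue
        x, y = pts[idx]
        fill = style.palette.get(atom.element, "#000000")
        label = atom.element
        if atom.formal_charge > 0:
            label += "+" if atom.formal_charge == 1 else f"{atom.formal_charge}+"
        elif atom.formal_charge < 0:
            label += "-" if atom.formal_charge == -1 else f"{-atom.formal_charge}-"
        parts.append(
            f'<circle cx="{ox + x:.2f}" cy="{oy + y:.2f}" r="{style.font_size * 0.75:.1f}" '
            f'fill="{style.background}"/>'
        )
        parts.append(
            f'<text class="atom" x="{ox + x:.2f}" y="{oy + y:.2f}" fill="{fill}" '
            f'font-size="{style.font_size}" font-family="sans-serif" '
            f'text-anchor="middle" dominant-baseline="central">{label}</text>'
        )
    return parts


def _legend_elements(style: DepictionStyle, gradient: Gradient, ox: float, oy: float) -> list[str]:
    parts = []
    steps = 20
    bar_h = style.size - 60
    for i in range(steps):
        nu = i / (steps - 1)
        r, g, b = score_to_color(nu, gradient)
        y = oy + 30 + bar_h * (1 - (i + 1) / steps)
        parts.append(
            f'<rect class="legend" x="{ox:.1f}" y="{y:.2f}" width="14" '
            f'height="{bar_h / steps:.2f}" fill="#{r:02x}{g:02x}{b:02x}"/>'
        )
    return parts


def _svg_document(width: float, height: float, body: list[str], background: str) -> str:
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:.0f}" height="{height:.0f}">\n'
        f'<rect x="0" y="0" width="{width:.0f}" height="{height:.0f}" fill="{background}"/>\n'
    )
    return head + "\n".join(body) + "\n</svg>\n"


def render_svg(
    coloring: BondColoring,
    style: Optional[DepictionStyle] = None,
    path=None,
    gradient: Gradient = DEFAULT_GRADIENT,
) -> str:
    """Render one molecule; returns the SVG text and optionally writes it."""
    style = style or DepictionStyle()
    body = _panel_elements(coloring, style)
    width = float(style.size)
    if style.legend:
        body += _legend_elements(style, gradient, ox=style.size - 24, oy=0)
    doc = _svg_document(width, style.size, body, style.background)
    if path is not None:
        try:
            with open(path, "w") as fh:
                fh.write(doc)
        except OSError as exc:
            raise RenderError(f"cannot write SVG to {path}: {exc}") from exc
    return doc


def render_grid(
    colorings: Sequence[BondColoring],
    style: Optional[DepictionStyle] = None,
    path=None,
    decision_values: Optional[Sequence[float]] = None,
    columns: Optional[int] = None,
) -> str:
    """Paginated grid of depictions captioned with names and prediction
    values (formatted to 3 decimals)."""
    if not colorings:
        raise RenderError("render_grid needs at least one coloring")
    style = style or DepictionStyle()
    if decision_values is not None and len(decision_values) != len(colorings):
        raise RenderError("decision_values length mismatch")
    n = len(colorings)
    cols = columns or max(1, math.ceil(math.sqrt(n)))
    rows = math.ceil(n / cols)
    caption_h = 24
    panel = style.size
    body = []
    for i, coloring in enumerate(colorings):
        r, c = divmod(i, cols)
        ox, oy = c * panel, r * (panel + caption_h)
        body.extend(_panel_elements(coloring, style, ox=ox, oy=oy))
        caption = coloring.molecule.name or f"molecule {i}"
        if decision_values is not None:
            caption += f"  f(x)={decision_values[i]:.3f}"
        body.append(
            f'<text class="caption" x="{ox + panel / 2:.1f}" y="{oy + panel + 16:.1f}" '
            f'font-size="12" font-family="sans-serif" text-anchor="middle" '
            f'fill="#000000">{caption}</text>'
        )
    doc = _svg_document(cols * panel, rows * (panel + caption_h), body, style.background)
    if path is not None:
        try:
            with open(path, "w") as fh:
                fh.write(doc)
        except OSError as exc:
            raise RenderError(f"cannot write SVG to {path}: {exc}") from exc
    return doc
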