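"""Channel visualization exports.

* :func:`box_diagram` — the 2D node-box metaphor: one *node box* per path
  tetrahedron holding four *atom boxes* (its vertex atoms); adjacent node
  boxes are joined by three connectors, the atoms of the shared triangle;
  consecutive atom boxes referring to the same atom are merged.  Atom boxes
  are colored by element, residue polarity, hydropathy, or conservation.
* :func:`render_svg` — a plain SVG rendering of a box diagram.
* :func:`projection_view` — the symmetric 2D projection of a channel bounded
  by ±radius(t), filled by color-mapping a second profile (blue = low,
  red = high, diverging); optionally split into upper/lower halves showing
  two different profiles.
* :func:`export_pymol` — a .pml script drawing the channel's union-of-balls
  (one sphere per path tetrahedron: its orthocenter and orthoradius) plus a
  selection of the lining residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import Normalize, to_hex

from .channels import Channel
from .exceptions import ParameterError
from .geometry import Triangulation
from .model_io import Structure
from .profiles import STANDARD_RESIDUES, Profile, load_scale

#: blue-to-red diverging map: blue = low values, red = high values
DIVERGING_CMAP = "coolwarm"

_POLAR = {"SER", "THR", "CYS", "TYR", "ASN", "GLN", "HIS", "TRP"}
_CHARGED = {"ASP", "GLU", "LYS", "ARG"}

_ELEMENT_COLORS = {"C": "#909090", "N": "#3050F8", "O": "#FF0D0D",
                   "S": "#FFFF30", "P": "#FF8000", "H": "#FFFFFF"}

COLOR_MODES = ("element", "polarity", "hydropathy", "conservation")


@dataclass
class AtomBox:
    atom: int           # atom index into the structure
    label: str
    color: str
    span: int = 1       # number of consecutive node boxes merged into this box


@dataclass
class BoxDiagram:
    """Plot-ready node-box representation of a channel."""

    node_boxes: list[list[int]]            # per node box: 4 atom indices (slot order)
    connectors: list[tuple[int, int, int]]  # per adjacency: shared-triangle atoms
    slots: np.ndarray                      # (n_boxes, 4) atom index per slot
    atom_boxes: list[list[AtomBox]] = field(default_factory=list)  # merged, per slot row
    tet_indices: list[int] = field(default_factory=list)           # path-local labels

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "node_boxes": [[int(a) for a in nb] for nb in self.node_boxes],
            "connectors": [[int(a) for a in c] for c in self.connectors],
            "tet_indices": self.tet_indices,
            "rows": [
                [{"atom": b.atom, "label": b.label, "color": b.color, "span": b.span}
                 for b in row]
                for row in self.atom_boxes
            ],
        }
        text = json.dumps(payload, indent=1)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _atom_color(structure: Structure, idx: int, color_by: str, conservation=None) -> str:
    a = structure.atoms[idx]
    if color_by == "element":
        return _ELEMENT_COLORS.get(a.element.upper(), "#B0B0B0")
    if color_by == "polarity":
        rn = a.residue_name.upper()
        if rn in _CHARGED:
            return "#2040C0"
        if rn in _POLAR:
            return "#40A0A0"
        if rn in STANDARD_RESIDUES:
            return "#C0A040"
        return "#B0B0B0"
    cmap = colormaps[DIVERGING_CMAP]
    if color_by == "hydropathy":
        scale = load_scale("hydropathy")
        v = scale.value(a.residue_name)
        if not np.isfinite(v):
            return "#B0B0B0"
        return to_hex(cmap(Normalize(-4.5, 4.5)(v)))
    if color_by == "conservation":
        if conservation is None:
            raise ParameterError("conservation coloring needs a ConservationTable")
        v = conservation.score(a.chain, a.residue_number)
        if not np.isfinite(v):
            return "#B0B0B0"
        return to_hex(cmap(Normalize(1.0, 9.0)(v)))
    raise ParameterError(f"unknown color_by {color_by!r}; valid: {COLOR_MODES}")


def box_diagram(channel: Channel, tri: Triangulation, structure: Structure,
                color_by: str = "element", conservation=None) -> BoxDiagram:
    """Build the node-box diagram of a channel.

    Slot ordering is stable: atoms shared with the previous tetrahedron keep
    their slot; the new vertex takes the freed slot.  Runs of the same atom in
    the same slot are merged into single atom boxes spanning several node
    boxes.
    """
    if color_by not in COLOR_MODES:
        raise ParameterError(f"unknown color_by {color_by!r}; valid: {COLOR_MODES}")
    path = channel.node_path
    n = len(path)
    slots = np.full((n, 4), -1, dtype=int)
    slots[0] = np.sort(tri.tets[path[0]])
    connectors: list[tuple[int, int, int]] = []
    for i in range(1, n):
        verts = set(int(v) for v in tri.tets[path[i]])
        shared = tuple(sorted(int(v) for v in tri.tris[channel.triangle_path[i - 1]]))
        connectors.append(shared)
        prev = slots[i - 1]
        row = np.full(4, -1, dtype=int)
        remaining = set(verts)
        for s in range(4):
            if int(prev[s]) in verts:
                row[s] = prev[s]
                remaining.discard(int(prev[s]))
        free = [s for s in range(4) if row[s] < 0]
        for s, v in zip(free, sorted(remaining)):
            row[s] = v
        slots[i] = row

    # merge runs per slot row
    rows: list[list[AtomBox]] = []
    for s in range(4):
        row: list[AtomBox] = []
        for i in range(n):
            a = int(slots[i, s])
            if row and row[-1].atom == a:
                row[-1].span += 1
            else:
                at = structure.atoms[a]
                row.append(AtomBox(
                    atom=a,
                    label=f"{at.residue_name}{at.residue_number}:{at.name}",
                    color=_atom_color(structure, a, color_by, conservation),
                ))
        rows.append(row)

    return BoxDiagram(
        node_boxes=[[int(v) for v in slots[i]] for i in range(n)],
        connectors=connectors,
        slots=slots,
        atom_boxes=rows,
        tet_indices=list(range(n)),
    )


def render_svg(diagram: BoxDiagram, path: str, box_w: float = 46.0,
               box_h: float = 22.0, gap: float = 18.0) -> None:
    """Render a box diagram as a standalone SVG file."""
    n = len(diagram.node_boxes)
    width = n * box_w + (n - 1) * gap + 20
    height = 4 * box_h + 60
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" font-family="monospace" font-size="8">'
    ]
    x0 = 10.0

    def bx(i: int) -> float:
        return x0 + i * (box_w + gap)

    # connectors between adjacent node boxes for the shared-triangle atoms
    for i, shared in enumerate(diagram.connectors):
        for s in range(4):
            a = diagram.slots[i, s]
            if a in shared and diagram.slots[i + 1, s] == a:
                y = 10 + s * box_h + box_h / 2
                parts.append(
                    f'<line x1="{bx(i) + box_w:.1f}" y1="{y:.1f}" '
                    f'x2="{bx(i + 1):.1f}" y2="{y:.1f}" stroke="#404040"/>'
                )
    # atom boxes (merged runs)
    for s, row in enumerate(diagram.atom_boxes):
        i = 0
        for box in row:
            x = bx(i)
            w = box.span * box_w + (box.span - 1) * gap
            y = 10 + s * box_h
            parts.append(
                f'<rect x="{x:.1f}" y="{y:.1f}" width="{w:.1f}" height="{box_h - 2:.1f}" '
                f'fill="{box.color}" stroke="black"/>'
                f'<text x="{x + 2:.1f}" y="{y + box_h / 2:.1f}">{box.label}</text>'
            )
            i += box.span
    # path-local tetrahedron indices under the node boxes
    for i, t in enumerate(diagram.tet_indices):
        parts.append(
            f'<text x="{bx(i) + box_w / 2 - 4:.1f}" y="{4 * box_h + 30:.1f}">{t}</text>'
        )
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def projection_view(radius: Profile, overlay: Profile,
                    second_overlay: Profile | None = None) -> dict:
    """Plot-ready data for the radius-projection view.

    Returns t, upper (+radius), lower (-radius), per-sample hex colors for
    the upper and lower fills (the overlay's minimum maps to the blue end of
    the diverging map, its maximum to red), and the region area
    2*integral(radius dt).
    """
    if len(radius.t) == 0 or len(overlay.t) == 0:
        raise ParameterError("empty profile")
    t = radius.t
    r = radius.values
    cmap = colormaps[DIVERGING_CMAP]

    def colors(p: Profile) -> list[str]:
        v = p.resample_onto(t)
        vmin, vmax = float(np.nanmin(v)), float(np.nanmax(v))
        norm = Normalize(vmin, vmax) if vmax > vmin else (lambda x: np.full_like(x, 0.5))
        return [to_hex(cmap(float(x))) for x in np.atleast_1d(norm(v))]

    upper_colors = colors(overlay)
    lower_colors = colors(second_overlay) if second_overlay is not None else upper_colors
    area = 2.0 * float(np.trapezoid(r, t))
    return {
        "t": t,
        "upper": r,
        "lower": -r,
        "upper_colors": upper_colors,
        "lower_colors": lower_colors,
        "split": second_overlay is not None,
        "area": area,
    }


def export_pymol(channel: Channel, tri: Triangulation, structure: Structure,
                 path: str, name: str = "channel") -> None:
    """Write a PyMOL script drawing the channel union-of-balls (one sphere
    per path tetrahedron: center at its orthocenter, radius its orthoradius)
    and selecting the lining residues.  Deterministic: same channel,
    byte-identical file."""
    lines = [
        "# PyMOL script generated by alphapore",
        f"# channel kind={channel.kind} length={channel.length:.3f} "
        f"bottleneck={channel.bottleneck_radius:.3f}",
        "from pymol import cmd",
    ]
    radii = np.sqrt(np.maximum(tri.tet_size[channel.node_path], 0.0))
    for i, (p, r) in enumerate(zip(channel.centerline, radii)):
        lines.append(
            f'cmd.pseudoatom("{name}", pos=[{p[0]:.3f}, {p[1]:.3f}, {p[2]:.3f}], '
            f'vdw={max(r, 0.0):.3f}, name="S{i}")'
        )
    lines += [
        f'cmd.show_as("spheres", "{name}")',
        f'cmd.color("marine", "{name}")',
    ]
    residues = sorted({
        (structure.atoms[v].chain, structure.atoms[v].residue_number)
        for t in channel.node_path for v in tri.tets[t]
    })
    sel = " or ".join(f"(chain {c} and resi {n})" for c, n in residues)
    lines.append(f'cmd.select("{name}_lining", "{sel}")')
    lines.append(f'cmd.show("sticks", "{name}_lining")')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
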