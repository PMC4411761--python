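"""Structure input/output and synthetic test structures.

A molecule is modelled as a union of balls: each atom is a ball of its van
der Waals radius, represented as a weighted point whose weight is the squared
radius.  This module reads PDB files into that representation, writes it back
out, reads per-residue conservation tables, and generates synthetic ball
arrangements (tubes with a known constriction, blobs, sealed shells,
multi-pore barrels) so that every downstream stage can be exercised with
known ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .exceptions import DegenerateInputError, FormatError, ParameterError

#: Bondi-style van der Waals radii (Å).  The table is total: unknown
#: elements fall back to carbon.  Configurable per call because bottleneck
#: radii shift with the radius table.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def vdw_radius(element: str, radii: dict[str, float] | None = None) -> float:
    """Van der Waals radius for an element symbol; total with carbon fallback."""
    table = VDW_RADII if radii is None else radii
    key = element.strip().capitalize()
    return table.get(key, table.get(key.upper(), DEFAULT_VDW_RADIUS))


@dataclass
class WeightedAtom:
    """An atom as a weighted point: weight equals the squared vdW radius."""

    serial: int
    element: str
    name: str
    residue_name: str
    residue_number: int
    chain: str
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ParameterError(f"atom {self.serial}: radius must be positive")

    @property
    def weight(self) -> float:
        return self.radius * self.radius


@dataclass
class Structure:
    """A set of weighted atoms; ``het_atoms`` keeps HETATM records that were
    excluded from the ball model but remain available for active-site
    seeding."""

    atoms: list[WeightedAtom]
    id: str = ""
    het_atoms: list[WeightedAtom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def centers(self) -> np.ndarray:
        return np.array([a.center for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def weights(self) -> np.ndarray:
        return np.array([a.weight for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def drop_duplicate_centers(self) -> "Structure":
        """Regular triangulations require distinct sites; later duplicates
        are dropped with a warning."""
        seen: dict[tuple, int] = {}
        kept = []
        for a in self.atoms:
            key = tuple(np.round(a.center, 6))
            if key in seen:
                warnings.warn(
                    f"duplicate atom center at {key} (serial {a.serial}) dropped",
                    stacklevel=2,
                )
                continue
            seen[key] = a.serial
            kept.append(a)
        return Structure(kept, self.id, self.het_atoms)


@dataclass
class ConservationTable:
    """Per-residue conservation scores keyed by (chain, residue_number)."""

    entries: dict[tuple[str, int], float] = field(default_factory=dict)
    missing: float = float("nan")

    def score(self, chain: str, residue_number: int) -> float:
        return self.entries.get((chain, residue_number), self.missing)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi)
# ---------------------------------------------------------------------------

def read_pdb(
    path: str,
    keep_hetatm: bool = False,
    keep_hydrogens: bool = False,
    radii: dict[str, float] | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Altloc handling keeps only blank or 'A' conformers; waters are always
    excluded from the ball model; HETATM atoms are excluded by default but
    retained in ``het_atoms`` for active-site seeding.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[0]
    atoms: list[WeightedAtom] = []
    het: list[WeightedAtom] = []
    for chain in model:
        for res in chain:
            is_water = res.name.strip() in _WATER_NAMES
            for at in res:
                if at.altloc not in ("\0", "", "A"):
                    continue
                el = at.element.name if at.element else "C"
                if not keep_hydrogens and el.upper() in ("H", "D"):
                    continue
                wa = WeightedAtom(
                    serial=at.serial,
                    element=el,
                    name=at.name,
                    residue_name=res.name.strip(),
                    residue_number=res.seqid.num,
                    chain=chain.name,
                    center=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    radius=vdw_radius(el, radii),
                )
                hetflag = res.het_flag == "H"
                if is_water:
                    continue
                if hetflag and not keep_hetatm:
                    het.append(wa)
                else:
                    atoms.append(wa)
    if len(atoms) < 4:
        raise DegenerateInputError(
            f"{path}: {len(atoms)} usable atoms; need at least 4 for triangulation"
        )
    return Structure(atoms, id=st.name or str(path), het_atoms=het).drop_duplicate_centers()


def write_pdb(structure: Structure, path: str) -> None:
    """Write a structure (including synthetic ones) as a PDB file."""
    st = gemmi.Structure()
    st.name = structure.id or "SYNTH"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in structure.atoms:
        ch = chains.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chains[a.chain] = ch
        if len(ch) == 0 or ch[-1].seqid.num != a.residue_number:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "A"  # write ATOM records even for synthetic residues
            ch.add_residue(res)
        res = ch[-1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.center)
        at.serial = a.serial
        at.occ = 1.0
        res.add_atom(at)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Conservation tables
# ---------------------------------------------------------------------------

def read_conservation(path: str) -> ConservationTable:
    """Read a whitespace/tab separated table of ``chain residue_number score``
    rows.  Duplicate rows: last one wins, with a warning."""
    table = ConservationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 'chain residue_number score', got {line!r}"
                )
            chain, num_s, score_s = parts
            try:
                num = int(num_s)
                score = float(score_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            key = (chain, num)
            if key in table.entries:
                warnings.warn(
                    f"{path}:{lineno}: duplicate entry for {key}; keeping last",
                    stacklevel=2,
                )
            table.entries[key] = score
    return table


def write_conservation(table: ConservationTable, path: str) -> None:
    with open(path, "w") as fh:
        for (chain, num), score in sorted(table.entries.items()):
            fh.write(f"{chain}\t{num}\t{score:g}\n")


# ---------------------------------------------------------------------------
# Synthetic structures
# ---------------------------------------------------------------------------

def _bead(i: int, xyz: np.ndarray, radius: float, resnum: int = 1, name: str = "BEA") -> WeightedAtom:
    return WeightedAtom(
        serial=i,
        element="C",
        name="C",
        residue_name=name,
        residue_number=resnum,
        chain="A",
        center=np.asarray(xyz, float),
        radius=radius,
    )


def _hex_ring_rows(length: float, spacing: float) -> np.ndarray:
    """z positions of bead rows, hex-packed row spacing, covering [0, length]."""
    dz = spacing * math.sqrt(3.0) / 2.0
    n = max(2, int(round(length / dz)) + 1)
    return np.linspace(0.0, length, n)


def _ring(z: float, ring_radius: float, spacing: float, phase: float) -> np.ndarray:
    """Bead centers on a circle of given radius at height z."""
    n = max(6, int(math.ceil(2.0 * math.pi * ring_radius / spacing)))
    theta = phase + 2.0 * math.pi * np.arange(n) / n
    return np.column_stack(
        [ring_radius * np.cos(theta), ring_radius * np.sin(theta), np.full(n, z)]
    )


def make_tube(
    length: float = 40.0,
    outer_radius: float = 8.0,
    lumen_radius: float = 4.0,
    constriction_radius: float = 2.0,
    constriction_position: float = 0.5,
    atom_radius: float = 0.25,
    seed: int = 0,
) -> Structure:
    """Hollow tube of overlapping beads, open at both ends, with one ring
    pinched so that the largest ball passing the constriction has radius
    ~= ``constriction_radius``.

    Construction (all around the z-axis, z in [0, length]):

    * a cylindrical lumen lining of vdW-scale beads whose inner ball surface
      sits at ``lumen_radius``; the two rim rings are modulated in z
      (irregular, exact) so the open poles have no flat extremal rings;
    * a constriction diaphragm at z = length * constriction_position: a
      coarse annulus out to the wall, plus a fine aperture ring of beads of
      ``atom_radius`` at ring radius constriction_radius + atom_radius — the
      fine beads make the orthoradius measured at the throat converge to the
      true probe radius (a probe of radius rho tangent to beads of radius r
      has orthoradius sqrt(rho^2 + 2 rho r));
    * an *exactly convex* spherical shell of coarse beads through the two
      rims, polar caps removed.  Exact placement keeps every shell hull
      facet a small sealed triangle, so boundary sliver tetrahedra — whose
      empty orthospheres are unbounded over any rough open surface — are
      confined behind sealed facets and pruned as voids.  The only openings
      are the two polar mouths.

    Deterministic for a given seed; the seeded jitter (1e-3 Å, interior
    beads only) breaks exact cospherical degeneracies.

    ``outer_radius`` is validated as the wall allowance but the shell radius
    itself is dictated by the construction (a sphere through the two rims),
    so the actual outer extent grows with ``length``.
    """
    if not (lumen_radius > constriction_radius > 0):
        raise ParameterError("need lumen_radius > constriction_radius > 0")
    if not (0.0 < constriction_position < 1.0):
        raise ParameterError("constriction_position must be a fraction in (0,1)")
    if length < 10 * atom_radius:
        raise ParameterError("tube too short")
    if outer_radius <= lumen_radius + 1.0:
        raise ParameterError("outer_radius must exceed lumen_radius + 1")

    lining_bead = 1.7       # vdW-scale wall/shell beads
    fine_spacing = 1.4 * atom_radius
    lin_spacing = 1.2 * lining_bead
    rng = np.random.default_rng(seed)
    rows = _hex_ring_rows(length, lin_spacing)
    zc_row = rows[int(np.argmin(np.abs(rows - length * constriction_position)))]

    jittered: list[tuple[np.ndarray, float]] = []   # (ring coords, bead radius)
    exact: list[tuple[np.ndarray, float]] = []

    def wavy(ring: np.ndarray, z: float, amp: float, k: int, phase: float) -> np.ndarray:
        # Irregular z-modulation for the rim rings.  An exactly flat extremal
        # ring would let sliver tetrahedra at the open pole acquire
        # near-unbounded empty orthospheres (nothing blocks them beyond the
        # end plane); a modulated wave whose lobes bottom out at different
        # depths caps them at the lobe scale and, being exact (no jitter),
        # makes the pole geometry identical for every seed.
        theta = np.arctan2(ring[:, 1], ring[:, 0])
        out = ring.copy()
        out[:, 2] = z + amp * np.sin(k * theta + phase) * (
            1.0 + 0.35 * np.sin(2.0 * theta + 1.1))
        return out

    # Lumen lining: a golden-angle helix rather than stacked rings.  Rings
    # are exactly cocircular, so the lumen triangulates into "fans" of
    # near-cospherical tetrahedra sharing one axis orthocenter that the dual
    # path must walk around; the quasi-uniform helix has no such degeneracy
    # and the path advances along the axis in a few chunky steps per turn.
    lin_r = lumen_radius + lining_bead
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z_lo, z_hi = rows[0] + 0.8 * lining_bead, rows[-1] - 0.8 * lining_bead
    n_helix = int(math.ceil(2.0 * math.pi * lin_r * (z_hi - z_lo)
                            / (lin_spacing * lin_spacing * math.sqrt(3.0) / 2.0)))
    j = np.arange(n_helix)
    theta = j * golden
    zs = z_lo + (z_hi - z_lo) * (j + 0.5) / n_helix
    helix = np.column_stack([lin_r * np.cos(theta), lin_r * np.sin(theta), zs])
    jittered.append((helix, lining_bead))

    # wavy rim rings at the two open ends (exact)
    n_lin = max(6, int(math.ceil(2.0 * math.pi * lin_r / lin_spacing)))
    for z in (rows[0], rows[-1]):
        th = 2.0 * math.pi * np.arange(n_lin) / n_lin
        ring = np.column_stack(
            [lin_r * np.cos(th), lin_r * np.sin(th), np.full(n_lin, z)])
        exact.append((wavy(ring, z, 0.9 * lining_bead, 5, 0.0), lining_bead))

    # Constriction: an hourglass.  The throat is a short helical collar of
    # fine beads at the aperture radius (golden-angle placement, like the
    # lining: no cocircular fans, so the dual path runs straight through).
    # Two conical funnels of mid-scale beads taper the wall smoothly down to
    # the throat — an abrupt wide-to-narrow step would leave a vestibule
    # whose tetrahedra span wall-to-collar and zigzag the centerline.
    aperture = constriction_radius + atom_radius
    half_throat = 0.7
    n_col = int(math.ceil(2.0 * math.pi * aperture * 2 * half_throat
                          / (fine_spacing * fine_spacing * math.sqrt(3.0) / 2.0)))
    jc = np.arange(n_col)
    th = jc * golden + 0.37
    zcol = zc_row - half_throat + 2 * half_throat * (jc + 0.5) / n_col
    collar = np.column_stack(
        [aperture * np.cos(th), aperture * np.sin(th), zcol])
    jittered.append((collar, atom_radius))

    cone_bead = 0.8
    cone_spacing = 1.25 * cone_bead
    r_in = constriction_radius + cone_bead + 0.3
    r_out = lumen_radius + lining_bead + 0.2
    z_far = 3.0
    for direction in (-1.0, 1.0):
        slant = math.hypot(z_far - half_throat, r_out - r_in)
        n_cone = int(math.ceil(math.pi * (r_in + r_out) * slant
                               / (cone_spacing * cone_spacing * math.sqrt(3.0) / 2.0)))
        jcn = np.arange(n_cone)
        frac = (jcn + 0.5) / n_cone
        rr = r_in + (r_out - r_in) * frac
        zz = zc_row + direction * (half_throat + (z_far - half_throat) * frac)
        tt = jcn * golden + (0.91 if direction > 0 else 2.13)
        cone = np.column_stack([rr * np.cos(tt), rr * np.sin(tt), zz])
        jittered.append((cone, cone_bead))

    # exactly convex spherical shell through the two rims, polar caps open
    shell_bead = lining_bead
    shell_spacing = 1.1 * shell_bead
    hole = lumen_radius + shell_bead  # polar hole: shell balls graze the lumen
    half = length / 2.0
    r_shell = math.sqrt(half * half + hole * hole)
    n_shell = int(math.ceil(4.0 * math.pi * r_shell * r_shell
                            / (shell_spacing * shell_spacing * math.sqrt(3.0) / 2.0)))
    i = np.arange(n_shell)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    zu = 1.0 - 2.0 * (i + 0.5) / n_shell
    ru = np.sqrt(np.maximum(1.0 - zu * zu, 0.0))
    shell = r_shell * np.column_stack([ru * np.cos(phi), ru * np.sin(phi), zu])
    shell[:, 2] += half
    shell = shell[np.hypot(shell[:, 0], shell[:, 1]) >= hole]
    exact.append((shell, shell_bead))

    coords_j = np.vstack([c for c, _ in jittered])
    coords_j = coords_j + rng.normal(scale=1e-3, size=coords_j.shape)
    coords = np.vstack([coords_j] + [c for c, _ in exact])
    radii = np.concatenate(
        [np.full(len(c), r) for c, r in jittered]
        + [np.full(len(c), r) for c, r in exact])
    atoms = [
        _bead(i + 1, coords[i], float(radii[i]), resnum=i // 100 + 1, name="TUB")
        for i in range(len(coords))
    ]
    return Structure(atoms, id=f"tube-l{length:g}-c{constriction_radius:g}-s{seed}")


def make_blob(n_atoms: int = 60, extent: float = 8.0, atom_radius: float = 1.7,
              seed: int = 0) -> Structure:
    """Random compact cluster of vdW-scale balls (no designed channels)."""
    if n_atoms < 4:
        raise ParameterError("need at least 4 atoms")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-extent / 2, extent / 2, size=(n_atoms, 3))
    atoms = [_bead(i + 1, coords[i], atom_radius, name="BLB") for i in range(n_atoms)]
    return Structure(atoms, id=f"blob-n{n_atoms}-s{seed}").drop_duplicate_centers()


def make_shell(radius: float = 4.0, atom_radius: float = 1.7, n_atoms: int = 150,
               seed: int = 0) -> Structure:
    """Closed spherical shell of overlapping balls with a sealed interior
    cavity (a void, not a channel)."""
    if n_atoms < 12:
        raise ParameterError("need at least 12 shell atoms")
    rng = np.random.default_rng(seed)
    # Fibonacci sphere: near-uniform coverage
    i = np.arange(n_atoms)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_atoms
    r = np.sqrt(1.0 - z * z)
    coords = radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    coords = coords + rng.normal(scale=1e-3, size=coords.shape)
    atoms = [_bead(k + 1, coords[k], atom_radius, name="SHL") for k in range(n_atoms)]
    return Structure(atoms, id=f"shell-r{radius:g}-s{seed}")


def make_barrel(
    n_pores: int = 2,
    slab: tuple[float, float, float] = (22.0, 22.0, 9.0),
    pore_radius: float = 2.5,
    atom_radius: float = 1.7,
    seed: int = 0,
) -> Structure:
    """Slab of balls perforated by parallel cylindrical pores along z."""
    if n_pores < 1:
        raise ParameterError("need at least one pore")
    sx, sy, sz = slab
    spacing = 1.35 * atom_radius
    rng = np.random.default_rng(seed)
    xs = np.arange(-sx / 2, sx / 2 + 1e-9, spacing)
    ys = np.arange(-sy / 2, sy / 2 + 1e-9, spacing)
    zs = np.arange(-sz / 2, sz / 2 + 1e-9, spacing * math.sqrt(3) / 2)
    axes_x = np.linspace(-sx / 4, sx / 4, n_pores) if n_pores > 1 else np.array([0.0])
    pts = []
    for k, z in enumerate(zs):
        off = (k % 2) * spacing / 2
        gx, gy = np.meshgrid(xs + off, ys + off)
        layer = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
        d = np.min(
            np.hypot(layer[:, 0][:, None] - axes_x[None, :], layer[:, 1][:, None]),
            axis=1,
        )
        pts.append(layer[d > pore_radius + atom_radius])
    coords = np.vstack(pts) + rng.normal(scale=5e-3, size=(sum(len(p) for p in pts), 3))
    atoms = [_bead(i + 1, coords[i], atom_radius, name="BRL") for i in range(len(coords))]
    return Structure(atoms, id=f"barrel-p{n_pores}-s{seed}")
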