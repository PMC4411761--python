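"""Channel profiles: 1D functions along the centerline, plus channel volume.

A profile is a real-valued function on [0, d], d the channel length, sampled
at centerline points parametrized by arc length.

* **Radius** — the orthosphere radius (sqrt of the size value) of every
  path tetrahedron at its centerline point, with each shared triangle's
  orthosphere radius sampled at the crossing between the two flanking
  tetrahedra.  Its minimum over the channel is the bottleneck radius.
* **Physico-chemical** — per-tetrahedron mean of a residue scale (hydropathy,
  charge, bulkiness, or any user table) over the residues owning the four
  vertex atoms.
* **Conservation** — per-tetrahedron mean of externally supplied per-residue
  conservation scores.
* **Electrostatic** — trilinear interpolation of a scalar grid (e.g. an APBS
  OpenDX map) at the centerline points.

Channel volume is the empty volume of the path tetrahedra (tetrahedron
volume minus the part covered by atom balls), estimated by Monte Carlo with
a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .channels import Channel
from .exceptions import FormatError, OutOfBoundsError, ParameterError
from .geometry import Triangulation
from .model_io import ConservationTable, Structure

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class Profile:
    """Samples (t, value) of a real function on [0, d] along a channel."""

    name: str
    t: np.ndarray
    values: np.ndarray
    d: float

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.values = np.asarray(self.values, float)
        if len(self.t) != len(self.values):
            raise ParameterError("t and values must have equal length")

    def resample_onto(self, t_new: np.ndarray) -> np.ndarray:
        """Linear interpolation of the profile at new arc-length positions
        (NaN samples are dropped first)."""
        ok = np.isfinite(self.values)
        return np.interp(t_new, self.t[ok], self.values[ok])

    def minimum(self) -> float:
        return float(np.nanmin(self.values))

    def write_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("t,value\n")
            for t, v in zip(self.t, self.values):
                fh.write(f"{t:.6g},{v:.6g}\n")


@dataclass
class ScaleTable:
    """Residue code -> scalar value; missing residues map to NaN."""

    name: str
    values: dict[str, float] = field(default_factory=dict)
    missing: float = float("nan")

    def value(self, residue_name: str) -> float:
        return self.values.get(residue_name.upper(), self.missing)


def read_scale(path: str, name: str | None = None) -> ScaleTable:
    """Read a two-column TSV residue scale (residue_code<TAB>value)."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'RES value'")
            try:
                values[parts[0].upper()] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return ScaleTable(name or str(path), values)


def load_scale(name: str) -> ScaleTable:
    """Load a shipped scale: 'hydropathy' (Kyte–Doolittle), 'charge', or
    'bulkiness' (Zimmerman)."""
    ref = resources.files("alphapore.data").joinpath(f"{name}.tsv")
    if not ref.is_file():
        raise ParameterError(f"unknown scale {name!r}; shipped scales: "
                             "hydropathy, charge, bulkiness")
    with resources.as_file(ref) as p:
        return read_scale(str(p), name)


@dataclass
class ScalarGrid:
    """Regular scalar grid with orthogonal axes (OpenDX-style)."""

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.values = np.asarray(self.values, float)
        if np.any(self.spacing <= 0):
            raise ParameterError("grid spacing must be positive")
        if self.values.ndim != 3:
            raise ParameterError("grid values must be a 3D array")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> list[np.ndarray]:
        return [self.origin[k] + self.spacing[k] * np.arange(self.dims[k])
                for k in range(3)]


def read_opendx(path: str) -> ScalarGrid:
    """Read an OpenDX scalar grid (e.g. APBS output).  Non-orthogonal deltas
    are rejected."""
    try:
        from gridData import Grid
    except ImportError as exc:  # pragma: no cover - present in supported envs
        raise FormatError("reading OpenDX grids requires the gridDataFormats "
                          "package") from exc
    try:
        g = Grid(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse OpenDX grid {path}: {exc}") from exc
    deltas = np.asarray(g.delta, float)
    if deltas.ndim == 2:
        if np.any(np.abs(deltas - np.diag(np.diag(deltas))) > 1e-12):
            raise FormatError(f"{path}: non-orthogonal grid axes not supported")
        deltas = np.diag(deltas)
    return ScalarGrid(np.asarray(g.origin, float), deltas, np.asarray(g.grid, float))


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def _arclengths(centerline: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def radius_profile(channel: Channel, tri: Triangulation) -> Profile:
    """Orthosphere radius along the channel.

    Tetrahedron orthoradii are sampled at their centerline points; each
    shared triangle's orthoradius is sampled at the crossing arc length
    midway between its two flanking tetrahedra.  The profile minimum equals
    the bottleneck radius (a simplex's face never has a larger size value
    than the simplex itself, so the minimum is attained at a triangle).
    """
    t_tet = _arclengths(channel.centerline)
    t, sizes = [], []
    for i, tet in enumerate(channel.node_path):
        t.append(t_tet[i])
        sizes.append(tri.tet_size[tet])
        if i < len(channel.triangle_path):
            t.append(0.5 * (t_tet[i] + t_tet[i + 1]))
            sizes.append(tri.tri_size[channel.triangle_path[i]])
    t = np.asarray(t)
    vals = np.sqrt(np.maximum(np.asarray(sizes, float), 0.0))
    # collapse coincident arc positions (orthocenters of consecutive tets
    # may coincide), keeping the narrower sample
    keep_t, keep_v = [t[0]], [vals[0]]
    for ti, vi in zip(t[1:], vals[1:]):
        if ti - keep_t[-1] < 1e-9:
            keep_v[-1] = min(keep_v[-1], vi)
        else:
            keep_t.append(ti)
            keep_v.append(vi)
    return Profile("radius", np.asarray(keep_t), np.asarray(keep_v), channel.length)


def _per_tet_profile(channel: Channel, tri: Triangulation, structure: Structure,
                     residue_value, name: str) -> Profile:
    """Mean of a per-residue value over the 4 vertex atoms of each path
    tetrahedron, sampled at the tetrahedron centerline points."""
    t_tets = _arclengths(channel.centerline)
    vals = np.empty(len(channel.node_path))
    for i, tet in enumerate(channel.node_path):
        scores = [residue_value(structure.atoms[v]) for v in tri.tets[tet]]
        scores = [s for s in scores if math.isfinite(s)]
        vals[i] = float(np.mean(scores)) if scores else float("nan")
    # pin the domain to [0, d] exactly
    t_tets = t_tets.copy()
    t_tets[0], t_tets[-1] = 0.0, channel.length
    return Profile(name, t_tets, vals, channel.length)


def physchem_profile(channel: Channel, tri: Triangulation, structure: Structure,
                     scale: ScaleTable) -> Profile:
    """Per-tetrahedron mean of a residue property scale; non-standard
    residues are excluded from the mean (NaN sample if all four are)."""
    return _per_tet_profile(
        channel, tri, structure,
        lambda a: scale.value(a.residue_name), scale.name,
    )


def conservation_profile(channel: Channel, tri: Triangulation, structure: Structure,
                         table: ConservationTable) -> Profile:
    """Per-tetrahedron mean of per-residue conservation scores."""
    return _per_tet_profile(
        channel, tri, structure,
        lambda a: table.score(a.chain, a.residue_number), "conservation",
    )


def electrostatic_profile(channel: Channel, grid: ScalarGrid) -> Profile:
    """Trilinear interpolation of the grid at every centerline point."""
    interp = RegularGridInterpolator(grid.axes(), grid.values, method="linear",
                                     bounds_error=True)
    pts = channel.centerline
    try:
        vals = interp(pts)
    except ValueError:
        lo = grid.origin
        hi = grid.origin + grid.spacing * (np.array(grid.dims) - 1)
        for p in pts:
            if np.any(p < lo) or np.any(p > hi):
                raise OutOfBoundsError(
                    f"centerline point {p.tolist()} outside grid bounds "
                    f"{lo.tolist()}..{hi.tolist()}") from None
        raise
    return Profile("electrostatic", _arclengths(pts), vals, channel.length)


# ---------------------------------------------------------------------------
# channel volume
# ---------------------------------------------------------------------------

def channel_volume(channel: Channel, tri: Triangulation, structure: Structure,
                   mc_samples: int = 20000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo estimate of the empty volume of the path tetrahedra.

    For each path tetrahedron, uniform samples are drawn and the fraction not
    covered by any atom ball is accumulated; returns (volume, stderr) in Å^3.
    """
    if mc_samples < 1000:
        raise ParameterError("mc_samples must be >= 1000")
    rng = np.random.default_rng(seed)
    tets = np.asarray(channel.node_path, dtype=int)
    T = tri.points[tri.tets[tets]]                      # (m, 4, 3)
    vols = np.abs(np.linalg.det(T[:, 1:] - T[:, :1])) / 6.0
    total_vol = vols.sum()
    if total_vol <= 0:
        return 0.0, 0.0
    centers = structure.centers
    radii = structure.radii
    kd = cKDTree(centers)
    rmax = float(radii.max())
    n_per = np.maximum((mc_samples * vols / total_vol).astype(int), 50)
    est = 0.0
    var = 0.0
    for m in range(len(tets)):
        n = int(n_per[m])
        # uniform barycentric coordinates in a simplex
        e = rng.exponential(size=(n, 4))
        bary = e / e.sum(axis=1, keepdims=True)
        pts = np.einsum("nk,kj->nj", bary, T[m])
        neigh = kd.query_ball_point(pts, rmax)
        covered = np.zeros(n, dtype=bool)
        for i, idx in enumerate(neigh):
            if idx:
                d = np.linalg.norm(centers[idx] - pts[i], axis=1)
                covered[i] = bool(np.any(d < radii[idx]))
        p_empty = 1.0 - covered.mean()
        est += vols[m] * p_empty
        var += (vols[m] ** 2) * p_empty * (1.0 - p_empty) / n
    return float(est), float(math.sqrt(var))
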