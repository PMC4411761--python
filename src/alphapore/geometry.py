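"""Regular (weighted Delaunay) triangulation and the alpha complex.

Atoms are weighted points p with weight w(p) = r(p)^2.  The power distance
from p to x is ||x - p||^2 - w(p); it is zero exactly on the ball surface.
The regular triangulation is the geometric dual of the power diagram.  It is
computed here by lifting each atom to 4D as (x, y, z, ||x||^2 - w) and taking
the lower convex hull: lower-hull facets project to the tetrahedra of the
regular triangulation, and atoms missing from the lower hull are *hidden*
(their power cell is empty) and appear in no simplex.

Every simplex carries an *orthosphere* — the sphere with zero power to all
of its weighted vertices (for dim < 3 the center is constrained to the
affine hull of the vertex centers).  Its squared radius is the simplex
``size_value``; it may be negative when the vertex balls overlap deeply.
The alpha complex at parameter alpha (in Å^2, since balls grown by alpha have
radius sqrt(r^2 + alpha)) is the subcomplex of simplices whose
``alpha_value`` is <= alpha, where alpha_value is the size value for
unattached simplices and the minimum coface alpha_value for attached ones.
At alpha = 0 the complex is the dual complex of the untouched balls and
represents the space the atoms cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .exceptions import DegenerateInputError
from .model_io import Structure, WeightedAtom

#: squared-radius tolerance used in attachment tests
_ATTACH_TOL = 1e-9


def power_distance(p: WeightedAtom, x) -> float:
    """Power distance ||x - p||^2 - w(p); zero on the ball surface."""
    d = np.asarray(x, float) - p.center
    return float(d @ d - p.weight)


def orthosphere(atoms: list[WeightedAtom]):
    """Orthocenter and size (squared orthoradius) of 2–4 weighted atoms.

    The returned center has equal power to all defining atoms; that common
    power is the size.  For fewer than 4 atoms the center is the point of the
    affine hull of the centers with that property.
    """
    P = np.array([a.center for a in atoms], float)
    w = np.array([a.weight for a in atoms], float)
    A = P[1:] - P[0]
    span = np.linalg.norm(A, axis=1).max() if len(A) else 0.0
    if span == 0 or np.linalg.matrix_rank(A, tol=1e-9 * span) < len(A):
        raise DegenerateInputError("affinely dependent centers")
    c, s = _orthospheres_batch(P[None, :, :], w[None, :])
    return c[0], float(s[0])


def _orthospheres_batch(P: np.ndarray, w: np.ndarray):
    """Vectorized orthosphere solve.

    P: (m, k, 3) vertex centers, w: (m, k) weights, 2 <= k <= 4.
    Solves 2 (p_i - p_1) . c = (|p_i|^2 - w_i) - (|p_1|^2 - w_1) with
    c = p_1 + A^T t restricted to the affine hull (A rows p_i - p_1).
    Returns centers (m, 3) and sizes (m,); NaN rows mark degeneracies.
    """
    P = np.asarray(P, float)
    w = np.asarray(w, float)
    p1 = P[:, 0, :]
    A = P[:, 1:, :] - p1[:, None, :]                       # (m, k-1, 3)
    lift = (P * P).sum(axis=2) - w                          # |p|^2 - w
    b = lift[:, 1:] - lift[:, :1]                           # (m, k-1)
    M = 2.0 * np.einsum("mik,mjk->mij", A, A)               # (m, k-1, k-1)
    rhs = b - 2.0 * np.einsum("mik,mk->mi", A, p1)
    k1 = A.shape[1]
    det = np.linalg.det(M)
    bad = np.abs(det) < 1e-13 * (np.abs(M).max(axis=(1, 2)) ** k1 + 1e-300)
    Msafe = M.copy()
    Msafe[bad] = np.eye(k1)
    t = np.linalg.solve(Msafe, rhs[..., None])[..., 0]
    if bad.any():
        # near-singular (sliver) simplices: minimum-norm pseudo-inverse
        t[bad] = np.einsum("mij,mj->mi", np.linalg.pinv(M[bad]), rhs[bad])
    c = p1 + np.einsum("mi,mik->mk", t, A)
    d = c - p1
    s = (d * d).sum(axis=1) - w[:, 0]
    return c, s


@dataclass
class SimplexRecord:
    """One simplex of the regular triangulation."""

    vertices: tuple[int, ...]
    dim: int
    orthocenter: np.ndarray
    size_value: float
    attached: bool
    alpha_value: float


class Triangulation:
    """Regular triangulation of a structure with per-simplex alpha values.

    Simplices of each dimension are stored as flat arrays:

    - ``tets``      (nt, 4) sorted vertex indices
    - ``tris``      (nf, 3), ``tri_tets`` (nf, 2) incident tets (-1 = none)
    - ``edges``     (ne, 2), plus incidence maps built from the tets
    - ``*_center``, ``*_size``, ``*_alpha``, ``*_attached`` parallel arrays

    ``hull_tris`` marks triangles with exactly one incident tetrahedron;
    these tile the convex hull boundary.
    """

    def __init__(self, structure: Structure):
        self.structure = structure
        self._build(structure)
        self._alpha_done = False

    # -- construction -------------------------------------------------------

    def _build(self, structure: Structure) -> None:
        P = structure.centers
        w = structure.weights
        n = len(P)
        if n < 4:
            raise DegenerateInputError(f"{n} atoms; need at least 4")
        tets = _lower_hull_tets(P, w)
        if tets.shape[0] == 0:
            raise DegenerateInputError("degenerate input: no tetrahedra (coplanar centers?)")
        self.points = P
        self.weights = w
        self.tets = tets

        # triangles: unique faces of tets, with incidence
        faces = np.vstack([np.delete(tets, i, axis=1) for i in range(4)])
        owner = np.tile(np.arange(len(tets)), 4)
        faces.sort(axis=1)
        tris, inv = np.unique(faces, axis=0, return_inverse=True)
        self.tris = tris
        tri_tets = np.full((len(tris), 2), -1, dtype=np.int64)
        order = np.argsort(inv, kind="stable")
        counts = np.bincount(inv, minlength=len(tris))
        starts = np.concatenate([[0], np.cumsum(counts)])
        for f in range(len(tris)):
            inc = owner[order[starts[f]:starts[f + 1]]]
            tri_tets[f, : len(inc)] = inc[:2]
        self.tri_tets = tri_tets
        self.hull_tris = tri_tets[:, 1] < 0
        # tet -> 4 triangle ids: rows of `faces` are grouped in 4 blocks by
        # which vertex was deleted, each block in tet order
        self.tet_tris = inv.reshape(4, len(tets)).T.copy()

        # edges: unique pairs from triangles
        pairs = np.vstack([tris[:, [0, 1]], tris[:, [0, 2]], tris[:, [1, 2]]])
        tri_of_pair = np.tile(np.arange(len(tris)), 3)
        edges, einv = np.unique(np.sort(pairs, axis=1), axis=0, return_inverse=True)
        self.edges = edges
        self.edge_tris: list[np.ndarray] = [None] * len(edges)  # type: ignore[list-item]
        eorder = np.argsort(einv, kind="stable")
        ecounts = np.bincount(einv, minlength=len(edges))
        estarts = np.concatenate([[0], np.cumsum(ecounts)])
        for e in range(len(edges)):
            self.edge_tris[e] = tri_of_pair[eorder[estarts[e]:estarts[e + 1]]]
        self.vertices = np.unique(tets)

        # orthocenters and sizes
        self.tet_center, self.tet_size = _orthospheres_batch(P[tets], w[tets])
        self.tri_center, self.tri_size = _orthospheres_batch(P[tris], w[tris])
        self.edge_center, self.edge_size = _orthospheres_batch(P[edges], w[edges])
        # centered ("self-centered") triangles: orthocenter inside the
        # triangle; sliver triangles are never centered, genuine opening
        # disks are — used when picking mouth representatives
        A, B, C = P[tris[:, 0]], P[tris[:, 1]], P[tris[:, 2]]
        v0, v1 = B - A, C - A
        pv = self.tri_center - A
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        dp0 = np.einsum("ij,ij->i", pv, v0)
        dp1 = np.einsum("ij,ij->i", pv, v1)
        den = d00 * d11 - d01 * d01
        den = np.where(np.abs(den) < 1e-300, 1e-300, den)
        b1 = (d11 * dp0 - d01 * dp1) / den
        b2 = (d00 * dp1 - d01 * dp0) / den
        self.tri_centered = (b1 >= -1e-9) & (b2 >= -1e-9) & (b1 + b2 <= 1 + 1e-9)
        for name in ("tet", "tri", "edge"):
            s = getattr(self, f"{name}_size")
            if not np.all(np.isfinite(s)):
                raise DegenerateInputError(f"degenerate {name} in triangulation")

    # -- alpha values --------------------------------------------------------

    def compute_alpha_values(self) -> "Triangulation":
        """Fill in attachment flags and alpha values for every simplex.

        A simplex of dim < 3 is attached iff its orthosphere intersects the
        ball of some vertex of a coface more than orthogonally (the weighted
        Gabriel test): ||o - q||^2 - w_q - size < 0 for a coface vertex q.
        Attached simplices inherit the minimum alpha value of their cofaces,
        which makes alpha monotone under the face relation.
        """
        P, w = self.points, self.weights
        self.tet_alpha = self.tet_size.copy()
        self.tet_attached = np.zeros(len(self.tets), dtype=bool)

        # triangles: the only coface vertices are the opposite vertices of
        # the (<=2) incident tets
        nt = len(self.tris)
        self.tri_attached = np.zeros(nt, dtype=bool)
        self.tri_alpha = self.tri_size.copy()
        coface_alpha = np.full(nt, np.inf)
        for col in range(2):
            tt = self.tri_tets[:, col]
            ok = tt >= 0
            opp = _opposite_vertex(self.tets[tt[ok]], self.tris[ok])
            d = self.tri_center[ok] - P[opp]
            pw = (d * d).sum(axis=1) - w[opp] - self.tri_size[ok]
            att = pw < -_ATTACH_TOL
            idx = np.where(ok)[0]
            self.tri_attached[idx[att]] = True
            coface_alpha[idx] = np.minimum(coface_alpha[idx], self.tet_alpha[tt[ok]])
        self.tri_alpha = np.where(self.tri_attached, coface_alpha, self.tri_size)
        # monotonicity guard against roundoff
        self.tri_alpha = np.minimum(self.tri_alpha, coface_alpha)

        # edges: cofaces are incident triangles
        ne = len(self.edges)
        self.edge_attached = np.zeros(ne, dtype=bool)
        alpha = self.edge_size.copy()
        for e in range(ne):
            tris = self.edge_tris[e]
            others = self.tris[tris].ravel()
            others = np.setdiff1d(others, self.edges[e])
            d = self.edge_center[e] - P[others]
            pw = (d * d).sum(axis=1) - w[others] - self.edge_size[e]
            min_cof = self.tri_alpha[tris].min()
            if np.any(pw < -_ATTACH_TOL):
                self.edge_attached[e] = True
                alpha[e] = min_cof
            else:
                alpha[e] = min(self.edge_size[e], min_cof)
        self.edge_alpha = alpha

        # vertices: cofaces are incident edges; a vertex is attached iff some
        # neighbour ball swallows its orthosphere-with-size -w more than
        # orthogonally, i.e. ||p-q||^2 - w_q + w_p < 0
        self.vert_size = -w
        self.vert_alpha = -w.copy()
        self.vert_attached = np.zeros(len(P), dtype=bool)
        vert_edge_min = np.full(len(P), np.inf)
        for e, (a, b) in enumerate(self.edges):
            vert_edge_min[a] = min(vert_edge_min[a], self.edge_alpha[e])
            vert_edge_min[b] = min(vert_edge_min[b], self.edge_alpha[e])
            dd = float(np.sum((P[a] - P[b]) ** 2))
            if dd - w[b] + w[a] < -_ATTACH_TOL:
                self.vert_attached[a] = True
            if dd - w[a] + w[b] < -_ATTACH_TOL:
                self.vert_attached[b] = True
        upd = self.vert_attached & np.isfinite(vert_edge_min)
        self.vert_alpha[upd] = vert_edge_min[upd]
        self.vert_alpha = np.minimum(self.vert_alpha, vert_edge_min)
        self._alpha_done = True
        return self

    # -- queries -------------------------------------------------------------

    def alpha_complex(self, alpha: float):
        """Simplices with alpha_value <= alpha, keyed by dimension.

        Returns a dict {3: tet ids, 2: triangle ids, 1: edge ids, 0: vertex
        ids} of numpy index arrays.  Closed under taking faces by
        monotonicity of the alpha values.
        """
        self._require_alpha()
        return {
            3: np.where(self.tet_alpha <= alpha)[0],
            2: np.where(self.tri_alpha <= alpha)[0],
            1: np.where(self.edge_alpha <= alpha)[0],
            0: self.vertices[self.vert_alpha[self.vertices] <= alpha],
        }

    def simplex(self, dim: int, i: int) -> SimplexRecord:
        """SimplexRecord view of simplex ``i`` of dimension ``dim``."""
        self._require_alpha()
        if dim == 3:
            return SimplexRecord(tuple(self.tets[i]), 3, self.tet_center[i],
                                 float(self.tet_size[i]), False, float(self.tet_alpha[i]))
        if dim == 2:
            return SimplexRecord(tuple(self.tris[i]), 2, self.tri_center[i],
                                 float(self.tri_size[i]), bool(self.tri_attached[i]),
                                 float(self.tri_alpha[i]))
        if dim == 1:
            return SimplexRecord(tuple(self.edges[i]), 1, self.edge_center[i],
                                 float(self.edge_size[i]), bool(self.edge_attached[i]),
                                 float(self.edge_alpha[i]))
        return SimplexRecord((i,), 0, self.points[i], float(self.vert_size[i]),
                             bool(self.vert_attached[i]), float(self.vert_alpha[i]))

    def tet_volumes(self) -> np.ndarray:
        T = self.points[self.tets]
        v = np.abs(np.linalg.det(T[:, 1:] - T[:, :1])) / 6.0
        return v

    def validate_filtration(self, tol: float = 1e-7) -> bool:
        """Check alpha monotonicity under the face relation (tri <= tet,
        edge <= tri)."""
        self._require_alpha()
        for col in range(2):
            tt = self.tri_tets[:, col]
            ok = tt >= 0
            if np.any(self.tri_alpha[ok] > self.tet_alpha[tt[ok]] + tol):
                return False
        for e in range(len(self.edges)):
            if np.any(self.edge_alpha[e] > self.tri_alpha[self.edge_tris[e]] + tol):
                return False
        return True

    def _require_alpha(self) -> None:
        if not self._alpha_done:
            raise RuntimeError("call compute_alpha_values() first")


def _opposite_vertex(tets: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """For each (tet row, face row) pair, the tet vertex not in the face."""
    # both are sorted; sum difference identifies the missing vertex
    return tets.sum(axis=1) - tris.sum(axis=1)


def _lower_hull_tets(P: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Tetrahedra of the regular triangulation via the 4D lifting map.

    Numerically cospherical configurations are resolved by a deterministic
    joggle (magnitude 1e-8 Å, fixed seed), re-run with a second seed if the
    hull code still reports precision loss.
    """
    n = len(P)
    span = P - P[0]
    scale = np.abs(span).max() + 1e-300
    if np.linalg.matrix_rank(span, tol=1e-9 * scale) < 3:
        raise DegenerateInputError("degenerate input: coplanar centers")
    if n == 4:
        return np.sort(np.arange(4))[None, :]

    def attempt(pts: np.ndarray) -> np.ndarray:
        lifted = np.column_stack([pts, (pts * pts).sum(axis=1) - w])
        hull = ConvexHull(lifted, qhull_options="Qt")
        eq = hull.equations
        scale = np.linalg.norm(eq[:, :4], axis=1)
        lower = eq[:, 3] / np.maximum(scale, 1e-300) < -1e-10
        tets = np.sort(hull.simplices[lower], axis=1)
        # drop exactly flat (zero-volume) facets that Qt may emit
        T = pts[tets]
        vol = np.abs(np.linalg.det(T[:, 1:] - T[:, :1])) / 6.0
        return tets[vol > 1e-12]

    try:
        return attempt(P)
    except QhullError:
        pass
    for seed in (0x5EED, 0x5EED + 1):
        rng = np.random.default_rng(seed)
        try:
            return attempt(P + rng.normal(scale=1e-8, size=P.shape))
        except QhullError:
            continue
    raise DegenerateInputError("Qhull failed even after joggle; input too degenerate")


def regular_triangulation(structure: Structure) -> Triangulation:
    """Build the regular triangulation of a structure (alpha values not yet
    assigned; call :func:`alpha_values`)."""
    return Triangulation(structure)


def alpha_values(tri: Triangulation) -> Triangulation:
    """Compute attachment flags and alpha values on a built triangulation."""
    return tri.compute_alpha_values()


def build_alpha_complex(structure: Structure) -> Triangulation:
    """Convenience: triangulate and compute alpha values in one call."""
    return regular_triangulation(structure).compute_alpha_values()
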