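"""Channel endpoint selection.

Two families of endpoints are supported:

* **Active sites** — given atom positions of a site (user residue list or a
  HETATM ligand), each site atom votes for its nearest network node; the
  deepest of those nodes represents the site.  Using the per-atom nearest
  nodes instead of the site centroid matters for large ligands, whose
  centroid can sit far from the deepest reachable point.

* **Mouth representatives** — openings of the molecule.  Mouths are connected
  components of complement hull triangles.  The number of mouths varies with
  the width level; we scan the hull triangles' size values (squared
  orthoradii — the physical widths of the openings) for the smallest
  ``alpha_max`` in [0, inf) that maximizes the mouth count, extract mouths
  there, and represent each mouth by the incident tetrahedron of its widest
  triangle.  The opening width doubles as the operational persistence of a
  mouth: for unattached simplices it equals the alpha interval, starting at
  0, during which the opening exists in the complement, and unlike the raw
  filtration entry time it is not distorted by attached boundary slivers
  whose entry times are inherited from arbitrarily large cofaces.

The ordered list of mouth representatives, sorted by decreasing tetrahedron
persistence and truncated to the user parameter k, is ``B_imp`` — the
candidate endpoints between which important pores are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import NoChannelError, ParameterError
from .geometry import Triangulation
from .network import ChannelNetwork

#: default number of top boundary nodes between which pores are extracted
DEFAULT_K = 10


@dataclass
class EndpointSet:
    """Selected channel endpoints."""

    active_site_node: int | None = None
    B_imp: list[int] = field(default_factory=list)
    alpha_max: float = 0.0
    persistence: dict[int, float] = field(default_factory=dict)
    mouth_components: list[list[int]] = field(default_factory=list)


def active_site_node(net: ChannelNetwork, site_atoms) -> int:
    """Representative network node for an active site.

    For each site atom position, find the nearest node (Euclidean distance to
    the node orthocenter); among those nearest nodes return the one with the
    highest depth.  Ties break toward larger node width, then lower tet id.
    """
    site_atoms = np.atleast_2d(np.asarray(site_atoms, float))
    nodes = net.nodes
    if not nodes:
        raise NoChannelError("empty channel network")
    pos = np.array([net.position(n) for n in nodes])
    candidates = set()
    for a in site_atoms:
        d = np.linalg.norm(pos - a[None, :], axis=1)
        candidates.add(nodes[int(np.argmin(d))])
    def key(n):
        nd = net.graph.nodes[n]
        return (nd.get("depth", 0), nd["width"], -n)
    return max(sorted(candidates), key=key)


def ligand_site_atoms(structure, ligand_code: str) -> np.ndarray:
    """Positions of a named HETATM ligand's atoms (active-site seed)."""
    pts = [a.center for a in structure.het_atoms if a.residue_name == ligand_code]
    if not pts:
        raise ParameterError(f"no HETATM atoms with residue name {ligand_code!r}")
    return np.array(pts)


def residue_site_atoms(structure, residues: list[tuple[str, int]]) -> np.ndarray:
    """Positions of all atoms of the given (chain, residue_number) list."""
    wanted = set(residues)
    pts = [a.center for a in structure.atoms + structure.het_atoms
           if (a.chain, a.residue_number) in wanted]
    if not pts:
        raise ParameterError(f"no atoms found for residues {sorted(wanted)}")
    return np.array(pts)


def _hull_adjacency(tri: Triangulation) -> nx.Graph:
    """Graph on hull triangles, adjacent iff they share a (hull) edge."""
    hull_ids = np.where(tri.hull_tris)[0]
    g = nx.Graph()
    g.add_nodes_from(int(f) for f in hull_ids)
    by_edge: dict[tuple[int, int], list[int]] = {}
    for f in hull_ids:
        a, b, c = tri.tris[f]
        for e in ((a, b), (a, c), (b, c)):
            by_edge.setdefault((int(e[0]), int(e[1])), []).append(int(f))
    for fs in by_edge.values():
        for i in range(1, len(fs)):
            g.add_edge(fs[0], fs[i])
    return g


def mouth_components_at(tri: Triangulation, alpha: float,
                        hull_graph: nx.Graph | None = None) -> list[list[int]]:
    """Connected components of complement hull triangles wider than alpha
    (size_value > alpha, restricted to triangles outside the alpha complex
    at 0)."""
    if hull_graph is None:
        hull_graph = _hull_adjacency(tri)
    keep = [f for f in hull_graph.nodes
            if tri.tri_size[f] > alpha and tri.tri_alpha[f] > 0.0]
    sub = hull_graph.subgraph(keep)
    return [sorted(c) for c in nx.connected_components(sub)]


def mouth_scan(tri: Triangulation) -> tuple[float, list[list[int]]]:
    """Scan the width level for the maximum mouth count.

    Candidate levels are the distinct size values of complement hull
    triangles in [0, inf), plus 0.  Returns the smallest level attaining the
    maximum number of mouth components, with the components at that level.
    Only complement hull triangles (alpha value > 0) can belong to a mouth.
    """
    hull_graph = _hull_adjacency(tri)
    open_tris = np.array(
        [f for f in hull_graph.nodes if tri.tri_alpha[f] > 0.0], dtype=int)
    if len(open_tris) == 0:
        return 0.0, []
    alphas = tri.tri_size[open_tris]
    cand = np.unique(alphas[alphas >= 0.0])
    cand = np.unique(np.concatenate([[0.0], cand]))

    # Descending sweep with a union-find: at candidate t the active triangles
    # are those with alpha > t; activating in decreasing alpha order and
    # merging with active neighbours keeps a running component count.
    idx_of = {int(f): i for i, f in enumerate(open_tris)}
    nbrs: list[list[int]] = [[] for _ in open_tris]
    for u, v in hull_graph.edges:
        iu, iv = idx_of.get(int(u)), idx_of.get(int(v))
        if iu is not None and iv is not None:
            nbrs[iu].append(iv)
            nbrs[iv].append(iu)
    parent = np.arange(len(open_tris))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = np.argsort(-alphas, kind="stable")
    active = np.zeros(len(open_tris), dtype=bool)
    n_comp = 0
    p = 0
    best_alpha, best_count = 0.0, -1
    for t in cand[::-1]:
        while p < len(order) and alphas[order[p]] > t:
            i = order[p]
            active[i] = True
            n_comp += 1
            for j in nbrs[i]:
                if active[j]:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
                        n_comp -= 1
            p += 1
        if n_comp >= best_count:  # ties -> smaller alpha (sweep is descending)
            best_alpha, best_count = float(t), n_comp
    return best_alpha, mouth_components_at(tri, best_alpha, hull_graph)


def rank_boundary_nodes(net: ChannelNetwork, mouth_components: list[list[int]],
                        k: int = DEFAULT_K) -> EndpointSet:
    """B_imp: one representative node per mouth, ranked by opening width.

    Per mouth, the representative triangle is its widest (maximum size
    value, the persistence of that opening) and the representative node is
    the incident tetrahedron.  The list is sorted by decreasing width and
    truncated to k.
    """
    if k < 2:
        raise ParameterError("k must be >= 2 for pore extraction")
    tri = net.triangulation
    reps: list[int] = []
    persistence: dict[int, float] = {}
    for comp in mouth_components:
        # only centered triangles qualify: the opening width of a mouth is
        # the orthoradius of a triangle whose orthosphere actually sits in
        # the opening; sliver triangles (orthocenter far outside) have
        # divergent orthoradii that measure nothing passable.  A component
        # with no centered triangle is a sliver artifact, not a mouth.
        centered = [f for f in comp if tri.tri_centered[f]]
        if not centered:
            continue
        f = max(centered, key=lambda f: (tri.tri_size[f], -f))
        node = int(tri.tri_tets[f, 0])
        if node not in net.graph:
            continue  # mouth opening onto a pruned region (should not happen)
        if node not in persistence:
            reps.append(node)
        persistence[node] = float(tri.tri_size[f])
    reps.sort(key=lambda n: (-persistence[n], n))
    alpha_max = 0.0
    return EndpointSet(B_imp=reps[:k], alpha_max=alpha_max,
                       persistence=persistence, mouth_components=mouth_components)


def select_endpoints(net: ChannelNetwork, k: int = DEFAULT_K) -> EndpointSet:
    """mouth_scan + rank_boundary_nodes, recording alpha_max."""
    alpha_max, comps = mouth_scan(net.triangulation)
    eps = rank_boundary_nodes(net, comps, k)
    eps.alpha_max = alpha_max
    return eps
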