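"""The channel network: dual graph of the alpha-complex complement.

Tetrahedra, triangles and edges of the regular triangulation that are *not*
in the alpha complex at the working alpha (normally 0) represent the empty
space of the molecule.  The dual graph of the complement has one node per
complement tetrahedron and one edge per complement triangle; hull triangles
in the complement are *mouth triangles* — entry points from the outside —
and link their (boundary) node to a distinguished EXTERIOR super-node.
Channels are routed through this network.

Edge attributes:

- ``width``   local squared constriction radius: the shared triangle's
  *size value* (its own squared orthoradius), floored at a tiny epsilon
  (Å^2).  Membership in the complement is decided by the alpha value, but
  the passable width of a crossing is the radius of the sphere orthogonal
  to its three flanking atoms — for an *attached* triangle the alpha value
  is inherited from a coface and can be arbitrarily larger than the real
  opening (boundary sliver tetrahedra have unbounded empty orthospheres),
  while the size value is the actual constriction a probe must pass.
- ``length``  Euclidean distance between the node orthocenters (Å); for
  exterior edges, node orthocenter to mouth-triangle orthocenter
- ``cost``    length / width — small for short, wide passages

Every network edge's triangle has alpha value > 0 at alpha = 0 (filtration
monotonicity), so channels found here are geometrically feasible; unattached
complement triangles additionally have positive width.
"""

from __future__ import annotations

import json

import networkx as nx
import numpy as np

from .geometry import Triangulation

#: the exterior super-node
EXTERIOR = "exterior"

#: width floor, Å^2
WIDTH_EPS = 1e-9


class ChannelNetwork:
    """Dual graph of the complement, wrapping a networkx Graph.

    ``graph`` nodes are tetrahedron ids (ints) plus EXTERIOR; node attributes
    ``pos`` (orthocenter), ``width`` (tet size value), ``is_boundary``, and
    after :func:`node_depths` a ``depth``.  Edge attributes ``triangle``,
    ``length``, ``width``, ``cost``.
    """

    def __init__(self, graph: nx.Graph, triangulation: Triangulation | None = None,
                 alpha: float = 0.0, mouth_triangles: set[int] | None = None):
        self.graph = graph
        self.triangulation = triangulation
        self.alpha = alpha
        if mouth_triangles is None:
            mouth_triangles = {
                d["triangle"] for _, _, d in graph.edges(EXTERIOR, data=True)
            } if EXTERIOR in graph else set()
        self.mouth_triangles = mouth_triangles
        self.voids: list[set[int]] = []

    # convenience views ------------------------------------------------------

    @property
    def nodes(self):
        return [n for n in self.graph.nodes if n != EXTERIOR]

    def position(self, node) -> np.ndarray:
        return self.graph.nodes[node]["pos"]

    def boundary_nodes(self) -> list[int]:
        return [n for n in self.nodes if self.graph.nodes[n].get("is_boundary")]

    def interior_graph(self) -> nx.Graph:
        """The network without the EXTERIOR super-node (channels may not
        shortcut through the outside)."""
        g = self.graph.subgraph(self.nodes)
        return g

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "alpha": self.alpha,
            "nodes": [
                {
                    "tet": int(n),
                    "pos": [float(x) for x in self.graph.nodes[n]["pos"]],
                    "width": float(self.graph.nodes[n]["width"]),
                    "depth": int(self.graph.nodes[n].get("depth", -1)),
                    "is_boundary": bool(self.graph.nodes[n].get("is_boundary", False)),
                }
                for n in self.nodes
            ],
            "edges": [
                {
                    "u": (int(u) if u != EXTERIOR else EXTERIOR),
                    "v": (int(v) if v != EXTERIOR else EXTERIOR),
                    "triangle": int(d["triangle"]),
                    "length": float(d["length"]),
                    "width": float(d["width"]),
                    "cost": float(d.get("cost", -1.0)),
                }
                for u, v, d in self.graph.edges(data=True)
            ],
            "mouth_triangles": sorted(int(t) for t in self.mouth_triangles),
            "voids": [sorted(int(t) for t in v) for v in self.voids],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_network(tri: Triangulation, alpha: float = 0.0) -> ChannelNetwork:
    """Construct the channel network at the given alpha.

    One node per complement tetrahedron (alpha_value > alpha); one edge per
    complement triangle.  By filtration monotonicity a complement triangle's
    incident tetrahedra are also complement, so interior complement triangles
    always join two existing nodes.  An empty complement yields an empty
    network (a solid blob).

    A boundary tetrahedron can be incident on several mouth triangles; the
    graph keeps a single exterior edge per boundary node (carrying the widest
    mouth), while the full mouth set is recorded in ``mouth_triangles``.
    """
    g = nx.Graph()
    g.add_node(EXTERIOR)
    comp_tet = tri.tet_alpha > alpha
    for t in np.where(comp_tet)[0]:
        g.add_node(int(t), pos=tri.tet_center[t], width=float(tri.tet_size[t]),
                   is_boundary=False)
    comp_tri = np.where(tri.tri_alpha > alpha)[0]
    mouths: set[int] = set()
    for f in comp_tri:
        t0, t1 = tri.tri_tets[f]
        width = float(tri.tri_size[f])
        if t1 >= 0:
            length = float(np.linalg.norm(tri.tet_center[t0] - tri.tet_center[t1]))
            g.add_edge(int(t0), int(t1), triangle=int(f), length=length, width=width)
        else:
            # mouth triangle: hull triangle in the complement
            mouths.add(int(f))
            length = float(np.linalg.norm(tri.tet_center[t0] - tri.tri_center[f]))
            prev = g.get_edge_data(int(t0), EXTERIOR)
            if prev is None or width > prev["width"]:
                g.add_edge(int(t0), EXTERIOR, triangle=int(f), length=length,
                           width=width)
            g.nodes[int(t0)]["is_boundary"] = True
    return ChannelNetwork(g, tri, alpha, mouth_triangles=mouths)


def prune_voids(net: ChannelNetwork) -> ChannelNetwork:
    """Keep only nodes accessible from the exterior; removed components are
    recorded as voids.  Idempotent."""
    g = net.graph
    reachable = nx.node_connected_component(g, EXTERIOR)
    removed = [n for n in g.nodes if n not in reachable]
    if removed:
        sub = g.subgraph(removed)
        net.voids.extend(set(c) for c in nx.connected_components(sub))
        g.remove_nodes_from(removed)
    return net


def edge_costs(net: ChannelNetwork) -> ChannelNetwork:
    """Assign cost = length / width to every edge (width floored at
    WIDTH_EPS)."""
    for _, _, d in net.graph.edges(data=True):
        w = max(WIDTH_EPS, d["width"])
        d["width"] = w
        d["cost"] = d["length"] / w
    return net


def node_depths(net: ChannelNetwork) -> ChannelNetwork:
    """Hop-count depth of every node from the boundary-node wave front.

    Boundary nodes have depth 0; interior nodes the minimum number of hops to
    any boundary node.  Unreachable nodes (only possible pre-pruning) get
    depth -1.
    """
    g = net.interior_graph()
    sources = [n for n in g.nodes if net.graph.nodes[n].get("is_boundary")]
    depths = nx.multi_source_dijkstra_path_length(g, sources, weight=None) if sources else {}
    for n in net.nodes:
        net.graph.nodes[n]["depth"] = int(depths.get(n, -1))
    return net


def build_pruned_network(tri: Triangulation, alpha: float = 0.0) -> ChannelNetwork:
    """build -> prune -> costs -> depths, the standard pipeline order."""
    return node_depths(edge_costs(prune_voids(build_network(tri, alpha))))
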