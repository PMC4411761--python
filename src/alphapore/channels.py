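"""Significant channel extraction on the channel network.

A channel is an ordered walk of complement tetrahedra, consecutive ones
sharing a complement triangle.  Its *centerline* is the polyline of the path
tetrahedra's orthocenters — the path representation with nodes at the
orthogonal-sphere centers of the top simplices.  The shared triangles are
kept alongside (``triangle_path``): their orthosphere radii are the
constrictions a probe must pass, and the narrowest of them is the
bottleneck radius.  Channel significance is the summed edge cost (length
over local width): short, wide channels cost little.

* :func:`shortest_channel` — minimum-cost path (Dijkstra).
* :func:`disjoint_channels` — iterated extraction; after each round the used
  edges are saturated with a cost exceeding any path of fresh edges, so
  subsequent rounds report edge-disjoint channels.
* :func:`widest_path_tree` — maximum spanning tree under edge width; the tree
  path between any two nodes maximizes the minimum width over all network
  paths (the max-min bottleneck property).
* :func:`important_pores` — channels between all pairs of the top-k mouth
  representatives.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .endpoints import EndpointSet
from .exceptions import NoChannelError, ParameterError
from .network import EXTERIOR, ChannelNetwork


@dataclass
class Channel:
    """An extracted channel with its geometry.

    ``centerline`` holds one point per path tetrahedron (its orthocenter).
    ``bottleneck_radius`` is min over path triangles of the orthosphere
    radius sqrt(size_value), in Å — the radius of the largest spherical
    probe that can traverse the channel.
    """

    node_path: list[int]
    triangle_path: list[int]
    centerline: np.ndarray
    length: float
    bottleneck_radius: float
    cost: float
    kind: str = "channel"
    straightness: float | None = None
    score: float | None = None

    def endpoints(self) -> tuple[int, int]:
        return self.node_path[0], self.node_path[-1]

    def to_json(self, triangulation=None, structure=None, path: str | None = None) -> str:
        payload = {
            "kind": self.kind,
            "nodes": [int(n) for n in self.node_path],
            "triangles": [int(f) for f in self.triangle_path],
            "centerline": [[float(x) for x in p] for p in self.centerline],
            "length": self.length,
            "bottleneck_radius": self.bottleneck_radius,
            "cost": self.cost,
            "straightness": self.straightness,
            "score": self.score,
        }
        if triangulation is not None:
            payload["radii"] = [
                float(np.sqrt(max(a, 0.0))) for a in _centerline_alphas(self, triangulation)
            ]
            payload["lining_atoms"] = [
                [int(v) for v in triangulation.tets[t]] for t in self.node_path
            ]
        if structure is not None and triangulation is not None:
            payload["lining_residues"] = sorted(
                {
                    f"{structure.atoms[v].chain}:{structure.atoms[v].residue_number}"
                    for t in self.node_path
                    for v in triangulation.tets[t]
                }
            )
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _centerline_alphas(c: Channel, tri) -> list[float]:
    """Squared orthoradii along the path, alternating tet / crossing
    triangle (2n-1 values for n path tets)."""
    out = []
    for i, t in enumerate(c.node_path):
        out.append(float(tri.tet_size[t]))
        if i < len(c.triangle_path):
            out.append(float(tri.tri_size[c.triangle_path[i]]))
    return out


@dataclass
class WidestPathTree:
    """Maximum spanning forest under edge width."""

    tree: nx.Graph
    important_leaves: set[int] = field(default_factory=set)

    def bottleneck(self, u: int, v: int) -> float:
        """Minimum edge width along the tree path u..v (the max-min width
        over all network paths)."""
        path = nx.shortest_path(self.tree, u, v)
        return min(
            self.tree.edges[a, b]["width"] for a, b in itertools.pairwise(path)
        )


def _channel_from_path(net: ChannelNetwork, path: list[int]) -> Channel:
    tri = net.triangulation
    g = net.graph
    tri_path = [g.edges[u, v]["triangle"] for u, v in itertools.pairwise(path)]
    centerline = np.array([tri.tet_center[n] for n in path])
    seglen = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    length = float(seglen.sum())
    # bottleneck: the narrowest orthosphere a probe must pass (triangle sizes)
    bn = float(np.sqrt(max(min(tri.tri_size[f] for f in tri_path), 0.0)))
    cost = float(sum(g.edges[u, v]["cost"] for u, v in itertools.pairwise(path)))
    return Channel(list(path), tri_path, centerline, length, bn, cost)


def shortest_channel(net: ChannelNetwork, src: int, dst: int,
                     graph: nx.Graph | None = None) -> Channel:
    """Minimum-total-cost channel between two network nodes (Dijkstra).

    Paths may not shortcut through the EXTERIOR super-node.  Raises
    NoChannelError for identical or disconnected endpoints.
    """
    if src == dst:
        raise NoChannelError(f"degenerate channel: src == dst == {src}")
    g = net.interior_graph() if graph is None else graph
    if src not in g or dst not in g:
        raise NoChannelError(f"endpoint {src if src not in g else dst} not in network")
    try:
        path = nx.dijkstra_path(g, src, dst, weight="cost")
    except nx.NetworkXNoPath:
        raise NoChannelError(f"no channel between {src} and {dst}") from None
    return _channel_from_path(net, path)


def disjoint_channels(net: ChannelNetwork, src: int, dst: int, count: int = 3) -> list[Channel]:
    """Up to ``count`` pairwise edge-disjoint channels, cheapest first.

    After each Dijkstra round, every used edge's cost is raised to
    1 + (sum of all original costs), which exceeds the cost of any path of
    unsaturated edges; a round whose path reuses a saturated edge is
    discarded and iteration stops.
    """
    if count < 1:
        raise ParameterError("count must be >= 1")
    g = nx.Graph()
    base = net.interior_graph()
    g.add_nodes_from(base.nodes)
    g.add_edges_from((u, v, dict(d)) for u, v, d in base.edges(data=True))
    saturation = 1.0 + sum(d["cost"] for _, _, d in g.edges(data=True))
    saturated: set[frozenset] = set()
    out: list[Channel] = []
    for _ in range(count):
        try:
            path = nx.dijkstra_path(g, src, dst, weight="cost")
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            break
        pairs = [frozenset(p) for p in itertools.pairwise(path)]
        if any(p in saturated for p in pairs):
            break
        out.append(_channel_from_path(net, path))
        for (u, v), p in zip(itertools.pairwise(path), pairs):
            g.edges[u, v]["cost"] = saturation
            saturated.add(p)
    if not out:
        raise NoChannelError(f"no channel between {src} and {dst}")
    # costs in the returned channels are w.r.t. original edge costs
    for c in out:
        c.cost = float(
            sum(base.edges[u, v]["cost"] for u, v in itertools.pairwise(c.node_path))
        )
    return out


def widest_path_tree(net: ChannelNetwork) -> WidestPathTree:
    """Maximum spanning forest of the (interior) network under edge width."""
    g = net.interior_graph()
    tree = nx.maximum_spanning_tree(g, weight="width")
    return WidestPathTree(tree)


def prune_tree(wpt: WidestPathTree, important: set[int]) -> WidestPathTree:
    """Iteratively delete degree-1 nodes not in ``important``: what is left
    is the union of tree paths between the important nodes."""
    tree = wpt.tree.copy()
    unknown = important - set(tree.nodes)
    if unknown:
        raise ParameterError(f"important nodes not in tree: {sorted(unknown)}")
    while True:
        leaves = [n for n in tree.nodes if tree.degree(n) <= 1 and n not in important]
        if not leaves:
            break
        tree.remove_nodes_from(leaves)
    return WidestPathTree(tree, important_leaves=set(important))


def important_pores(net: ChannelNetwork, eps: EndpointSet, k: int | None = None) -> list[Channel]:
    """Shortest channels between all pairs of the top-k B_imp nodes.

    Channels with identical triangle paths (same geometric pore reached from
    duplicate representatives) are collapsed.  Result sorted by cost.
    """
    reps = eps.B_imp if k is None else eps.B_imp[:k]
    if len(reps) < 2:
        raise NoChannelError("fewer than 2 boundary representatives; no pores")
    g = net.interior_graph()
    seen: set[tuple] = set()
    pores: list[Channel] = []
    for u, v in itertools.combinations(reps, 2):
        try:
            c = shortest_channel(net, u, v, graph=g)
        except NoChannelError:
            continue
        key = tuple(sorted(c.triangle_path))
        if key in seen:
            continue
        seen.add(key)
        c.kind = "pore"
        pores.append(c)
    pores.sort(key=lambda c: c.cost)
    return pores
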