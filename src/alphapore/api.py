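"""High-level pipelines composing the extraction stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import channels as _channels
from . import endpoints as _endpoints
from . import network as _network
from . import transmembrane as _tm
from .geometry import Triangulation, build_alpha_complex
from .model_io import Structure
from .network import ChannelNetwork


@dataclass
class Analysis:
    """Triangulation + pruned channel network of a structure."""

    structure: Structure
    triangulation: Triangulation
    network: ChannelNetwork


def analyze(structure: Structure, alpha: float = 0.0) -> Analysis:
    """Triangulate, compute alpha values, and build the pruned channel
    network with costs and depths."""
    tri = build_alpha_complex(structure)
    net = _network.build_pruned_network(tri, alpha)
    return Analysis(structure, tri, net)


def find_pores(analysis: Analysis, k: int = _endpoints.DEFAULT_K) -> list[_channels.Channel]:
    """Important pores: channels between all pairs of the top-k mouth
    representatives, cheapest first."""
    eps = _endpoints.select_endpoints(analysis.network, k)
    return _channels.important_pores(analysis.network, eps)


def find_tm_pores(analysis: Analysis, slab: _tm.MembraneSlab,
                  k: int = _endpoints.DEFAULT_K) -> list[_channels.Channel]:
    """Ranked transmembrane pores (best first) for a membrane slab."""
    eps = _endpoints.select_endpoints(analysis.network, k)
    cls = _tm.classify_boundary(eps, analysis.network, slab)
    pores = _tm.extract_tm_pores(analysis.network, cls)
    return _tm.rank_tm_pores(pores)


def channels_to_site(analysis: Analysis, site_atoms: np.ndarray,
                     n_channels: int = 3) -> list[_channels.Channel]:
    """Edge-disjoint channels from an active site to the nearest boundary.

    The site node is the deepest of the nearest nodes of the site atoms; the
    destination is the boundary node reached at minimum cost from it.
    """
    net = analysis.network
    src = _endpoints.active_site_node(net, site_atoms)
    import networkx as nx

    g = net.interior_graph()
    dist = nx.single_source_dijkstra_path_length(g, src, weight="cost")
    boundary = [n for n in net.boundary_nodes() if n in dist and n != src]
    if not boundary:
        from .exceptions import NoChannelError

        raise NoChannelError("no boundary node reachable from the site")
    dst = min(boundary, key=lambda n: dist[n])
    chans = _channels.disjoint_channels(net, src, dst, n_channels)
    for c in chans:
        c.kind = "active-site"
    return chans
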