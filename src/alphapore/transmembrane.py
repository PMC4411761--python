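"""Transmembrane pore classification and ranking.

The membrane is modelled as a slab between two parallel planes orthogonal to
a normal vector (by default the z-axis, matching the OPM convention of
membrane-oriented structures with planes at z = ±h).  Mouth-representative
nodes are classified by projecting their position on the normal:

    projection < lower_offset  ->  B_in   (e.g. cytoplasmic side)
    projection > upper_offset  ->  B_out  (extracellular side)
    otherwise                  ->  B_mem  (inside the membrane)

Pores with one endpoint in B_in and the other in B_out traverse the
membrane.  Each such pore x is scored

    f(x) = (|x| / max|y|  +  bn(x) / max bn(y)  +  s(x)) / 3

over the transmembrane set: length |x| and bottleneck radius bn(x) are
normalized by the set maxima, and s(x) is the multi-scale straightness of the
uniformly resampled centerline,

    s(S) = sum_{d=1}^{|S|/2} sum_{i=1}^{|S|-2d} d * cos(angle_i,d)
           / sum_{d=1}^{|S|/2} sum_{i=1}^{|S|-2d} d

where angle_i,d is the *turning* angle between the direction vectors
S[i+d]-S[i] and S[i+2d]-S[i+d] (so a perfectly straight path scores exactly
1).  The inner average at separation d measures curvature at that scale;
weighting by d emphasizes large-scale winding.  The highest-scoring pore is
reported as the best transmembrane pore.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .channels import Channel, shortest_channel
from .endpoints import EndpointSet
from .exceptions import DegeneratePathError, NoChannelError, ParameterError
from .network import ChannelNetwork

#: default arc-length spacing of straightness resampling, Å
DEFAULT_SPACING = 1.0
#: cap on the number of resampled points (cost control)
MAX_SAMPLES = 512


@dataclass
class MembraneSlab:
    """Two parallel planes orthogonal to ``normal`` at signed offsets."""

    lower_offset: float
    upper_offset: float
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        if self.lower_offset >= self.upper_offset:
            raise ParameterError("need lower_offset < upper_offset")
        self.normal = np.asarray(self.normal, float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ParameterError("membrane normal must be non-zero")
        self.normal = self.normal / n


@dataclass
class TMClassification:
    B_in: set[int] = field(default_factory=set)
    B_out: set[int] = field(default_factory=set)
    B_mem: set[int] = field(default_factory=set)


@dataclass
class ResampledPath:
    """Uniform arc-length samples S along a centerline."""

    samples: np.ndarray
    spacing: float

    def __len__(self) -> int:
        return len(self.samples)


def classify_boundary(eps: EndpointSet, net: ChannelNetwork,
                      slab: MembraneSlab) -> TMClassification:
    """Split B_imp by which side of the membrane slab each node lies on."""
    cls = TMClassification()
    for n in eps.B_imp:
        z = float(net.position(n) @ slab.normal)
        if z < slab.lower_offset:
            cls.B_in.add(n)
        elif z > slab.upper_offset:
            cls.B_out.add(n)
        else:
            cls.B_mem.add(n)
    return cls


def resample(channel_or_points, spacing: float = DEFAULT_SPACING) -> ResampledPath:
    """Uniformly distributed sample points along a centerline polyline.

    The nominal spacing is adjusted so that the last sample lands exactly on
    the far endpoint; the sample count is capped at MAX_SAMPLES and floored
    so that at least 5 samples are produced.
    """
    pts = channel_or_points.centerline if isinstance(channel_or_points, Channel) \
        else np.asarray(channel_or_points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 2.0 * spacing:
        raise DegeneratePathError(
            f"centerline length {total:.3g} Å too short for spacing {spacing:g} Å")
    n = int(np.ceil(total / spacing))
    n = min(max(n, 4), MAX_SAMPLES - 1)
    h = total / n
    t = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n + 1)
    samples = np.empty((n + 1, 3))
    for k in range(3):
        samples[:, k] = np.interp(targets, t, pts[:, k])
    return ResampledPath(samples, h)


def straightness(path: ResampledPath | np.ndarray) -> float:
    """Multi-scale straightness s(S) in [-1, 1]; 1 iff samples are collinear
    in order."""
    S = path.samples if isinstance(path, ResampledPath) else np.asarray(path, float)
    m = len(S)
    if m < 5:
        raise DegeneratePathError(f"need at least 5 samples, got {m}")
    num = 0.0
    den = 0.0
    for d in range(1, m // 2 + 1):
        v = S[d:] - S[:-d]                    # chords of separation d
        u1 = v[: m - 2 * d]
        u2 = v[d:]
        n1 = np.linalg.norm(u1, axis=1)
        n2 = np.linalg.norm(u2, axis=1)
        if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
            raise DegeneratePathError("coincident samples in resampled path")
        cos = np.einsum("ij,ij->i", u1, u2) / (n1 * n2)
        num += d * float(np.clip(cos, -1.0, 1.0).sum())
        den += d * (m - 2 * d)
    return num / den


def extract_tm_pores(net: ChannelNetwork, cls: TMClassification) -> list[Channel]:
    """Shortest channels for every (B_in, B_out) endpoint pair."""
    pores: list[Channel] = []
    seen: set[tuple] = set()
    g = net.interior_graph()
    for u, v in itertools.product(sorted(cls.B_in), sorted(cls.B_out)):
        try:
            c = shortest_channel(net, u, v, graph=g)
        except NoChannelError:
            continue
        key = tuple(sorted(c.triangle_path))
        if key in seen:
            continue
        seen.add(key)
        c.kind = "transmembrane"
        pores.append(c)
    return pores


def rank_tm_pores(pores: list[Channel], spacing: float = DEFAULT_SPACING) -> list[Channel]:
    """Score and sort transmembrane pores by f(x), best first."""
    if not pores:
        raise NoChannelError("no transmembrane pores to rank")
    for c in pores:
        if c.straightness is None:
            c.straightness = straightness(resample(c, spacing))
    max_len = max(c.length for c in pores)
    max_bn = max(c.bottleneck_radius for c in pores)
    for c in pores:
        c.score = (c.length / max_len + c.bottleneck_radius / max_bn + c.straightness) / 3.0
        c.kind = "transmembrane"
    return sorted(pores, key=lambda c: -c.score)
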