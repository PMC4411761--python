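"""Independent reference implementations used as test oracles.

Everything here is deliberately written with different algorithms (and, for
numerics, different linear-system formulations) than the package, so that
agreement is informative.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# geometry oracles
# ---------------------------------------------------------------------------

def orthosphere_4(P: np.ndarray, w: np.ndarray):
    """Orthocenter/size of 4 weighted points by solving the 4x4 linear
    system in (c, u) with u = c.c - s (a different linearization than the
    package's affine-hull reduction)."""
    A = np.column_stack([-2.0 * P, np.ones(4)])
    b = w - np.einsum("ij,ij->i", P, P)
    sol = np.linalg.solve(A, b)
    c = sol[:3]
    s = float(c @ c - sol[3])
    return c, s


def brute_force_regular_tets(P: np.ndarray, w: np.ndarray, tol: float = 1e-9):
    """All 4-subsets whose orthosphere has power >= 0 to every other point
    (the empty-orthosphere definition of the regular triangulation),
    enumerated by brute force."""
    n = len(P)
    tets = []
    for comb in itertools.combinations(range(n), 4):
        idx = np.array(comb)
        if abs(np.linalg.det(P[idx[1:]] - P[idx[0]])) < 1e-10:
            continue
        try:
            c, s = orthosphere_4(P[idx], w[idx])
        except np.linalg.LinAlgError:
            continue
        others = np.setdiff1d(np.arange(n), idx)
        power = np.einsum("ij,ij->i", P[others] - c, P[others] - c) - w[others] - s
        if np.all(power > -tol):
            tets.append(tuple(sorted(comb)))
    return set(tets)


def brute_force_regular_tets_vectorized(P: np.ndarray, w: np.ndarray,
                                        tol: float = 1e-9):
    """Same empty-orthosphere enumeration as
    :func:`brute_force_regular_tets`, but batched in numpy so 50-point
    instances stay affordable.  Solves the (c, u) linearization for every
    4-subset at once and checks all other points' powers."""
    n = len(P)
    combs = np.array(list(itertools.combinations(range(n), 4)), dtype=int)
    Pk = P[combs]                                   # (C, 4, 3)
    wk = w[combs]
    vol = np.abs(np.linalg.det(Pk[:, 1:] - Pk[:, :1]))
    ok = vol > 1e-10
    A = np.concatenate([-2.0 * Pk, np.ones((len(combs), 4, 1))], axis=2)
    b = wk - np.einsum("cij,cij->ci", Pk, Pk)
    A_ok = A[ok]
    sol = np.linalg.solve(A_ok, b[ok][..., None])[..., 0]
    c = sol[:, :3]
    s = np.einsum("ci,ci->c", c, c) - sol[:, 3]
    # power of every point to each candidate orthosphere
    d2 = ((P[None, :, :] - c[:, None, :]) ** 2).sum(axis=2)
    power = d2 - w[None, :] - s[:, None]
    members = np.zeros((ok.sum(), n), dtype=bool)
    rows = np.repeat(np.arange(ok.sum()), 4)
    members[rows, combs[ok].ravel()] = True
    power[members] = np.inf
    empty = power.min(axis=1) > -tol
    return {tuple(t) for t in combs[ok][empty]}


def dual_complex_member_by_sampling(P, w, simplex, n_samples=4000, rng=None):
    """Dual-complex membership of a simplex at alpha=0 by sampling its dual
    power-diagram face.

    The dual face of simplex {p_1..p_k} lies in the affine subspace of
    points with equal power to all p_i; the simplex is in the dual complex
    iff some point of that subspace (a) has non-positive power to p_1 (the
    balls reach it) and (b) is not beaten by any other site's power (it lies
    in the cells of the p_i).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    idx = np.array(simplex)
    Pk, wk = P[idx], w[idx]
    # anchor = projection of p_1 onto the dual subspace, i.e. the simplex
    # orthocenter (the minimum-power point of the dual face's affine hull)
    A = 2.0 * (Pk[1:] - Pk[0])
    b = (np.einsum("ij,ij->i", Pk[1:], Pk[1:]) - wk[1:]) - (Pk[0] @ Pk[0] - wk[0])
    disp, *_ = np.linalg.lstsq(A, b - A @ Pk[0], rcond=None)
    anchor = Pk[0] + disp
    # directions spanning the dual subspace = null space of A
    _, sv, vt = np.linalg.svd(A)
    null = vt[len(sv[sv > 1e-9]):]
    max_scale = 3.0 * (np.abs(P).max() + 1.0)
    others = np.setdiff1d(np.arange(len(P)), idx)

    def covered(x):
        pw = float((x - Pk[0]) @ (x - Pk[0]) - wk[0])
        if pw > 1e-9:
            return False  # outside the balls
        if len(others):
            po = np.einsum("ij,ij->i", P[others] - x, P[others] - x) - w[others]
            if np.min(po) < pw - 1e-9:
                return False  # another site owns this point
        return True

    if covered(anchor):
        return True
    for _ in range(n_samples):
        if not len(null):
            break
        # mixture of scales: the covered patch of the dual face can be tiny
        scale = np.exp(rng.uniform(np.log(1e-3), np.log(max_scale)))
        x = anchor + (rng.normal(size=len(null)) * scale) @ null
        if covered(x):
            return True
    return False


def trilinear_eval(coef, x, y, z):
    """a + bx + cy + dz + exy + fyz + gzx + hxyz."""
    a, b, c, d, e, f, g, h = coef
    return (a + b * x + c * y + d * z + e * x * y + f * y * z + g * z * x
            + h * x * y * z)


# ---------------------------------------------------------------------------
# graph oracles
# ---------------------------------------------------------------------------

def brute_shortest_path(edges: dict, src, dst):
    """Minimum-total-cost simple path by exhaustive enumeration.

    ``edges`` maps frozenset({u, v}) -> cost.  Returns (cost, path) or None.
    """
    adj = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    best = None

    def walk(node, seen, cost, path):
        nonlocal best
        if node == dst:
            if best is None or cost < best[0]:
                best = (cost, list(path))
            return
        for nxt in adj.get(node, ()):
            if nxt in seen:
                continue
            walk(nxt, seen | {nxt}, cost + edges[frozenset((node, nxt))],
                 path + [nxt])

    if src not in adj or dst not in adj:
        return None
    walk(src, {src}, 0.0, [src])
    return best


def brute_widest_bottleneck(edges: dict, src, dst):
    """max over paths of (min edge width along the path), by enumeration."""
    adj = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    best = None

    def walk(node, seen, width):
        nonlocal best
        if node == dst:
            if best is None or width > best:
                best = width
            return
        for nxt in adj.get(node, ()):
            if nxt in seen:
                continue
            walk(nxt, seen | {nxt}, min(width, edges[frozenset((node, nxt))]))

    if src not in adj or dst not in adj:
        return None
    walk(src, {src}, float("inf"))
    return best


def bfs_depths(adjacency: dict, sources):
    """Multi-source BFS hop counts (plain deque implementation)."""
    depth = {s: 0 for s in sources}
    q = deque(sources)
    while q:
        u = q.popleft()
        for v in adjacency.get(u, ()):
            if v not in depth:
                depth[v] = depth[u] + 1
                q.append(v)
    return depth


# ---------------------------------------------------------------------------
# straightness oracle: literal transcription of the double sum
# ---------------------------------------------------------------------------

def straightness_reference(S: np.ndarray) -> float:
    """s(S) = sum_{d=1}^{|S|/2} sum_{i=1}^{|S|-2d} d cos(angle(S[i], S[i+d],
    S[i+2d])) / (same sum of d), with the turning-angle cosine convention,
    written as plain nested loops."""
    S = np.asarray(S, float)
    m = len(S)
    num = 0.0
    den = 0.0
    for d in range(1, m // 2 + 1):
        for i in range(0, m - 2 * d):
            u = S[i + d] - S[i]
            v = S[i + 2 * d] - S[i + d]
            cosang = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
            num += d * max(-1.0, min(1.0, cosang))
            den += d
    return num / den


# ---------------------------------------------------------------------------
# tube constriction oracle: dense sampling of clearance along the axis
# ---------------------------------------------------------------------------

def axis_clearance_profile(structure, z_values):
    """Distance from axis points (0, 0, z) to the nearest atom ball surface."""
    P = structure.centers
    r = structure.radii
    out = []
    for z in z_values:
        d = np.linalg.norm(P - np.array([0.0, 0.0, z]), axis=1) - r
        out.append(float(d.min()))
    return np.array(out)
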