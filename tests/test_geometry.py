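import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull, Delaunay

from alphapore.exceptions import DegenerateInputError
from alphapore.geometry import (
    build_alpha_complex,
    orthosphere,
    power_distance,
    regular_triangulation,
)
from alphapore.model_io import WeightedAtom

from .conftest import random_structure, structure_from_points
from .oracles import brute_force_regular_tets, dual_complex_member_by_sampling


def atom(center, radius, serial=1):
    return WeightedAtom(serial, "C", "C", "ALA", serial, "A",
                        np.asarray(center, float), radius)


class TestPowerDistance:
    def test_unit_ball_at_distance_two(self):
        assert power_distance(atom([0, 0, 0], 1.0), [2, 0, 0]) == pytest.approx(3.0)

    def test_zero_on_ball_surface(self):
        a = atom([1, 2, 3], 1.5)
        x = a.center + np.array([0, 0, 1.5])
        assert power_distance(a, x) == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_agrees_with_naive_formula(self, seed):
        rng = np.random.default_rng(seed)
        p = atom(rng.normal(size=3), float(rng.uniform(0.3, 2.0)))
        x = rng.normal(size=3) * 5
        expected = sum((x[i] - p.center[i]) ** 2 for i in range(3)) - p.radius ** 2
        assert power_distance(p, x) == pytest.approx(expected, rel=1e-12)


class TestOrthosphere:
    def test_regular_tetrahedron_closed_form(self):
        # edge a=2, all radii 1: circumradius a*sqrt(6)/4, size = 6/4 - 1
        a = 2.0
        P = np.array([
            [0, 0, 0], [a, 0, 0], [a / 2, a * math.sqrt(3) / 2, 0],
            [a / 2, a * math.sqrt(3) / 6, a * math.sqrt(2.0 / 3.0)],
        ])
        c, s = orthosphere([atom(p, 1.0, i + 1) for i, p in enumerate(P)])
        assert s == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(c, P.mean(axis=0), atol=1e-9)

    def test_equilateral_triangle_zero_weight_is_circumcircle(self):
        P = np.array([[0, 0, 0], [2, 0, 0], [1, math.sqrt(3), 0]])
        c, s = orthosphere([atom(p, 1e-9, i + 1) for i, p in enumerate(P)])
        circumradius_sq = (2 / math.sqrt(3)) ** 2
        assert s == pytest.approx(circumradius_sq, rel=1e-6)
        assert np.allclose(c, [1, 1 / math.sqrt(3), 0], atol=1e-6)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_zero_power_residual(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        P = rng.normal(size=(k, 3)) * 4
        if k > 2 and abs(np.linalg.det(np.cov(P.T))) < 1e-8:
            return
        atoms = [atom(P[i], float(rng.uniform(0.3, 2.0)), i + 1) for i in range(k)]
        try:
            c, s = orthosphere(atoms)
        except DegenerateInputError:
            return
        scale = max(1.0, abs(s))
        for a in atoms:
            assert power_distance(a, c) == pytest.approx(s, abs=1e-9 * scale)

    def test_collinear_centers_rejected(self):
        atoms = [atom([float(i), 0, 0], 1.0, i + 1) for i in range(3)]
        with pytest.raises(DegenerateInputError):
            orthosphere(atoms)


class TestRegularTriangulation:
    def test_four_points_single_tet(self):
        st4 = structure_from_points(
            [[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]], 1.0)
        tri = regular_triangulation(st4)
        assert len(tri.tets) == 1
        assert int(tri.hull_tris.sum()) == 4

    def test_zero_weight_matches_scipy_delaunay(self):
        s = random_structure(50, seed=11, weighted=False)
        tri = regular_triangulation(s)
        ours = set(map(tuple, tri.tets))
        theirs = set(map(tuple, np.sort(Delaunay(s.centers).simplices, axis=1)))
        assert ours == theirs

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_enumeration(self, seed):
        s = random_structure(16, seed=seed, extent=8.0)
        tri = regular_triangulation(s)
        ours = set(map(tuple, tri.tets))
        expected = brute_force_regular_tets(s.centers, s.weights)
        assert ours == expected

    def test_dominated_point_is_hidden(self):
        rng = np.random.default_rng(4)
        P = rng.uniform(0, 6, size=(10, 3))
        # an extra point sitting next to a giant ball that hides it
        big = np.vstack([P, [[3.0, 3.0, 3.0], [3.2, 3.0, 3.0]]])
        radii = np.concatenate([np.full(10, 0.8), [8.0, 0.1]])
        s = structure_from_points(big, radii)
        tri = regular_triangulation(s)
        assert 11 not in set(np.unique(tri.tets))  # the tiny dominated point
        assert 10 in set(np.unique(tri.tets))

    def test_tet_volumes_tile_hull(self):
        s = random_structure(60, seed=9)
        tri = regular_triangulation(s)
        assert tri.tet_volumes().sum() == pytest.approx(
            ConvexHull(s.centers).volume, rel=1e-6)

    def test_hull_surface_is_closed(self):
        s = random_structure(40, seed=21)
        tri = regular_triangulation(s)
        from collections import Counter
        cnt = Counter()
        for f in np.where(tri.hull_tris)[0]:
            a, b, c = tri.tris[f]
            cnt[(a, b)] += 1
            cnt[(a, c)] += 1
            cnt[(b, c)] += 1
        assert all(v == 2 for v in cnt.values())

    def test_coplanar_input_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 1, 0]],
                     float)
        with pytest.raises(DegenerateInputError):
            regular_triangulation(structure_from_points(P, 1.0))


class TestAlphaValues:
    def test_overlapping_pair_edge_in_complex_at_zero(self):
        # two radius-1 atoms 1.9 apart: edge size (1.9/2)^2 - 1 < 0
        s = structure_from_points(
            [[0, 0, 0], [1.9, 0, 0], [10, 10, 0], [0, 10, 10], [10, 0, 10]],
            [1.0, 1.0, 0.5, 0.5, 0.5])
        tri = build_alpha_complex(s)
        e = [i for i, ed in enumerate(tri.edges) if tuple(ed) == (0, 1)][0]
        assert tri.edge_size[e] == pytest.approx(0.95 ** 2 - 1.0, abs=1e-9)
        assert tri.edge_alpha[e] <= 0.0

    def test_separated_pair_edge_not_in_complex_at_zero(self):
        s = structure_from_points(
            [[0, 0, 0], [2.2, 0, 0], [10, 10, 0], [0, 10, 10], [10, 0, 10]],
            [1.0, 1.0, 0.5, 0.5, 0.5])
        tri = build_alpha_complex(s)
        e = [i for i, ed in enumerate(tri.edges) if tuple(ed) == (0, 1)][0]
        assert tri.edge_size[e] == pytest.approx(1.1 ** 2 - 1.0, abs=1e-9)
        assert tri.edge_alpha[e] > 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_membership_matches_dual_complex_sampling(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 9))
        s = structure_from_points(rng.uniform(0, 5, size=(n, 3)),
                                  rng.uniform(0.8, 1.6, size=n))
        try:
            tri = build_alpha_complex(s)
        except DegenerateInputError:
            return
        rng2 = np.random.default_rng(seed)
        # edges and triangles: in complex at 0 iff the dual-face sampling
        # finds a commonly-covered point
        for dim, simplices, alphas in ((1, tri.edges, tri.edge_alpha),
                                       (2, tri.tris, tri.tri_alpha)):
            for i, simplex in enumerate(simplices):
                member = alphas[i] <= 0.0
                sampled = dual_complex_member_by_sampling(
                    s.centers, s.weights, tuple(simplex), rng=rng2)
                if abs(alphas[i]) < 1e-3:
                    continue  # too close to the boundary for sampling
                assert member == sampled, (dim, tuple(simplex), alphas[i])

    @pytest.mark.parametrize("seed", [3, 17])
    def test_filtration_monotone(self, seed):
        s = random_structure(40, seed=seed)
        tri = build_alpha_complex(s)
        assert tri.validate_filtration()

    def test_alpha_complex_extremes_and_monotone(self):
        s = random_structure(30, seed=5)
        tri = build_alpha_complex(s)
        empty = tri.alpha_complex(-1e12)
        assert all(len(v) == 0 for v in empty.values())
        full = tri.alpha_complex(1e12)
        assert len(full[3]) == len(tri.tets)
        a1 = tri.alpha_complex(0.5)
        a2 = tri.alpha_complex(2.0)
        for d in range(4):
            assert set(a1[d]) <= set(a2[d])

    def test_equal_weights_same_simplices_as_unweighted(self):
        rng = np.random.default_rng(8)
        P = rng.uniform(0, 10, size=(30, 3))
        t_w = regular_triangulation(structure_from_points(P, 1.3))
        t_0 = regular_triangulation(structure_from_points(P, 1e-9))
        assert set(map(tuple, t_w.tets)) == set(map(tuple, t_0.tets))
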