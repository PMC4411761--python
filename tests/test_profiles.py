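import numpy as np
import pytest

from alphapore.channels import shortest_channel
from alphapore.exceptions import OutOfBoundsError, ParameterError
from alphapore.model_io import ConservationTable
from alphapore.profiles import (
    ScalarGrid,
    channel_volume,
    conservation_profile,
    electrostatic_profile,
    load_scale,
    physchem_profile,
    radius_profile,
    read_opendx,
    read_scale,
)

from .oracles import trilinear_eval


@pytest.fixture(scope="module")
def tube_channel(tube_analysis, tube_tm_pores):
    return tube_tm_pores[0]


class TestRadiusProfile:
    def test_domain_pinned_to_channel_length(self, tube_analysis, tube_channel):
        rp = radius_profile(tube_channel, tube_analysis.triangulation)
        assert rp.t[0] == 0.0
        assert rp.t[-1] == pytest.approx(tube_channel.length)
        assert np.all(np.diff(rp.t) > 0)

    def test_minimum_equals_bottleneck(self, tube_analysis, tube_channel):
        rp = radius_profile(tube_channel, tube_analysis.triangulation)
        assert rp.minimum() == pytest.approx(tube_channel.bottleneck_radius,
                                             abs=1e-12)

    def test_min_equals_bn_for_every_extracted_channel(self, tube_analysis,
                                                       tube_endpoints):
        net = tube_analysis.network
        reps = tube_endpoints.B_imp
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                c = shortest_channel(net, reps[i], reps[j])
                rp = radius_profile(c, tube_analysis.triangulation)
                assert rp.minimum() == pytest.approx(c.bottleneck_radius,
                                                     abs=1e-12)

    def test_dip_at_the_constriction(self, tube_analysis, tube_channel):
        rp = radius_profile(tube_channel, tube_analysis.triangulation)
        t_min = rp.t[int(np.argmin(rp.values))]
        # constriction is at tube mid-length; allow the funnel width
        assert abs(t_min - tube_channel.length / 2) < 5.0
        assert abs(rp.minimum() - 2.0) < 0.3
        assert np.all(rp.values > 0)


class TestScaleTables:
    def test_kyte_doolittle_values(self):
        scale = load_scale("hydropathy")
        assert scale.value("ILE") == 4.5
        assert scale.value("ARG") == -4.5
        assert len(scale.values) == 20

    def test_unknown_scale_rejected(self):
        with pytest.raises(ParameterError):
            load_scale("nope")

    def test_missing_residue_is_nan(self):
        scale = load_scale("charge")
        assert np.isnan(scale.value("LIG"))

    def test_read_scale_roundtrip(self, tmp_path):
        p = tmp_path / "scale.tsv"
        p.write_text("ALA\t1.5\nGLY\t-2\n")
        s = read_scale(p, "custom")
        assert s.value("ala") == 1.5
        assert s.value("GLY") == -2


class TestPerTetProfiles:
    def _patched_residues(self, structure, mapping):
        """Temporarily give atoms residue names from atom index -> name."""
        for idx, name in mapping.items():
            structure.atoms[idx].residue_name = name

    def test_uniform_ile_gives_45(self, tube_analysis, tube_channel):
        st = tube_analysis.structure
        old = [a.residue_name for a in st.atoms]
        try:
            for a in st.atoms:
                a.residue_name = "ILE"
            prof = physchem_profile(tube_channel, tube_analysis.triangulation,
                                    st, load_scale("hydropathy"))
            assert np.allclose(prof.values, 4.5)
        finally:
            for a, name in zip(st.atoms, old):
                a.residue_name = name

    def test_mixed_arg_ile_averages_to_zero(self, tube_analysis, tube_channel):
        st = tube_analysis.structure
        tri = tube_analysis.triangulation
        old = [a.residue_name for a in st.atoms]
        try:
            tet0 = tube_channel.node_path[0]
            verts = tri.tets[tet0]
            for a in st.atoms:
                a.residue_name = "GLY"
            for v, name in zip(verts, ["ARG", "ARG", "ILE", "ILE"]):
                st.atoms[v].residue_name = name
            prof = physchem_profile(tube_channel, tri, st, load_scale("hydropathy"))
            assert prof.values[0] == pytest.approx(0.0, abs=1e-12)
        finally:
            for a, name in zip(st.atoms, old):
                a.residue_name = name

    def test_nonstandard_residues_flagged_missing(self, tube_analysis, tube_channel):
        prof = physchem_profile(tube_channel, tube_analysis.triangulation,
                                tube_analysis.structure, load_scale("hydropathy"))
        # the synthetic tube has only TUB residues: every sample is missing
        assert np.all(np.isnan(prof.values))

    def test_conservation_mean(self, tube_analysis, tube_channel):
        st = tube_analysis.structure
        tri = tube_analysis.triangulation
        table = ConservationTable(
            {(a.chain, a.residue_number): 9.0 for a in st.atoms})
        prof = conservation_profile(tube_channel, tri, st, table)
        assert np.allclose(prof.values, 9.0)

    def test_conservation_matches_recomputation(self, tube_analysis, tube_channel):
        st = tube_analysis.structure
        tri = tube_analysis.triangulation
        rng = np.random.default_rng(0)
        table = ConservationTable(
            {(a.chain, a.residue_number): float(rng.uniform(1, 9))
             for a in st.atoms})
        prof = conservation_profile(tube_channel, tri, st, table)
        for i, tet in enumerate(tube_channel.node_path):
            scores = [table.score(st.atoms[v].chain, st.atoms[v].residue_number)
                      for v in tri.tets[tet]]
            assert prof.values[i] == pytest.approx(np.mean(scores))


class TestElectrostaticProfile:
    def _grid_from_function(self, fn, origin=(-5, -5, -5), spacing=1.0, n=25):
        ax = [origin[k] + spacing * np.arange(n) for k in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return ScalarGrid(np.array(origin, float), np.full(3, spacing),
                          fn(X, Y, Z))

    def test_linear_field_reproduced_exactly(self, tube_analysis, tube_channel):
        grid = self._grid_from_function(lambda x, y, z: 2 * x - y + 3 * z,
                                        origin=(-10, -10, -5), spacing=2.0, n=30)
        prof = electrostatic_profile(tube_channel, grid)
        pts = tube_channel.centerline
        expected = 2 * pts[:, 0] - pts[:, 1] + 3 * pts[:, 2]
        assert np.allclose(prof.values, expected, atol=1e-9)

    def test_grid_node_returns_stored_value(self):
        grid = self._grid_from_function(lambda x, y, z: x * y + z, n=10)
        c = _StraightChannel([[-2.0, -1.0, 0.0]])
        prof = electrostatic_profile(c, grid)
        assert prof.values[0] == pytest.approx((-2.0) * (-1.0) + 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_trilinear_polynomial_exact_in_cell(self, seed):
        rng = np.random.default_rng(seed)
        coef = rng.normal(size=8)
        grid = self._grid_from_function(
            lambda x, y, z: trilinear_eval(coef, x, y, z), n=8)
        pts = rng.uniform(-4.9, 1.9, size=(12, 3))
        prof = electrostatic_profile(_StraightChannel(pts), grid)
        expected = [trilinear_eval(coef, *p) for p in pts]
        assert np.allclose(prof.values, expected, atol=1e-9)

    def test_out_of_bounds_names_the_point(self):
        grid = self._grid_from_function(lambda x, y, z: x, n=5)
        with pytest.raises(OutOfBoundsError, match="outside grid"):
            electrostatic_profile(_StraightChannel([[100.0, 0, 0]]), grid)

    def test_read_opendx_roundtrip(self, tmp_path):
        from gridData import Grid
        vals = np.arange(27, dtype=float).reshape(3, 3, 3)
        g = Grid(vals, origin=(1.0, 2.0, 3.0), delta=(0.5, 0.5, 0.5))
        p = tmp_path / "pot.dx"
        g.export(str(p), file_format="dx")
        grid = read_opendx(p)
        assert grid.dims == (3, 3, 3)
        assert np.allclose(grid.values, vals)
        assert np.allclose(grid.origin, [1, 2, 3])


class _StraightChannel:
    """Minimal stand-in with just a centerline and a length."""

    def __init__(self, pts):
        self.centerline = np.atleast_2d(np.asarray(pts, float))
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        self.length = float(seg.sum())


class TestChannelVolume:
    def test_no_balls_gives_sum_of_tet_volumes(self, tube_analysis, tube_channel):
        from alphapore.model_io import Structure, WeightedAtom
        tri = tube_analysis.triangulation
        far = Structure([WeightedAtom(1, "C", "C", "ALA", 1, "A",
                                      [500.0, 0, 0], 1.0)])
        sub = tube_channel.node_path[:20]
        c = type(tube_channel)(sub, tube_channel.triangle_path[:19],
                               tube_channel.centerline[:20], 1.0, 1.0, 1.0)
        vol, err = channel_volume(c, tri, far, mc_samples=20000, seed=1)
        T = tri.points[tri.tets[sub]]
        exact = float(np.abs(np.linalg.det(T[:, 1:] - T[:, :1])).sum() / 6.0)
        assert abs(vol - exact) <= max(3 * err, 1e-9)

    def test_full_cover_gives_zero(self, tube_analysis, tube_channel):
        from alphapore.model_io import Structure, WeightedAtom
        tri = tube_analysis.triangulation
        huge = Structure([WeightedAtom(1, "C", "C", "ALA", 1, "A",
                                       [0.0, 0.0, 20.0], 500.0)])
        sub = tube_channel.node_path[:10]
        c = type(tube_channel)(sub, tube_channel.triangle_path[:9],
                               tube_channel.centerline[:10], 1.0, 1.0, 1.0)
        vol, err = channel_volume(c, tri, huge, mc_samples=5000, seed=2)
        assert vol == pytest.approx(0.0, abs=1e-12)

    def test_matches_voxel_oracle_on_two_tets(self):
        from .conftest import structure_from_points
        from alphapore.geometry import build_alpha_complex
        # two adjacent tets from 5 points, one small ball inside
        P = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [4, 4, 4]],
                     float)
        st = structure_from_points(P, 1.0)
        tri = build_alpha_complex(st)
        path = list(range(len(tri.tets)))[:2]
        shared = [f for f in range(len(tri.tris))
                  if set(tri.tri_tets[f]) == set(path)]
        c = _StraightChannel(tri.tet_center[path])
        c.node_path = path
        c.triangle_path = shared
        vol, err = channel_volume(c, tri, st, mc_samples=120_000, seed=3)
        # voxel oracle over the two tets
        T = tri.points[tri.tets[path]]
        lo, hi = T.reshape(-1, 3).min(0), T.reshape(-1, 3).max(0)
        n = 160
        gx = [lo[k] + (np.arange(n) + 0.5) * (hi[k] - lo[k]) / n for k in range(3)]
        X, Y, Z = np.meshgrid(*gx, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        voxel = np.prod((hi - lo) / n)
        inside_any = np.zeros(len(pts), dtype=bool)
        for m in range(2):
            A = T[m, 0]
            M = (T[m, 1:] - A).T
            bary = np.linalg.solve(M, (pts - A).T).T
            ok = (bary >= -1e-12).all(axis=1) & (bary.sum(axis=1) <= 1 + 1e-12)
            inside_any |= ok
        covered = np.zeros(len(pts), dtype=bool)
        for p, r in zip(st.centers, st.radii):
            covered |= np.linalg.norm(pts - p, axis=1) < r
        oracle = float((inside_any & ~covered).sum()) * voxel
        assert vol == pytest.approx(oracle, rel=0.02)

    def test_too_few_samples_rejected(self, tube_analysis, tube_channel):
        with pytest.raises(ParameterError):
            channel_volume(tube_channel, tube_analysis.triangulation,
                           tube_analysis.structure, mc_samples=10)
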