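"""Mesh container, I/O round trips, cleaning and rigid transforms."""

import numpy as np
import pytest
import trimesh

import molartopo as mt


def _tetra():
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return mt.TriMesh(v, f)


def _cube():
    box = trimesh.creation.box(extents=(1, 1, 1))
    return mt.TriMesh(np.array(box.vertices), np.array(box.faces))


class TestReadWrite:
    def test_ascii_ply_tetra_counts(self, tmp_path):
        path = tmp_path / "tetra.ply"
        mt.write_mesh(_tetra(), path)
        m = mt.read_mesh(path)
        assert m.n_vertices == 4 and m.n_faces == 4

    def test_binary_stl_cube(self, tmp_path):
        path = tmp_path / "cube.stl"
        _cube().to_trimesh().export(str(path))  # trimesh writes binary STL
        m = mt.read_mesh(path)
        assert m.n_faces == 12

    @pytest.mark.parametrize("fmt", ["ply", "stl", "off"])
    def test_geometry_round_trip(self, tmp_path, fmt):
        mesh = _tetra()
        path = tmp_path / f"m.{fmt}"
        mt.write_mesh(mesh, path)
        back = mt.read_mesh(path)
        if fmt == "stl":  # stl stores per-facet corners; compare unique points
            a = np.unique(mesh.vertices.round(6), axis=0)
            b = np.unique(back.vertices.round(6), axis=0)
        else:  # vertex order preserved
            a, b = mesh.vertices, back.vertices
        assert a.shape == b.shape
        assert np.allclose(a, b, atol=1e-6)

    def test_scalar_fields_round_trip(self, tmp_path):
        mesh = _tetra()
        path = tmp_path / "m.ply"
        fd = np.array([0.5, 1.25, -3.0, 0.0])
        vp = np.linspace(0, 1, 4)
        mt.write_mesh(mesh, path, vertex_scalars={"pcv": vp},
                      face_scalars={"dne": fd})
        back = mt.read_mesh(path)
        assert np.allclose(back.face_scalars["dne"], fd)
        assert np.allclose(back.vertex_scalars["pcv"], vp)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)

    def test_stl_with_scalars_warns_geometry_only(self, tmp_path):
        with pytest.warns(UserWarning, match="no scalar fields"):
            mt.write_mesh(_tetra(), tmp_path / "m.stl",
                          face_scalars={"dne": np.zeros(4)})
        assert mt.read_mesh(tmp_path / "m.stl").n_faces == 4

    def test_scalar_contract_errors(self, tmp_path):
        with pytest.raises(ValueError, match="length"):
            mt.write_mesh(_tetra(), tmp_path / "m.ply",
                          face_scalars={"dne": np.zeros(3)})
        with pytest.raises(ValueError, match="non-empty"):
            mt.write_mesh(_tetra(), tmp_path / "m.ply",
                          face_scalars={"": np.zeros(4)})

    def test_unparseable_file_is_format_error(self, tmp_path):
        bad = tmp_path / "bad.ply"
        bad.write_text("this is not a ply file\n")
        with pytest.raises(mt.MeshFormatError):
            mt.read_mesh(bad)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            mt.read_mesh(tmp_path / "absent.ply")

    def test_face_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            mt.TriMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))


class TestClean:
    def test_zero_area_face_removed_others_kept(self):
        m = _tetra()
        faces = np.vstack([m.faces, [0, 0, 1]])  # repeated vertex: zero area
        dirty = mt.TriMesh(m.vertices, faces)
        clean = mt.clean_mesh(dirty, mt.TopoConfig(component_min_faces=1))
        assert clean.n_faces == 4

    def test_small_component_removed(self):
        big = make_sheet(30)  # ~1700 faces
        tri = mt.TriMesh(
            np.array([[10, 10, 0], [11, 10, 0], [10, 11, 0.0]]),
            np.array([[0, 1, 2]]),
        )
        v = np.vstack([big.vertices, tri.vertices])
        f = np.vstack([big.faces, tri.faces + big.n_vertices])
        merged = mt.TriMesh(v, f)
        clean = mt.clean_mesh(merged, mt.TopoConfig(component_min_faces=5))
        assert clean.n_faces == big.n_faces
        assert clean.n_vertices == big.n_vertices

    def test_idempotent(self, molar_tiny):
        cfg = mt.TopoConfig()
        once = mt.clean_mesh(molar_tiny, cfg)
        twice = mt.clean_mesh(once, cfg)
        assert np.allclose(once.vertices, twice.vertices)
        assert np.array_equal(once.faces, twice.faces)

    def test_fully_degenerate_mesh_errors(self):
        m = mt.TriMesh(np.zeros((3, 3)), np.array([[0, 1, 2]]))
        with pytest.raises(mt.EmptyMeshError):
            mt.clean_mesh(m)


def make_sheet(n):
    """Planar triangulated grid over [0,1]^2."""
    x = np.linspace(0, 1, n)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    idx = np.arange(n * n).reshape(n, n)
    a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
    c, d = idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
    return mt.TriMesh(verts, faces)


class TestTaubin:
    def test_planar_sheet_is_fixed_plane(self):
        """A regular planar grid has zero umbrella vectors at interior
        vertices, so one pass leaves them exactly in place; over many passes
        the unpinned boundary drifts in-plane only (the sheet never leaves
        its plane)."""
        sheet = make_sheet(15)
        one = mt.taubin_smooth(sheet, 0.9, -0.95, 1)
        boundary = sheet.boundary_vertex_mask()
        # the inflate half-step sees the boundary's lambda-step motion, so
        # the exact fixed point is the deep interior (>= 2 rings in)
        e, _ = sheet.edges_unique()
        near = boundary.copy()
        near[e[boundary[e].any(axis=1)].ravel()] = True
        deep = ~near
        assert deep.sum() > 50
        assert np.allclose(one.vertices[deep], sheet.vertices[deep], atol=1e-12)
        many = mt.taubin_smooth(sheet, 0.9, -0.95, 10)
        assert np.allclose(many.vertices[:, 2], 0.0, atol=1e-9)

    def test_zero_steps_identity(self, molar_tiny):
        out = mt.taubin_smooth(molar_tiny, 0.0, 0.0, 10)
        assert np.array_equal(out.vertices, molar_tiny.vertices)

    def test_smoothing_reduces_dne_of_noisy_sphere(self):
        import trimesh
        ico = trimesh.creation.icosphere(subdivisions=4)
        rng = np.random.default_rng(3)
        r = 1.0 + rng.normal(0, 0.02, len(ico.vertices))
        noisy = mt.TriMesh(np.array(ico.vertices) * r[:, None], np.array(ico.faces))
        cfg = mt.TopoConfig(dne_outlier_quantile=0.0)
        before = mt.dne(noisy, cfg)[0]
        after = mt.dne(mt.taubin_smooth(noisy, 0.9, -0.95, 10), cfg)[0]
        assert after < before

    def test_volume_preserved_vs_pure_laplacian(self):
        import trimesh
        ico = trimesh.creation.icosphere(subdivisions=3)
        sph = mt.TriMesh(np.array(ico.vertices), np.array(ico.faces))
        v0 = mt.mesh_volume(sph)
        taubin = mt.mesh_volume(mt.taubin_smooth(sph, 0.9, -0.95, 10))
        laplace = mt.mesh_volume(mt.taubin_smooth(sph, 0.9, 0.0, 10))
        assert abs(taubin / v0 - 1) < 0.02
        assert abs(laplace / v0 - 1) > 0.05

    def test_connectivity_unchanged(self, molar_tiny):
        out = mt.taubin_smooth(molar_tiny, 0.9, -0.95, 2)
        assert np.array_equal(out.faces, molar_tiny.faces)


class TestRotateAndArea:
    def test_zero_angle_identity(self, molar_tiny):
        out = mt.rotate_mesh(molar_tiny, "x", 0.0)
        assert np.allclose(out.vertices, molar_tiny.vertices)

    def test_rotation_inverse(self, molar_tiny):
        out = mt.rotate_mesh(mt.rotate_mesh(molar_tiny, "y", 17.3), "y", -17.3)
        assert np.allclose(out.vertices, molar_tiny.vertices, atol=1e-9)

    def test_area_rotation_invariant(self, molar_tiny):
        a0 = mt.surface_area(molar_tiny)
        for axis, ang in [("x", 31.0), ("y", -12.0), ("z", 123.0)]:
            assert np.isclose(mt.surface_area(mt.rotate_mesh(molar_tiny, axis, ang)),
                              a0, rtol=1e-9)

    def test_cube_area(self):
        assert np.isclose(mt.surface_area(_cube()), 6.0)

    def test_hemisphere_area_converges(self):
        errs = []
        for res in (20, 40):
            sa = mt.surface_area(mt.make_fixture("hemisphere", res))
            errs.append(abs(sa / (2 * np.pi) - 1))
        assert errs[1] < errs[0]
        assert errs[1] < 0.005

    def test_area_scaling_law(self, molar_tiny):
        scaled = mt.TriMesh(molar_tiny.vertices * 2.0, molar_tiny.faces)
        assert np.isclose(mt.surface_area(scaled), 4 * mt.surface_area(molar_tiny),
                          rtol=1e-12)
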