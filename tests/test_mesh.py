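"""Discrete geometry: areas, volumes, normals, smoothing, deformation markers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from shapemorph import (
    CorrespondenceError,
    MeshValidationError,
    TriangleMesh,
    deformation_marker,
    mesh_volume,
    smooth_field,
    vertex_areas,
)
from shapemorph.synthetic import icosphere


def brute_force_vertex_areas(mesh):
    """Independent per-face accumulation: one third of incident triangle areas."""
    va = np.zeros(mesh.n_vertices)
    for tri in mesh.faces:
        p0, p1, p2 = mesh.vertices[tri]
        area = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0))
        for v in tri:
            va[v] += area / 3.0
    return va


class TestAnalyticGeometry:
    def test_cube_area_and_volume_exact(self, cube_mesh):
        assert cube_mesh.area() == pytest.approx(24.0, abs=1e-12)
        assert mesh_volume(cube_mesh) == pytest.approx(8.0, abs=1e-12)

    def test_flipped_faces_negate_volume(self, cube_mesh):
        flipped = TriangleMesh(cube_mesh.vertices, cube_mesh.faces[:, ::-1])
        assert mesh_volume(flipped, validate=False) == pytest.approx(-8.0, abs=1e-12)

    def test_icosphere_matches_closed_forms(self):
        mesh = icosphere(4)
        mesh = TriangleMesh(mesh.vertices * 10.0, mesh.faces)
        assert mesh.area() == pytest.approx(4 * np.pi * 100, rel=0.01)
        assert mesh.volume() == pytest.approx(4 / 3 * np.pi * 1000, rel=0.01)

    def test_vertex_areas_match_brute_force(self, cube_mesh):
        rng = np.random.default_rng(0)
        bumpy = TriangleMesh(
            cube_mesh.vertices + 0.1 * rng.standard_normal(cube_mesh.vertices.shape),
            cube_mesh.faces,
        )
        expected = brute_force_vertex_areas(bumpy)
        got = vertex_areas(bumpy)
        np.testing.assert_allclose(got, expected, rtol=1e-9)
        assert got.sum() == pytest.approx(bumpy.area(), rel=1e-12)

    def test_rigid_motion_invariance(self):
        mesh = icosphere(3)
        rng = np.random.default_rng(5)
        for _ in range(3):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(0, 50, 3)
            moved = TriangleMesh(mesh.vertices @ R.T + t, mesh.faces)
            assert moved.volume() == pytest.approx(mesh.volume(), rel=1e-9)
            assert moved.area() == pytest.approx(mesh.area(), rel=1e-9)


class TestValidation:
    def test_open_mesh_rejected_with_edges(self, cube_mesh):
        open_mesh = TriangleMesh(cube_mesh.vertices, cube_mesh.faces[:-1])
        with pytest.raises(MeshValidationError) as exc:
            open_mesh.validate()
        assert exc.value.offending_edges  # offending boundary edges reported

    def test_degenerate_face_rejected(self, cube_mesh):
        faces = cube_mesh.faces.copy()
        faces[0] = [0, 0, 1]
        with pytest.raises(MeshValidationError, match="degenerate|duplicated"):
            TriangleMesh(cube_mesh.vertices, faces).validate()

    def test_unreferenced_vertex_rejected(self, cube_mesh):
        verts = np.vstack([cube_mesh.vertices, [[5, 5, 5]]])
        with pytest.raises(MeshValidationError, match="unreferenced"):
            TriangleMesh(verts, cube_mesh.faces).validate()

    def test_out_of_range_face_index_rejected(self, cube_mesh):
        faces = cube_mesh.faces.copy()
        faces[0, 0] = 99
        with pytest.raises(MeshValidationError, match="out of range"):
            TriangleMesh(cube_mesh.vertices, faces)


class TestSmoothField:
    def test_constant_field_fixed_point_and_zero_iterations_identity(self, cube_mesh):
        const = np.full(cube_mesh.n_vertices, 3.7)
        np.testing.assert_allclose(smooth_field(cube_mesh, const, 5), const)
        rng = np.random.default_rng(1)
        f = rng.standard_normal(cube_mesh.n_vertices)
        np.testing.assert_array_equal(smooth_field(cube_mesh, f, 0), f)

    def test_spike_max_decreases_and_maximum_principle(self):
        mesh = icosphere(2)
        f = np.zeros(mesh.n_vertices)
        f[0] = 1.0
        g = smooth_field(mesh, f, 1)
        assert g.max() < f.max()
        rng = np.random.default_rng(2)
        f = rng.uniform(-2, 5, mesh.n_vertices)
        g = smooth_field(mesh, f, 7, weight=0.8)
        assert g.min() >= f.min() - 1e-12 and g.max() <= f.max() + 1e-12

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        field=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=12, max_size=12
        ),
        weight=st.floats(0.05, 1.0),
        iterations=st.integers(0, 6),
    )
    def test_smoothing_contracts_range_property(self, field, weight, iterations):
        """For any field, weight and iteration count, iterated one-ring
        averaging never leaves the input range (discrete maximum principle)."""
        mesh = icosphere(0)  # icosahedron, 12 vertices
        f = np.array(field)
        g = smooth_field(mesh, f, iterations, weight=weight)
        tol = 1e-9 * max(1.0, np.abs(f).max())
        assert g.min() >= f.min() - tol and g.max() <= f.max() + tol

    def test_invalid_parameters_rejected(self, cube_mesh):
        f = np.zeros(cube_mesh.n_vertices)
        with pytest.raises(ValueError):
            smooth_field(cube_mesh, f, -1)
        with pytest.raises(ValueError):
            smooth_field(cube_mesh, f, 1, weight=0.0)


class TestDeformationMarker:
    def test_identity_map_gives_unit_markers(self, sphere_template):
        mesh, _ = sphere_template
        np.testing.assert_allclose(deformation_marker(mesh, mesh), 1.0, atol=1e-14)
        np.testing.assert_allclose(deformation_marker(mesh, mesh, log_scale=True), 0.0, atol=1e-14)

    @pytest.mark.parametrize("c", [0.9, 1.3])
    def test_uniform_scaling_gives_c_squared(self, sphere_template, c):
        mesh, _ = sphere_template
        scaled = TriangleMesh(mesh.vertices * c, mesh.faces)
        np.testing.assert_allclose(deformation_marker(mesh, scaled), c**2, rtol=1e-12)

    def test_multiplicative_under_composed_scalings(self, sphere_template):
        mesh, _ = sphere_template
        c, d = 1.1, 0.8
        stage1 = TriangleMesh(mesh.vertices * c, mesh.faces)
        stage2 = TriangleMesh(mesh.vertices * (c * d), mesh.faces)
        combined = deformation_marker(mesh, stage2)
        product = deformation_marker(mesh, stage1) * deformation_marker(stage1, stage2)
        np.testing.assert_allclose(combined, product, rtol=1e-12)

    def test_random_deformation_matches_per_vertex_oracle(self, sphere_template):
        mesh, _ = sphere_template
        rng = np.random.default_rng(11)
        subject = TriangleMesh(
            mesh.vertices * (1 + 0.05 * np.sin(mesh.vertices[:, [0]]))
            + 0.1 * rng.standard_normal(mesh.vertices.shape),
            mesh.faces,
        )
        oracle = brute_force_vertex_areas(subject) / brute_force_vertex_areas(mesh)
        np.testing.assert_allclose(deformation_marker(mesh, subject), oracle, rtol=1e-12)

    def test_correspondence_mismatch_rejected(self, sphere_template, cube_mesh):
        mesh, _ = sphere_template
        with pytest.raises(CorrespondenceError):
            deformation_marker(mesh, cube_mesh)
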