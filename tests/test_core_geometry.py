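"""Geometric primitives: I/O, volume, clipping, nearest queries, labeling."""

import numpy as np
import pytest
import trimesh

from tmj3d.core_geometry import (
    MeshError,
    Plane,
    REGIONS,
    RigidTransform,
    SurfaceMesh,
    VoxelVolume,
    clip_by_plane,
    label_by_planes,
    mesh_volume,
    nearest_surface_point,
    read_mesh,
    volume_to_mesh,
    write_mesh,
)

SPHERE_VOL = 4.0 / 3.0 * np.pi * 1000.0  # r = 10 mm

TETRA_STL = """solid tetra
facet normal 0 0 -1
 outer loop
  vertex 0 0 0
  vertex 1 0 0
  vertex 0 1 0
 endloop
endfacet
facet normal 0 -1 0
 outer loop
  vertex 0 0 0
  vertex 0 0 1
  vertex 1 0 0
 endloop
endfacet
facet normal -1 0 0
 outer loop
  vertex 0 0 0
  vertex 0 1 0
  vertex 0 0 1
 endloop
endfacet
facet normal 1 1 1
 outer loop
  vertex 1 0 0
  vertex 0 0 1
  vertex 0 1 0
 endloop
endfacet
endsolid tetra
"""


class TestMeshIO:
    def test_roundtrip_identity(self, tmp_path):
        verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        mesh = SurfaceMesh(verts, faces)
        for ext in (".stl", ".ply", ".obj"):
            path = tmp_path / f"square{ext}"
            write_mesh(mesh, path)
            back = read_mesh(path)
            assert len(back.vertices) == 4 and len(back.faces) == 2
            # vertex sets identical up to float precision and ordering
            a = np.sort(back.vertices.view([("", float)] * 3), axis=0)
            b = np.sort(verts.view([("", float)] * 3), axis=0)
            assert np.allclose(a.view(float), b.view(float), atol=1e-6)

    def test_ascii_stl_tetrahedron_merges_vertices(self, tmp_path):
        path = tmp_path / "tetra.stl"
        path.write_text(TETRA_STL)
        mesh = read_mesh(path)
        assert len(mesh.faces) == 4
        assert len(mesh.vertices) == 4
        assert abs(mesh_volume(mesh) - 1.0 / 6.0) < 1e-12

    def test_empty_file_is_io_error(self, tmp_path):
        path = tmp_path / "empty.stl"
        path.write_text("")
        with pytest.raises(IOError):
            read_mesh(path)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_mesh(tmp_path / "nope.stl")


class TestMeshVolume:
    def test_unit_cube_exact(self, unit_cube):
        assert mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)

    def test_icosphere_within_one_percent(self, sphere10):
        assert mesh_volume(sphere10) == pytest.approx(SPHERE_VOL, rel=0.01)

    def test_open_mesh_raises_with_boundary_count(self, unit_cube):
        open_mesh = SurfaceMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(MeshError, match="open mesh"):
            mesh_volume(open_mesh)

    def test_rigid_invariance(self, sphere10):
        t = RigidTransform.from_axis_angle((1, 2, 3), 33.0, translation=(5, -7, 11))
        moved = SurfaceMesh(t.apply(sphere10.vertices), sphere10.faces)
        assert mesh_volume(moved) == pytest.approx(mesh_volume(sphere10), rel=1e-9)


class TestClipByPlane:
    def test_hemisphere_volume(self, sphere10):
        plane = Plane([0, 0, 0], [0, 0, 1])
        half = clip_by_plane(sphere10, plane, "positive", cap=True)
        assert half.is_closed()
        assert mesh_volume(half) == pytest.approx(SPHERE_VOL / 2, rel=0.01)

    def test_cap_additivity(self, sphere10):
        # volumes of the two capped halves must sum to the whole
        plane = Plane([0.5, -0.3, 1.2], [0.2, 0.3, 0.93])
        up = clip_by_plane(sphere10, plane, "positive", cap=True)
        dn = clip_by_plane(sphere10, plane, "negative", cap=True)
        total = mesh_volume(up) + mesh_volume(dn)
        assert total == pytest.approx(mesh_volume(sphere10), rel=1e-6)

    def test_plane_missing_mesh_is_noop(self, sphere10):
        plane = Plane([0, 0, -100], [0, 0, 1])
        out = clip_by_plane(sphere10, plane, "positive")
        assert np.array_equal(out.vertices, sphere10.vertices)
        assert np.array_equal(out.faces, sphere10.faces)

    def test_plane_missing_mesh_empty_side(self, sphere10):
        plane = Plane([0, 0, -100], [0, 0, 1])
        out = clip_by_plane(sphere10, plane, "negative")
        assert out.is_empty()

    def test_uncapped_boundary_lies_on_plane(self, sphere10):
        plane = Plane([0, 0, 2.0], [0, 0, 1])
        open_half = clip_by_plane(sphere10, plane, "positive", cap=False)
        boundary = np.unique(open_half.boundary_edges())
        assert len(boundary) > 0
        assert np.abs(open_half.vertices[boundary][:, 2] - 2.0).max() < 1e-6


class TestNearestSurfacePoint:
    def test_own_vertex_distance_zero(self, sphere5_coarse):
        d, cp, fi = nearest_surface_point(sphere5_coarse.vertices[17], sphere5_coarse)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_outside_sphere_analytic(self, sphere10):
        d, cp, fi = nearest_surface_point([0.0, 0.0, 11.0], sphere10)
        assert d == pytest.approx(1.0, abs=0.02)  # facet tolerance

    def test_matches_brute_force(self, sphere5_coarse):
        from trimesh.triangles import closest_point

        rng = np.random.default_rng(42)
        queries = rng.normal(0.0, 8.0, (100, 3))
        d, _, _ = nearest_surface_point(queries, sphere5_coarse)
        tri = sphere5_coarse.vertices[sphere5_coarse.faces]
        for q, di in zip(queries, d):
            brute = np.linalg.norm(
                closest_point(tri, np.repeat(q[None], len(tri), axis=0)) - q, axis=1
            ).min()
            assert di == pytest.approx(brute, abs=1e-9)

    def test_empty_mesh_raises(self):
        empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(MeshError):
            nearest_surface_point([0, 0, 0], empty)


class TestLabelByPlanes:
    def test_symmetric_sphere_quarters(self, sphere10):
        labels = label_by_planes(
            sphere10, Plane([0, 0, 0], [0, 1, 0]), Plane([0, 0, 0], [1, 0, 0])
        )
        n = len(sphere10.vertices)
        for region in REGIONS:
            frac = np.mean(labels == region)
            assert abs(frac - 0.25) < 0.02
        # partition: every vertex labeled exactly once
        assert sum(np.sum(labels == r) for r in REGIONS) == n

    def test_single_label_when_offset(self, sphere10):
        labels = label_by_planes(
            sphere10, Plane([0, -50, 0], [0, 1, 0]), Plane([-50, 0, 0], [1, 0, 0])
        )
        assert set(labels) == {"anterior-lateral"}

    def test_on_plane_tie_goes_anterior_lateral(self):
        mesh = SurfaceMesh(
            np.array([[0.0, 0.0, 0.0], [1e-12, 0.0, 1.0], [0.0, 1e-12, 2.0]]),
            np.array([[0, 1, 2]]),
        )
        labels = label_by_planes(
            mesh, Plane([0, 0, 0], [0, 1, 0]), Plane([0, 0, 0], [1, 0, 0])
        )
        assert list(labels) == ["anterior-lateral"] * 3

    def test_flipping_plane_swaps_label_pairs(self, sphere10):
        ap = Plane([0, 0, 0], [0, 1, 0])
        lm = Plane([0, 0, 0], [1, 0, 0])
        labels = label_by_planes(sphere10, ap, lm)
        flipped = label_by_planes(sphere10, ap.flipped(), lm)
        on_plane = np.abs(sphere10.vertices[:, 1]) < 1e-9
        swap = {
            "anterior-lateral": "posterior-lateral",
            "anterior-medial": "posterior-medial",
            "posterior-lateral": "anterior-lateral",
            "posterior-medial": "anterior-medial",
        }
        expected = np.array([swap[l] for l in labels])
        assert np.array_equal(flipped[~on_plane], expected[~on_plane])

    def test_near_parallel_planes_rejected(self, sphere10):
        with pytest.raises(ValueError, match="parallel"):
            label_by_planes(
                sphere10, Plane([0, 0, 0], [0, 1, 0]), Plane([0, 0, 0], [0.05, 1, 0])
            )


@pytest.fixture(scope="module")
def sphere_volume():
    spacing = 0.3
    x = np.arange(-10, 10, spacing)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    occ = ((X**2 + Y**2 + Z**2) < 64.0).astype(np.float32)
    return VoxelVolume(occ, [spacing] * 3, [x[0]] * 3), occ


class TestVolumeToMesh:

    def test_rasterized_sphere_volume(self, sphere_volume):
        vol, _ = sphere_volume
        mesh = volume_to_mesh(vol, 0.5)
        analytic = 4.0 / 3.0 * np.pi * 512.0
        assert mesh_volume(mesh) == pytest.approx(analytic, rel=0.05)

    def test_uniform_volume_yields_empty_mesh(self):
        vol = VoxelVolume(np.zeros((8, 8, 8)), [1.0] * 3, [0.0] * 3)
        mesh = volume_to_mesh(vol, 0.0)
        assert mesh.is_empty()

    def test_threshold_outside_range_rejected(self, sphere_volume):
        vol, _ = sphere_volume
        with pytest.raises(ValueError, match="range"):
            volume_to_mesh(vol, 5.0)

    def test_largest_component_kept(self):
        spacing = 0.5
        x = np.arange(-12, 12, spacing)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        big = ((X + 5) ** 2 + Y**2 + Z**2) < 25.0
        small = ((X - 7) ** 2 + Y**2 + Z**2) < 4.0
        vol = VoxelVolume((big | small).astype(np.float32), [spacing] * 3, [x[0]] * 3)
        mesh = volume_to_mesh(vol, 0.5)
        # only the larger sphere survives
        assert mesh_volume(mesh) == pytest.approx(4 / 3 * np.pi * 125, rel=0.1)
        assert mesh.vertices[:, 0].max() < 2.0


class TestRigidTransform:
    def test_rotation_90_deg(self):
        t = RigidTransform.from_axis_angle((0, 0, 1), 90.0)
        assert np.allclose(t.apply([1.0, 0.0, 0.0]), [0.0, 1.0, 0.0], atol=1e-12)

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(3)
        t = RigidTransform.from_axis_angle(rng.normal(size=3), 37.0, translation=(4, 5, 6))
        pts = rng.normal(0, 20, (1000, 3))
        back = t.inverse().apply(t.apply(pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_invalid_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_json_roundtrip(self, tmp_path):
        t = RigidTransform.from_axis_angle((1, 1, 0), 12.0, translation=(1, 2, 3))
        t.to_json(tmp_path / "t.json")
        back = RigidTransform.from_json(tmp_path / "t.json")
        assert np.allclose(back.to_matrix(), t.to_matrix())
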