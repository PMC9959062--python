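"""Plane construction, condyle isolation, fossa patch extraction."""

import numpy as np
import pytest
import trimesh

from tmj3d.core_geometry import (
    LandmarkSet,
    Plane,
    REGIONS,
    RigidTransform,
    SurfaceMesh,
    label_by_planes,
    mesh_volume,
)
from tmj3d.anatomy_partition import (
    CutPlaneSet,
    attach_curve_to_surface,
    build_c_plane,
    build_cut_planes,
    build_subregion_planes,
    extract_fossa_patch,
    frankfurt_plane,
    isolate_condyle,
    partition_fossa,
    region_areas,
)


def lm(**points):
    return LandmarkSet(points)


class TestFrankfurtPlane:
    def test_coplanar_landmarks_give_z_normal(self):
        plane = frankfurt_plane(
            lm(porion_right=(40, 0, 0), porion_left=(-40, 0, 0), orbitale=(0, 60, 0))
        )
        assert np.allclose(plane.normal, [0, 0, 1], atol=1e-12)

    def test_collinear_landmarks_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            frankfurt_plane(
                lm(porion_right=(10, 0, 0), porion_left=(-10, 0, 0), orbitale=(20, 0, 0))
            )

    def test_generic_landmarks_lie_on_plane(self):
        pts = {
            "porion_right": (37.0, -3.0, 2.0),
            "porion_left": (-41.0, 1.0, 4.0),
            "orbitale": (3.0, 58.0, -1.0),
        }
        plane = frankfurt_plane(lm(**pts))
        for p in pts.values():
            assert abs(plane.signed_distance(np.array(p, dtype=float))) < 1e-9


class TestCPlane:
    def test_parallel_through_c_point(self):
        fh = Plane([0, 0, 0], [0, 0, 1])
        cp = build_c_plane((10.0, 5.0, 30.0), fh)
        assert np.allclose(cp.normal, fh.normal)
        assert cp.signed_distance(np.array([7.0, -2.0, 30.0])) == pytest.approx(0.0)

    def test_c_point_on_fh_gives_fh(self):
        fh = Plane([0, 0, 0], [0, 0, 1])
        cp = build_c_plane((4.0, 4.0, 0.0), fh)
        assert abs(fh.signed_distance(cp.point)) < 1e-12


class TestSubregionPlanes:
    LM = dict(
        lateral_pole=(10.0, 0.0, 30.0),
        medial_pole=(-10.0, 0.0, 30.0),
        anterior_reference=(0.0, 50.0, 30.0),
    )

    def test_axis_aligned_construction(self):
        fh = Plane([0, 0, 0], [0, 0, 1])
        pole, mid = build_subregion_planes(lm(**self.LM), fh)
        assert np.allclose(pole.normal, [0, 1, 0], atol=1e-12)
        assert np.allclose(mid.normal, [1, 0, 0], atol=1e-12)
        assert np.allclose(mid.point, [0, 0, 30], atol=1e-12)

    def test_poles_on_pole_plane(self):
        fh = Plane([0, 0, 0], [0.1, 0.05, 0.99])
        pole, _ = build_subregion_planes(lm(**self.LM), fh)
        for p in (self.LM["lateral_pole"], self.LM["medial_pole"]):
            assert abs(pole.signed_distance(np.array(p))) < 1e-9

    def test_orthogonality_invariants(self):
        fh = Plane([0, 0, 0], [0.2, -0.1, 0.97])
        pole, mid = build_subregion_planes(lm(**self.LM), fh)
        assert abs(pole.normal @ fh.normal) < 1e-9
        assert abs(mid.normal @ pole.normal) < 1e-9

    def test_coincident_poles_rejected(self):
        bad = dict(self.LM, medial_pole=self.LM["lateral_pole"])
        with pytest.raises(ValueError):
            build_subregion_planes(lm(**bad), Plane([0, 0, 0], [0, 0, 1]))

    def test_pole_axis_near_fh_normal_rejected(self):
        bad = dict(
            lateral_pole=(0.0, 0.0, 40.0),
            medial_pole=(0.3, 0.0, 20.0),
            anterior_reference=(0.0, 50.0, 30.0),
        )
        with pytest.raises(ValueError):
            build_subregion_planes(lm(**bad), Plane([0, 0, 0], [0, 0, 1]))


class TestIsolateCondyle:
    def test_volumes_and_additivity(self, default_case):
        planes = build_cut_planes(
            default_case.landmarks, condylar_mesh=default_case.pre_ramus
        )
        condyle, neck, head = isolate_condyle(default_case.pre_ramus, planes)
        v_c, v_n, v_h = mesh_volume(condyle), mesh_volume(neck), mesh_volume(head)
        assert v_c == pytest.approx(default_case.truth.condyle_volume_pre, rel=1e-6)
        assert abs(v_h + v_n - v_c) / v_c < 0.005

    def test_degenerate_split_head_equals_condyle(self, default_case):
        planes = build_cut_planes(
            default_case.landmarks, condylar_mesh=default_case.pre_ramus
        )
        degenerate = CutPlaneSet(
            planes.frankfurt, planes.c_plane, planes.pole_plane, planes.mid_plane,
            planes.c_plane,
        )
        condyle, neck, head = isolate_condyle(default_case.pre_ramus, degenerate)
        assert neck.is_empty()
        assert mesh_volume(head) == pytest.approx(mesh_volume(condyle), rel=1e-9)

    def test_c_plane_above_mesh_rejected(self, default_case):
        planes = build_cut_planes(
            default_case.landmarks, condylar_mesh=default_case.pre_ramus
        )
        high = CutPlaneSet(
            planes.frankfurt,
            Plane([0, 0, 100.0], planes.c_plane.normal),
            planes.pole_plane, planes.mid_plane,
            Plane([0, 0, 101.0], planes.c_plane.normal),
        )
        with pytest.raises(Exception, match="empty condyle"):
            isolate_condyle(default_case.pre_ramus, high)


@pytest.fixture(scope="module")
def bowl():
    """Open hemispherical bowl (inner surface of a sphere), radius 10."""
    ico = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    keep = ico.vertices[:, 2] < 0.0
    fmask = keep[ico.faces].all(axis=1)
    faces = ico.faces[fmask]
    used = np.unique(faces)
    remap = np.full(len(ico.vertices), -1)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(ico.vertices[used], remap[faces], process=False)


class TestAttachCurve:
    def test_on_surface_curve_is_idempotent(self, sphere10):
        # ordered ring of vertices near the equator, already on the surface
        band = np.nonzero(np.abs(sphere10.vertices[:, 2]) < 0.6)[0]
        angles = np.arctan2(sphere10.vertices[band, 1], sphere10.vertices[band, 0])
        ring = band[np.argsort(angles)][::4]
        curve = sphere10.vertices[ring]
        loop = attach_curve_to_surface(curve, sphere10)
        snapped = sphere10.vertices[loop]
        for p in curve:
            assert np.linalg.norm(snapped - p, axis=1).min() < 1e-6

    def test_two_point_curve_rejected(self, sphere10):
        with pytest.raises(ValueError):
            attach_curve_to_surface(sphere10.vertices[:2], sphere10)

    def test_point_beyond_capture_distance(self, sphere10):
        curve = np.array([[0, 0, 50.0], [5, 0, 11.0], [0, 5, 11.0]])
        with pytest.raises(ValueError, match="capture"):
            attach_curve_to_surface(curve, sphere10)

    def test_hovering_circle_matches_dijkstra_oracle(self, bowl):
        # circle of radius 8 hovering 1 mm above (inside) the bowl surface
        thetas = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        r, z = 8.0, -6.0
        scale = (10.0 - 1.0) / 10.0  # pull 1 mm toward the center
        curve = np.column_stack(
            [r * np.cos(thetas), r * np.sin(thetas), np.full_like(thetas, z)]
        ) * scale
        loop = attach_curve_to_surface(curve, bowl)
        pts = bowl.vertices[loop]
        length = np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1).sum()
        # independent oracle: networkx shortest paths between the snap anchors
        import networkx as nx

        g = nx.Graph()
        tm = bowl.as_trimesh()
        for (u, v), w in zip(
            tm.edges_unique,
            np.linalg.norm(
                bowl.vertices[tm.edges_unique[:, 0]] - bowl.vertices[tm.edges_unique[:, 1]],
                axis=1,
            ),
        ):
            g.add_edge(int(u), int(v), weight=float(w))
        anchors = []
        for p in curve:
            anchors.append(int(np.argmin(np.linalg.norm(bowl.vertices - p, axis=1))))
        oracle = 0.0
        for a, b in zip(anchors, anchors[1:] + anchors[:1]):
            oracle += nx.shortest_path_length(g, a, b, weight="weight")
        assert length == pytest.approx(oracle, rel=0.05)


class TestFossaPatch:
    def test_equatorial_loop_hemisphere_area(self, sphere10):
        thetas = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        curve = np.column_stack(
            [10.0 * np.cos(thetas), 10.0 * np.sin(thetas), np.zeros_like(thetas)]
        )
        patch = extract_fossa_patch(sphere10, curve, seed=(0, 0, 10.0), loop_is_indices=False)
        assert patch.area() == pytest.approx(2 * np.pi * 100.0, rel=0.02)

    def test_opposite_seed_gives_complement(self, sphere10):
        thetas = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        curve = np.column_stack(
            [10.0 * np.cos(thetas), 10.0 * np.sin(thetas), np.zeros_like(thetas)]
        )
        north = extract_fossa_patch(sphere10, curve, (0, 0, 10.0), loop_is_indices=False)
        south = extract_fossa_patch(sphere10, curve, (0, 0, -10.0), loop_is_indices=False)
        total = north.mesh.n_faces + south.mesh.n_faces
        assert total == sphere10.n_faces

    def test_open_loop_rejected(self, sphere10):
        # consecutive vertices far apart are not mesh edges: the polyline is
        # not a closed edge path, so nothing separates
        loop = np.array([0, 500, 1500])
        with pytest.raises(ValueError, match="separate"):
            extract_fossa_patch(sphere10, loop, (0, 0, 10.0))

    def test_phantom_partition_areas_balanced(self, default_case):
        planes = build_cut_planes(
            default_case.landmarks, condylar_mesh=default_case.pre_ramus
        )
        patch = extract_fossa_patch(
            default_case.pre_skull, default_case.fossa_curve,
            default_case.fossa_seed_point, loop_is_indices=False,
        )
        partition_fossa(patch, planes.pole_plane, planes.mid_plane)
        areas = region_areas(patch)
        total = sum(areas.values())
        for region in REGIONS:
            assert abs(areas[region] / total - 0.25) < 0.03

    def test_condyle_and_fossa_share_label_names(self, default_case):
        planes = build_cut_planes(
            default_case.landmarks, condylar_mesh=default_case.pre_ramus
        )
        patch = extract_fossa_patch(
            default_case.pre_skull, default_case.fossa_curve,
            default_case.fossa_seed_point, loop_is_indices=False,
        )
        partition_fossa(patch, planes.pole_plane, planes.mid_plane)
        condyle, _, _ = isolate_condyle(default_case.pre_ramus, planes)
        condyle_labels = set(
            label_by_planes(condyle, planes.pole_plane, planes.mid_plane)
        )
        assert condyle_labels == set(patch.labels) == set(REGIONS)


class TestRigidEquivariance:
    def test_labeling_invariant_under_common_transform(self, default_case):
        t = RigidTransform.from_axis_angle((1, 2, 1), 17.0, translation=(5, -3, 8))
        planes = build_cut_planes(
            default_case.landmarks, condylar_mesh=default_case.pre_ramus
        )
        condyle, _, _ = isolate_condyle(default_case.pre_ramus, planes)
        labels = label_by_planes(condyle, planes.pole_plane, planes.mid_plane)

        moved_lm = default_case.landmarks.transformed(t)
        moved_ramus = SurfaceMesh(
            t.apply(default_case.pre_ramus.vertices), default_case.pre_ramus.faces
        )
        planes_t = build_cut_planes(moved_lm, condylar_mesh=moved_ramus)
        condyle_t = SurfaceMesh(t.apply(condyle.vertices), condyle.faces, process=False)
        labels_t = label_by_planes(condyle_t, planes_t.pole_plane, planes_t.mid_plane)
        assert np.array_equal(labels, labels_t)
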