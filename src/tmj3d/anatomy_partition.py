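"""Anatomical plane construction and sub-region partitioning.

Builds the landmark-defined planes (Frankfurt horizontal, C-plane, pole
plane, mid-plane, head/neck divider), isolates the condyle from the ramus,
extracts the glenoid fossa patch from the skull by a traced curve, and
partitions both structures into the four sub-regions
(anterior/posterior x lateral/medial).

All anatomical directions come from landmarks — the lateral pole fixes
"lateral", the anterior reference fixes "anterior" — never from world axes,
so left and right joints are handled symmetrically and any scan orientation
is admissible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .core_geometry import (
    LandmarkSet,
    MeshError,
    Plane,
    REGIONS,
    SurfaceMesh,
    clip_by_plane,
    label_by_planes,
    mesh_volume,
    nearest_surface_point,
)

logger = logging.getLogger("tmj3d")


@dataclass
class CutPlaneSet:
    """The five planes driving condylar isolation and partitioning.

    Invariants (asserted): the C-plane and head/neck plane are parallel to
    Frankfurt; the pole plane is perpendicular to Frankfurt; the mid-plane is
    perpendicular to the pole plane.
    """

    frankfurt: Plane
    c_plane: Plane
    pole_plane: Plane
    mid_plane: Plane
    head_neck_plane: Plane

    def __post_init__(self):
        fh_n = self.frankfurt.normal
        if abs(abs(self.c_plane.normal @ fh_n) - 1.0) > 1e-9:
            raise ValueError("C-plane must be parallel to the Frankfurt plane")
        if abs(self.pole_plane.normal @ fh_n) > 1e-9:
            raise ValueError("pole plane must be perpendicular to Frankfurt")
        if abs(self.mid_plane.normal @ self.pole_plane.normal) > 1e-9:
            raise ValueError("mid-plane must be perpendicular to the pole plane")
        if abs(abs(self.head_neck_plane.normal @ fh_n) - 1.0) > 1e-9:
            raise ValueError("head/neck plane must be parallel to Frankfurt")


@dataclass
class FossaPatch:
    """Open sub-mesh of the skull surface bounded by the traced curve."""

    mesh: SurfaceMesh  # open patch, same frame as the skull it came from
    boundary: np.ndarray  # (k, 3) closed polyline on the surface
    labels: np.ndarray | None = None  # per-vertex region labels

    def area(self) -> float:
        return self.mesh.area()


# ---------------------------------------------------------------------------
# Plane constructions
# ---------------------------------------------------------------------------


def frankfurt_plane(landmarks: LandmarkSet) -> Plane:
    """Plane through both porions and orbitale, normal oriented superiorly.

    The superior orientation follows the right-handed anatomical arrangement:
    (orbitale - porion midpoint) x (porion_left - porion_right) points up for
    a head in any pose, because anterior x subject-left = superior.
    """
    landmarks.require("porion_right", "porion_left", "orbitale")
    pr, pl, orb = landmarks["porion_right"], landmarks["porion_left"], landmarks["orbitale"]
    mid = 0.5 * (pr + pl)
    n = np.cross(orb - mid, pl - pr)
    area = 0.5 * np.linalg.norm(np.cross(pl - pr, orb - pr))
    if area < 1.0:  # mm^2
        raise ValueError("porions and orbitale are (near-)collinear")
    return Plane(mid, n)


def build_c_plane(c_point, fh: Plane) -> Plane:
    """Plane parallel to Frankfurt through the C-point (mandibular notch)."""
    return Plane(np.asarray(c_point, dtype=float), fh.normal)


def build_subregion_planes(landmarks: LandmarkSet, fh: Plane) -> tuple[Plane, Plane]:
    """The two cutting planes dividing the condylar head into four sub-regions.

    * *pole plane*: contains both condylar poles, perpendicular to the
      Frankfurt plane; its positive side is anterior (fixed by the
      ``anterior_reference`` landmark).
    * *mid-plane*: through the pole midpoint with normal along the pole
      axis; its positive side is lateral (toward ``lateral_pole``).
    """
    landmarks.require("lateral_pole", "medial_pole", "anterior_reference")
    lat, med = landmarks["lateral_pole"], landmarks["medial_pole"]
    aref = landmarks["anterior_reference"]
    axis = lat - med
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("condylar poles are coincident")
    axis = axis / norm
    if abs(axis @ fh.normal) > np.cos(np.deg2rad(5.0)):
        raise ValueError("pole axis is within 5 degrees of the Frankfurt normal")
    n_pole = np.cross(axis, fh.normal)
    n_pole = n_pole / np.linalg.norm(n_pole)
    mid = 0.5 * (lat + med)
    if (aref - mid) @ n_pole < 0:
        n_pole = -n_pole
    pole_plane = Plane(mid, n_pole)
    # remove the (tiny) component of the pole axis along fh.normal so the
    # orthogonality invariant holds exactly
    n_mid = axis - (axis @ n_pole) * n_pole
    mid_plane = Plane(mid, n_mid)
    if (lat - mid) @ mid_plane.normal < 0:
        mid_plane = mid_plane.flipped()
    return pole_plane, mid_plane


def build_cut_planes(landmarks: LandmarkSet, condylar_mesh: SurfaceMesh | None = None,
                     head_neck_point=None) -> CutPlaneSet:
    """Assemble the full :class:`CutPlaneSet` from landmarks.

    The head/neck divider is not anatomically standardized; by default it is
    the plane parallel to Frankfurt midway between the C-point and the
    superior-most condylar vertex (requires ``condylar_mesh``), overridable
    with an explicit ``head_neck_point``.
    """
    landmarks.require("c_point")
    fh = frankfurt_plane(landmarks)
    c_plane = build_c_plane(landmarks["c_point"], fh)
    pole_plane, mid_plane = build_subregion_planes(landmarks, fh)
    if head_neck_point is not None:
        hn_point = np.asarray(head_neck_point, dtype=float)
    elif condylar_mesh is not None and not condylar_mesh.is_empty():
        heights = c_plane.signed_distance(condylar_mesh.vertices)
        hn_point = landmarks["c_point"] + 0.5 * float(heights.max()) * fh.normal
    else:
        raise ValueError("head/neck plane needs a condylar mesh or an explicit point")
    head_neck = Plane(hn_point, fh.normal)
    return CutPlaneSet(fh, c_plane, pole_plane, mid_plane, head_neck)


# ---------------------------------------------------------------------------
# Condyle isolation
# ---------------------------------------------------------------------------


def isolate_condyle(ramus: SurfaceMesh, planes: CutPlaneSet):
    """Split the ramus into (condyle, neck, head), all capped and closed.

    The condyle is everything above the C-plane; head and neck are split by
    the head/neck plane.  Volume additivity ``V(head) + V(neck) = V(condyle)``
    holds to meshing precision because the caps are exact planar
    triangulations.
    """
    condyle = clip_by_plane(ramus, planes.c_plane, "positive", cap=True)
    if condyle.is_empty():
        raise MeshError("empty condyle: the C-plane lies above the mesh")
    head = clip_by_plane(condyle, planes.head_neck_plane, "positive", cap=True)
    neck = clip_by_plane(condyle, planes.head_neck_plane, "negative", cap=True)
    if not neck.is_empty() and not head.is_empty():
        v_c, v_h, v_n = mesh_volume(condyle), mesh_volume(head), mesh_volume(neck)
        if abs(v_h + v_n - v_c) / v_c > 0.005:
            raise MeshError("head/neck split lost volume (> 0.5% discrepancy)")
    return condyle, neck, head


# ---------------------------------------------------------------------------
# Fossa: curve attachment + patch extraction
# ---------------------------------------------------------------------------


def _edge_graph(mesh: SurfaceMesh):
    e = mesh.as_trimesh().edges_unique
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = len(mesh.vertices)
    g = coo_matrix(
        (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])), shape=(n, n)
    ).tocsr()
    return g


def attach_curve_to_surface(
    curve: np.ndarray, surface: SurfaceMesh, capture_mm: float = 10.0
) -> np.ndarray:
    """Snap a traced curve onto the mesh as a closed loop of vertex indices.

    Each curve point is attracted to its nearest surface vertex; consecutive
    snapped vertices are joined by shortest edge paths (discrete Dijkstra).
    Returns the loop as vertex indices into ``surface``; accidental
    sub-cycles (a vertex visited twice) are excised so the loop is simple.
    """
    curve = np.atleast_2d(np.asarray(curve, dtype=float))
    if len(curve) < 3:
        raise ValueError("a traced curve needs at least 3 points")
    d, cp, fi = nearest_surface_point(curve, surface)
    too_far = np.nonzero(d > capture_mm)[0]
    if len(too_far):
        raise ValueError(
            f"curve points beyond {capture_mm} mm capture distance: indices {too_far.tolist()}"
        )
    # snap to the nearest mesh vertex of the closest face
    anchors = []
    for p, f in zip(curve, fi):
        vs = surface.faces[f]
        anchors.append(vs[np.argmin(np.linalg.norm(surface.vertices[vs] - p, axis=1))])
    anchors = [int(a) for a in anchors]
    g = _edge_graph(surface)
    loop: list[int] = []
    for a, b in zip(anchors, anchors[1:] + anchors[:1]):
        if a == b:
            continue
        dist, pred = dijkstra(g, indices=a, return_predecessors=True)
        if not np.isfinite(dist[b]):
            raise ValueError("curve anchors lie on disconnected surface components")
        path = [b]
        while path[-1] != a:
            path.append(int(pred[path[-1]]))
        loop.extend(path[::-1][:-1])  # drop endpoint, added by next segment
    simple = _simplify_loop(loop)
    if len(simple) < 3:
        raise ValueError("attached curve degenerated to fewer than 3 vertices")
    return np.asarray(simple, dtype=np.int64)


def _simplify_loop(loop: list[int]) -> list[int]:
    """Remove accidental sub-cycles, always discarding the *shorter* one.

    Jittered anchors can make consecutive edge paths backtrack or cross,
    producing small spurs and figure-eights; keeping the longer cycle at
    each repeated vertex preserves the dominant ring.
    """
    changed = True
    while changed:
        changed = False
        pos: dict[int, int] = {}
        for i, v in enumerate(loop):
            if v in pos:
                j = pos[v]
                inner = loop[j:i]
                outer = loop[:j] + loop[i:]
                loop = inner if len(inner) > len(outer) else outer
                changed = True
                break
            pos[v] = i
    return loop


def extract_fossa_patch(
    skull: SurfaceMesh, loop: np.ndarray, seed, loop_is_indices: bool = True,
    capture_mm: float = 10.0,
) -> FossaPatch:
    """The connected face set enclosed by the loop, on the seed's side.

    ``loop`` is either a vertex-index loop from
    :func:`attach_curve_to_surface` or a raw 3D polyline (then attached
    first).  The loop's edges are removed from the face adjacency graph; the
    patch is the connected component containing the face nearest ``seed``.
    A loop that fails to separate the surface is an error.
    """
    loop = np.asarray(loop)
    if loop.ndim == 2 or not loop_is_indices:
        loop = attach_curve_to_surface(loop, skull, capture_mm)
    if len(loop) < 3:
        raise ValueError("loop must contain at least 3 vertices")
    loop_edges = {
        tuple(sorted((int(a), int(b))))
        for a, b in zip(loop, np.roll(loop, -1))
    }
    tm = skull.as_trimesh()
    fadj = tm.face_adjacency  # (k, 2) face pairs sharing an edge
    fedges = tm.face_adjacency_edges  # the shared vertex pair per face pair
    keep = np.array(
        [tuple(sorted((int(a), int(b)))) not in loop_edges for a, b in fedges]
    )
    nf = len(skull.faces)
    pairs = fadj[keep]
    g = coo_matrix(
        (np.ones(2 * len(pairs)), (np.r_[pairs[:, 0], pairs[:, 1]], np.r_[pairs[:, 1], pairs[:, 0]])),
        shape=(nf, nf),
    ).tocsr()
    n_comp, comp = connected_components(g, directed=False)
    if n_comp < 2:
        raise ValueError("loop does not separate the surface")
    _, _, seed_face = nearest_surface_point(np.asarray(seed, dtype=float), skull)
    patch_faces = np.nonzero(comp == comp[seed_face])[0]
    if len(patch_faces) == nf:
        raise ValueError("loop does not separate the surface")
    sub_f = skull.faces[patch_faces]
    used = np.unique(sub_f)
    remap = np.full(len(skull.vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    patch = SurfaceMesh(
        skull.vertices[used], remap[sub_f], frame=skull.frame, process=False
    )
    return FossaPatch(patch, skull.vertices[loop])


def partition_fossa(patch: FossaPatch, pole_plane: Plane, mid_plane: Plane) -> FossaPatch:
    """Label the fossa patch with the same four sub-regions as the condyle."""
    labels = label_by_planes(patch.mesh, pole_plane, mid_plane)
    patch.labels = labels
    patch.mesh.labels = labels
    return patch


def region_areas(patch: FossaPatch) -> dict[str, float]:
    """Face-area per region (face region = majority vote of its vertices)."""
    if patch.labels is None:
        raise ValueError("patch is not partitioned")
    areas = patch.mesh.face_areas()
    out = {r: 0.0 for r in REGIONS}
    fl = face_labels(patch.mesh)
    for r in REGIONS:
        out[r] = float(areas[fl == r].sum())
    return out


def face_labels(mesh: SurfaceMesh) -> np.ndarray:
    """Per-face region labels by majority vote (ties -> lowest region index)."""
    if mesh.labels is None:
        raise ValueError("mesh has no vertex labels")
    vl = mesh.labels[mesh.faces]  # (m, 3) strings
    out = np.empty(len(mesh.faces), dtype=mesh.labels.dtype)
    order = {r: i for i, r in enumerate(REGIONS)}
    for i, row in enumerate(vl):
        vals, counts = np.unique(row, return_counts=True)
        best = counts == counts.max()
        cand = sorted(vals[best], key=lambda r: order.get(str(r), 99))
        out[i] = cand[0]
    return out
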