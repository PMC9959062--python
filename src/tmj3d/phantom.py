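"""Synthetic TMJ phantom: meshes, volumes, landmarks, curves, ground truth.

The phantom emulates every input of the assessment with idealized geometry
chosen for analytic ground truth rather than anatomical realism:

* **condylar process + ramus** — an ellipsoidal condylar head (semi-axes
  defaulting to 10 x 5 x 6 mm, poles exactly at the lateral/medial
  extremities) blending into a vertical shaft standing in for neck and
  ramus, built as one closed parametric surface.
* **glenoid fossa** — the constant-distance (Minkowski) offset of the
  condylar head at gap ``g``, thickened into a shell: the minimum
  condyle-to-fossa distance is exactly ``g`` everywhere under the roof,
  in every sub-region.
* **cranial base** — a slab with asymmetric bumps above the fossa, giving
  the voxel-based registration enough structure.
* **remodeling** — smooth radial Gaussian indentations (resorption) of
  stated depth and radius at stated sub-regions; the peak inward
  displacement equals the stated depth.
* **positional change** — a small translation of the post-operative
  mandible relative to the cranium (condylar displacement within the
  fossa), applied before the simulated scanner pose changes.
* **scanner pose** — independent rigid perturbations of the post-operative
  mandible and cranium, which the SBR / VBR stages must undo.
* **pseudo-CT intensities** — bone 1200, air 0, Gaussian PSF smoothing and
  additive noise, rasterized by voxel-center parity at a configurable
  spacing (0.3 mm isotropic matching CBCT by default; tests use coarser
  grids).

All randomness is driven by ``spec.seed``; the same seed reproduces the
phantom bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_geometry import (
    LandmarkSet,
    MeshError,
    Plane,
    REGIONS,
    RigidTransform,
    SurfaceMesh,
    VoxelVolume,
    mesh_volume,
)

logger = logging.getLogger("tmj3d")


@dataclass
class RemodelingSite:
    """Gaussian resorption dimple: peak depth ``depth_mm`` at the site center,
    falling off with ``radius_mm`` (the Gaussian sigma)."""

    region: str
    depth_mm: float
    radius_mm: float
    center: tuple | None = None  # explicit site center; derived from region if None

    def __post_init__(self):
        if self.region not in REGIONS + ("neck",):
            raise ValueError(f"unknown region {self.region!r}")
        if self.depth_mm < 0:
            raise ValueError("remodeling depth must be >= 0")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic TMJ (mm / degrees)."""

    condyle_semiaxes: tuple = (10.0, 5.0, 6.0)  # lateral, anterior, superior
    neck_scale: tuple = (0.55, 0.9)  # neck semi-axes as fraction of head
    ramus_height: float = 45.0  # shaft length below the head equator
    fossa_gap: float = 3.0
    fossa_thickness: float = 2.0
    fossa_phi_max_deg: float = 65.0  # angular coverage of the fossa roof
    remodeling_sites: list = field(default_factory=list)  # condylar sites
    fossa_remodeling_sites: list = field(default_factory=list)
    condylar_shift: tuple = (0.0, 0.0, 0.0)  # positional change within the fossa
    mandible_rotation_deg: float = 0.0
    mandible_rotation_axis: tuple = (0.0, 0.0, 1.0)
    mandible_translation: tuple = (0.0, 0.0, 0.0)
    cranial_rotation_deg: float = 0.0
    cranial_rotation_axis: tuple = (0.0, 1.0, 0.0)
    cranial_translation: tuple = (0.0, 0.0, 0.0)
    voxel_spacing: float = 0.75
    noise_sd: float = 10.0
    n_theta: int = 48  # circumferential resolution (multiple of 4)
    n_z: int = 48
    seed: int = 0

    def __post_init__(self):
        if self.fossa_gap <= 0:
            raise ValueError("fossa gap must be positive")
        if self.n_theta % 4:
            raise ValueError("n_theta must be a multiple of 4 so the poles are vertices")


@dataclass
class PhantomTruth:
    """Ground truth recorded at generation time."""

    mandible_transform: RigidTransform  # post mandible pose -> pre frame
    cranial_transform: RigidTransform  # post cranium pose -> pre frame
    condyle_volume_pre: float
    condyle_volume_post: float
    carved_volume: float
    region_depths: dict
    joint_space_pre: dict
    joint_space_post: dict
    condylar_shift: np.ndarray


@dataclass
class PhantomCase:
    """One synthetic joint: pre/post anatomy plus all assessment inputs."""

    pre_ramus: SurfaceMesh
    post_ramus: SurfaceMesh
    pre_skull: SurfaceMesh
    post_skull: SurfaceMesh
    landmarks: LandmarkSet
    fossa_curve: np.ndarray
    fossa_seed_point: np.ndarray
    truth: PhantomTruth
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Parametric surfaces
# ---------------------------------------------------------------------------


def _tube_mesh(profile_fn, z_levels, n_theta, top_point, bottom_point):
    """Closed tube: rings of elliptical cross-sections plus apex fans."""
    thetas = np.arange(n_theta) * (2 * np.pi / n_theta)
    ct, st = np.cos(thetas), np.sin(thetas)
    verts = []
    for z in z_levels:
        ax, ay = profile_fn(z)
        ring = np.column_stack([ax * ct, ay * st, np.full(n_theta, z)])
        verts.append(ring)
    verts = np.vstack(verts)
    nz = len(z_levels)
    faces = []
    for i in range(nz - 1):
        a0 = i * n_theta
        b0 = (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append((a0 + j, b0 + j, b0 + jn))
            faces.append((a0 + j, b0 + jn, a0 + jn))
    verts = np.vstack([verts, top_point, bottom_point])
    i_top = len(verts) - 2
    i_bot = len(verts) - 1
    top0 = (nz - 1) * n_theta
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append((top0 + j, top0 + jn, i_top))
        faces.append((j, i_bot, jn))
    mesh = SurfaceMesh(verts, np.asarray(faces, dtype=np.int64), process=False)
    if mesh.as_trimesh().volume < 0:
        mesh = SurfaceMesh(verts, np.asarray(faces)[:, ::-1], process=False)
    return mesh


def _make_ramus(spec: PhantomSpec) -> SurfaceMesh:
    a, b, c = spec.condyle_semiaxes
    an, bn = spec.neck_scale[0] * a, spec.neck_scale[1] * b

    def profile(z):
        if z >= 0:
            f = np.sqrt(max(1.0 - (z / c) ** 2, 0.0))
            return max(a * f, 1e-3), max(b * f, 1e-3)
        f = np.sqrt(max(1.0 - (z / c) ** 2, 0.0)) if z > -c else 0.0
        return max(a * f, an), max(b * f, bn)

    lat = np.linspace(0.0, np.pi / 2, spec.n_z // 2 + 1)[1:-1]
    z_head = c * np.sin(lat)  # equator excluded (in shaft), pole is the apex vertex
    z_shaft = np.linspace(-spec.ramus_height, 0.0, spec.n_z)
    z_levels = np.concatenate([z_shaft, z_head])
    return _tube_mesh(
        profile, z_levels, spec.n_theta, (0.0, 0.0, c), (0.0, 0.0, -spec.ramus_height)
    )


def _ellipsoid_point_normal(a, b, c, phi, theta):
    """Point on the ellipsoid and its outward unit normal (phi from +z)."""
    p = np.stack(
        [
            a * np.sin(phi) * np.cos(theta),
            b * np.sin(phi) * np.sin(theta),
            c * np.cos(phi),
        ],
        axis=-1,
    )
    n = p / np.array([a**2, b**2, c**2])
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    return p, n


def _make_fossa_shell(spec: PhantomSpec) -> SurfaceMesh:
    """Offset shell over the condylar head at constant gap g."""
    a, b, c = spec.condyle_semiaxes
    g, t = spec.fossa_gap, spec.fossa_thickness
    n_theta = spec.n_theta
    n_phi = max(10, spec.n_z // 2)
    phis = np.linspace(0.0, np.deg2rad(spec.fossa_phi_max_deg), n_phi + 1)[1:]
    thetas = np.arange(n_theta) * (2 * np.pi / n_theta)
    PH, TH = np.meshgrid(phis, thetas, indexing="ij")
    p, n = _ellipsoid_point_normal(a, b, c, PH, TH)
    inner = (p + g * n).reshape(-1, 3)
    outer = (p + (g + t) * n).reshape(-1, 3)
    apex_p, apex_n = _ellipsoid_point_normal(a, b, c, 0.0, 0.0)
    inner_apex = apex_p + g * apex_n
    outer_apex = apex_p + (g + t) * apex_n

    verts = [inner, outer, inner_apex[None], outer_apex[None]]
    verts = np.vstack(verts)
    n_grid = n_phi * n_theta
    i_in_apex, i_out_apex = 2 * n_grid, 2 * n_grid + 1

    def gi(layer, i, j):  # layer 0 inner, 1 outer
        return layer * n_grid + i * n_theta + (j % n_theta)

    faces = []
    for i in range(n_phi - 1):
        for j in range(n_theta):
            # inner sheet: normals must face the condyle (downward/inward)
            faces.append((gi(0, i, j), gi(0, i + 1, j), gi(0, i + 1, j + 1)))
            faces.append((gi(0, i, j), gi(0, i + 1, j + 1), gi(0, i, j + 1)))
            # outer sheet: opposite winding
            faces.append((gi(1, i, j), gi(1, i + 1, j + 1), gi(1, i + 1, j)))
            faces.append((gi(1, i, j), gi(1, i, j + 1), gi(1, i + 1, j + 1)))
    for j in range(n_theta):
        faces.append((gi(0, 0, j + 1), gi(0, 0, j), i_in_apex))
        faces.append((gi(1, 0, j), gi(1, 0, j + 1), i_out_apex))
        # rim annulus closing inner and outer sheets at phi_max
        faces.append((gi(0, n_phi - 1, j), gi(1, n_phi - 1, j), gi(1, n_phi - 1, j + 1)))
        faces.append((gi(0, n_phi - 1, j), gi(1, n_phi - 1, j + 1), gi(0, n_phi - 1, j + 1)))
    mesh = SurfaceMesh(verts, np.asarray(faces, dtype=np.int64), process=False)
    if mesh.as_trimesh().volume < 0:
        mesh = SurfaceMesh(verts, np.asarray(faces)[:, ::-1], process=False)
    return mesh


def _subdivided_box(extents, center, edge_mm=4.0) -> SurfaceMesh:
    import trimesh

    box = trimesh.creation.box(extents=extents)
    while box.edges_unique_length.max() > edge_mm:
        box = box.subdivide()
    return SurfaceMesh(box.vertices + np.asarray(center), box.faces, process=False)


def _make_cranial_base(spec: PhantomSpec) -> SurfaceMesh:
    a, b, c = spec.condyle_semiaxes
    z0 = c + spec.fossa_gap + spec.fossa_thickness + 4.0
    slab = _subdivided_box((76.0, 70.0, 6.0), (0.0, 8.0, z0 + 3.0))
    mesh = slab
    # asymmetric features so rigid pose is fully observable by VBR
    for extents, center in [
        ((10.0, 10.0, 8.0), (-24.0, -12.0, z0 + 9.0)),
        ((8.0, 14.0, 6.0), (18.0, 20.0, z0 + 8.0)),
        ((14.0, 6.0, 10.0), (6.0, 34.0, z0 + 10.0)),
    ]:
        mesh = mesh.merged(_subdivided_box(extents, center))
    # generic tilt: no face stays grid-axis-aligned, so rasterized edges
    # staircase-average to their true position instead of quantizing, which
    # keeps intensity registration free of half-voxel bias
    tilt = RigidTransform.from_axis_angle(
        (1.0, 0.6, 0.25), 8.0, center=(0.0, 8.0, z0 + 3.0)
    )
    return SurfaceMesh(tilt.apply(mesh.vertices), mesh.faces, process=False)


# ---------------------------------------------------------------------------
# Remodeling
# ---------------------------------------------------------------------------

_REGION_DIRECTIONS = {
    # unit directions (pre-normalization) in the phantom frame:
    # +x lateral, +y anterior, +z superior; sites sit on the upper head
    "anterior-lateral": (0.6, 0.6, 0.55),
    "anterior-medial": (-0.6, 0.6, 0.55),
    "posterior-lateral": (0.6, -0.6, 0.55),
    "posterior-medial": (-0.6, -0.6, 0.55),
}


def _head_surface_point(semiaxes, u, offset: float = 0.0) -> np.ndarray:
    """Point on the condylar-head ellipsoid in direction ``u`` (or its
    constant-distance offset surface at ``offset``)."""
    a, b, c = semiaxes
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    tt = 1.0 / np.sqrt(np.sum((u / np.array([a, b, c])) ** 2))
    p = tt * u
    if offset == 0.0:
        return p
    n = p / np.array([a**2, b**2, c**2])
    n = n / np.linalg.norm(n)
    return p + offset * n


def _site_center(site: RemodelingSite, semiaxes, offset: float) -> np.ndarray:
    if site.center is not None:
        return np.asarray(site.center, dtype=float)
    if site.region == "neck":
        raise ValueError("neck remodeling sites need an explicit center")
    return _head_surface_point(semiaxes, _REGION_DIRECTIONS[site.region], offset)


def _apply_remodeling(mesh: SurfaceMesh, sites, semiaxes, offset: float = 0.0) -> SurfaceMesh:
    """Indent the surface along outward vertex normals by Gaussian dimples.

    ``offset`` shifts derived site centers onto the fossa offset surface when
    remodeling the skull (fossa resorption moves the socket into the bone).
    """
    if not sites:
        return mesh.copy()
    a, b, c = semiaxes
    if any(s.radius_mm > min(a, b, c) for s in sites):
        raise ValueError("remodeling radius larger than the sub-region extent")
    out = mesh.copy()
    normals = mesh.vertex_normals
    v = out.vertices.copy()
    for s in sites:
        center = _site_center(s, semiaxes, offset)
        r2 = np.sum((v - center) ** 2, axis=1)
        w = np.exp(-r2 / (2.0 * s.radius_mm**2))
        w[w < 1e-3] = 0.0
        v = v - s.depth_mm * w[:, None] * normals
    out.vertices = v
    out._tm = None
    out._query = None
    return out


# ---------------------------------------------------------------------------
# Rasterization (voxel-center parity) and pseudo-CT synthesis
# ---------------------------------------------------------------------------


def rasterize(
    mesh: SurfaceMesh,
    spacing: float,
    padding: float = 3.0,
    bone_hu: float = 1200.0,
    smooth_sigma_vox: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    bounds=None,
) -> VoxelVolume:
    """Binary occupancy (optionally pseudo-CT) of a closed mesh.

    A voxel is inside when its center has odd ray-crossing parity along +z;
    crossings are computed per (x, y) column against the triangles whose 2D
    bounding boxes cover it, which is exact for closed meshes.  With
    ``smooth_sigma_vox`` and ``noise_sd`` the binary map becomes a pseudo-CT
    (bone ~ ``bone_hu``, air ~ 0) suitable for intensity registration.
    """
    if mesh.is_empty():
        raise MeshError("cannot rasterize an empty mesh")
    spacing = float(spacing)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo = mesh.vertices.min(axis=0) - padding
    hi = mesh.vertices.max(axis=0) + padding
    if bounds is not None:
        lo, hi = np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float)
    # sub-voxel origin shift so voxel-center rays avoid exact edge/vertex hits
    lo = lo - 1.2345e-4 * spacing
    if np.any(hi - lo < spacing):
        raise ValueError("voxel spacing larger than the mesh extent")
    nx, ny, nz = (np.ceil((hi - lo) / spacing)).astype(int)
    xs = lo[0] + (np.arange(nx) + 0.5) * spacing
    ys = lo[1] + (np.arange(ny) + 0.5) * spacing
    zs = lo[2] + (np.arange(nz) + 0.5) * spacing

    tri = mesh.vertices[mesh.faces]
    # bucket triangles by the x columns their bbox covers
    t_lo = tri.min(axis=1)
    t_hi = tri.max(axis=1)
    ix_lo = np.clip(np.searchsorted(xs, t_lo[:, 0]) - 1, 0, nx - 1)
    ix_hi = np.clip(np.searchsorted(xs, t_hi[:, 0]), 0, nx - 1)
    occ = np.zeros((nx, ny, nz), dtype=bool)
    for xi in range(nx):
        cand = np.nonzero((ix_lo <= xi) & (ix_hi >= xi))[0]
        if len(cand) == 0:
            continue
        x = xs[xi]
        iy_lo = np.clip(np.searchsorted(ys, t_lo[cand, 1]) - 1, 0, ny - 1)
        iy_hi = np.clip(np.searchsorted(ys, t_hi[cand, 1]), 0, ny - 1)
        for k, ti in enumerate(cand):
            A, B, C = tri[ti]
            for yi in range(iy_lo[k], iy_hi[k] + 1):
                y = ys[yi]
                z = _ray_z_hit(A, B, C, x, y)
                if z is not None:
                    zi = np.searchsorted(zs, z)
                    occ[xi, yi, zi:] ^= True
    # cells above all crossings must end outside; parity guarantees this for
    # closed meshes (even number of crossings per column)
    data = occ.astype(np.float32) * bone_hu
    if smooth_sigma_vox > 0:
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(data, smooth_sigma_vox)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        data = data + rng.normal(0.0, noise_sd, data.shape).astype(np.float32)
    # data[i,j,k] sits at the voxel center lo + (i+0.5) * spacing
    return VoxelVolume(data, [spacing] * 3, lo + 0.5 * spacing)


def _ray_z_hit(A, B, C, x, y):
    """z of the intersection of the vertical line (x, y) with triangle ABC.

    Half-open edge rule (top-left style on the xy projection) so a ray
    crossing a shared edge counts exactly once.
    """
    d = (B[1] - C[1]) * (A[0] - C[0]) + (C[0] - B[0]) * (A[1] - C[1])
    if d == 0.0:
        return None
    w0 = ((B[1] - C[1]) * (x - C[0]) + (C[0] - B[0]) * (y - C[1])) / d
    w1 = ((C[1] - A[1]) * (x - C[0]) + (A[0] - C[0]) * (y - C[1])) / d
    w2 = 1.0 - w0 - w1
    eps = 1e-12
    if w0 < -eps or w1 < -eps or w2 < -eps:
        return None
    # half-open rule: treat boundary hits as inside only on the "low" side
    if abs(w0) <= eps or abs(w1) <= eps or abs(w2) <= eps:
        if d < 0:
            return None
    return w0 * A[2] + w1 * B[2] + w2 * C[2]


# ---------------------------------------------------------------------------
# Observer-rating simulation
# ---------------------------------------------------------------------------


def simulate_observer_ratings(
    true_values, between_sd: float, error_sd: float, k_raters: int = 2, seed: int = 0
):
    """Two-level rating model with known true ICC.

    Subject effects ~ N(0, between_sd^2) are added to the true values, each
    rater adds independent N(0, error_sd^2) noise; the implied true ICC is
    ``between_sd^2 / (between_sd^2 + error_sd^2)`` when the true values are
    constant (all between-subject variance comes from the simulated
    effects).  Returns (RatingsTable, true_icc).
    """
    if between_sd < 0 or error_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if k_raters < 2:
        raise ValueError("need at least 2 raters")
    from .reliability_stats import RatingsTable

    true_values = np.asarray(true_values, dtype=float)
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, between_sd, len(true_values))
    noise = rng.normal(0.0, error_sd, (len(true_values), k_raters))
    values = true_values[:, None] + subj[:, None] + noise
    denom = between_sd**2 + error_sd**2
    true_icc = 1.0 if denom == 0 else between_sd**2 / denom
    return RatingsTable(values), true_icc


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def make_tmj_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build one synthetic TMJ with full ground truth (deterministic per seed).

    Post-operative anatomy is constructed in the pre-operative (cranial)
    frame — remodeling dimples, then the condylar positional shift and any
    extra mandibular segment motion relative to the cranium — and finally
    the whole post scan (skull and mandible together) is moved by the
    cranial scanner pose.  VBR must undo the cranial pose; SBR must undo the
    cranial pose composed with the mandibular relative motion.
    """
    a, b, c = spec.condyle_semiaxes
    sites = [
        s if isinstance(s, RemodelingSite) else RemodelingSite(*s)
        for s in spec.remodeling_sites
    ]
    fossa_sites = [
        s if isinstance(s, RemodelingSite) else RemodelingSite(*s)
        for s in spec.fossa_remodeling_sites
    ]
    pre_ramus = _make_ramus(spec).with_frame("cranial")
    fossa = _make_fossa_shell(spec)
    base = _make_cranial_base(spec)
    pre_skull = fossa.merged(base).with_frame("cranial")

    landmarks = LandmarkSet(
        {
            "porion_right": (40.0, -10.0, 0.0),
            "porion_left": (-40.0, -10.0, 0.0),
            "orbitale": (0.0, 55.0, 0.0),
            "c_point": (0.0, 2.0, -12.0),
            "lateral_pole": (a, 0.0, 0.0),
            "medial_pole": (-a, 0.0, 0.0),
            "anterior_reference": (0.0, 50.0, 0.0),
        }
    )

    # remodeled (but unmoved) post anatomy, still in the cranial frame
    post_ramus_remod = _apply_remodeling(pre_ramus, sites, spec.condyle_semiaxes)
    post_skull_remod = _apply_remodeling(
        pre_skull, fossa_sites, spec.condyle_semiaxes, offset=spec.fossa_gap
    )

    # condylar positional change + segment motion relative to the cranium
    shift = np.asarray(spec.condylar_shift, dtype=float)
    t_seg = RigidTransform.from_axis_angle(
        spec.mandible_rotation_axis,
        spec.mandible_rotation_deg,
        center=(0.0, 0.0, -spec.ramus_height / 2),
        translation=spec.mandible_translation,
    ).compose(RigidTransform(np.eye(3), shift))
    t_cran = RigidTransform.from_axis_angle(
        spec.cranial_rotation_axis,
        spec.cranial_rotation_deg,
        center=(0.0, 0.0, 0.0),
        translation=spec.cranial_translation,
    )
    t_mand_total = t_cran.compose(t_seg)

    c_plane = Plane(landmarks["c_point"], (0.0, 0.0, 1.0))
    from .core_geometry import clip_by_plane

    pre_condyle = clip_by_plane(pre_ramus, c_plane, "positive", cap=True)
    post_condyle = clip_by_plane(post_ramus_remod, c_plane, "positive", cap=True)
    v_pre = mesh_volume(pre_condyle)
    v_post = mesh_volume(post_condyle)

    js_pre = {r: spec.fossa_gap for r in REGIONS}
    # under the fossa roof the gap shrinks by the superior shift component
    js_post = {r: spec.fossa_gap - float(shift[2]) for r in REGIONS}

    post_ramus = SurfaceMesh(
        t_mand_total.apply(post_ramus_remod.vertices), post_ramus_remod.faces,
        frame="post-scan", process=False,
    )
    post_skull = SurfaceMesh(
        t_cran.apply(post_skull_remod.vertices), post_skull_remod.faces,
        frame="post-scan", process=False,
    )

    # traced fossa curve: ring hovering 1 mm off the inner fossa surface
    phi_c = np.deg2rad(spec.fossa_phi_max_deg - 12.0)
    thetas = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    p, n = _ellipsoid_point_normal(a, b, c, np.full_like(thetas, phi_c), thetas)
    curve = p + (spec.fossa_gap - 1.0) * n  # 1 mm below the inner surface
    seed_pt = np.array([0.0, 0.0, c + spec.fossa_gap])

    truth = PhantomTruth(
        mandible_transform=t_mand_total.inverse(),
        cranial_transform=t_cran.inverse(),
        condyle_volume_pre=v_pre,
        condyle_volume_post=v_post,
        carved_volume=v_pre - v_post,
        region_depths={s.region: s.depth_mm for s in sites},
        joint_space_pre=js_pre,
        joint_space_post=js_post,
        condylar_shift=shift,
    )
    return PhantomCase(
        pre_ramus, post_ramus, pre_skull, post_skull,
        landmarks, curve, seed_pt, truth, spec,
    )


def pseudo_ct_pair(case: PhantomCase, spacing: float | None = None):
    """Pre/post pseudo-CT volumes of the cranium plus the VBR mask.

    The post volume is rasterized in the post-scan pose on its own grid; the
    mask selects the cranial-base slab (and bumps) on the pre grid,
    excluding the fossa region, mirroring the "stable anatomy" volume of
    interest.
    """
    spec = case.spec
    spacing = spacing or spec.voxel_spacing
    rng = np.random.default_rng(spec.seed + 1)
    pre_vol = rasterize(
        case.pre_skull, spacing, padding=4.0, smooth_sigma_vox=1.0,
        noise_sd=spec.noise_sd, rng=rng,
    )
    post_vol = rasterize(
        case.post_skull, spacing, padding=4.0, smooth_sigma_vox=1.0,
        noise_sd=spec.noise_sd, rng=rng,
    )
    a, b, c = spec.condyle_semiaxes
    z_base = c + spec.fossa_gap + spec.fossa_thickness + 0.5
    xs, ys, zs = pre_vol.world_coords()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    mask = (pre_vol.data > 400) & (Z > z_base)
    mask_vol = VoxelVolume(mask.astype(np.uint8), pre_vol.spacing, pre_vol.origin)
    return pre_vol, post_vol, mask_vol
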