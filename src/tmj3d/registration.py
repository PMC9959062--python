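"""The two rigid alignment frames of the TMJ assessment.

Condylar remodeling is measured after *surface-based registration* (SBR):
trimmed point-to-plane ICP aligning the post-operative ramus to the
pre-operative ramus on the stable reference region below the condyle.  Fossa
remodeling and joint-space change are measured after *voxel-based
registration* (VBR): masked rigid intensity registration of the
post-operative scan to the pre-operative scan on the anterior cranial base.

Meshes carry a frame tag; downstream metrics refuse to mix the two frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_geometry import (
    MeshError,
    Plane,
    RigidTransform,
    SurfaceMesh,
    VoxelVolume,
)

logger = logging.getLogger("tmj3d")


class RegistrationError(RuntimeError):
    pass


@dataclass
class ICPParams:
    """Trimmed point-to-plane ICP settings.

    The defaults (10% trimming, 10 mm correspondence cutoff, 1e-5 mm RMS
    tolerance, 200 iterations) suit clean bone surface meshes at CBCT
    resolution; trimming makes the alignment robust to the remodeled and
    osteotomized areas that remain after cropping.
    """

    max_iterations: int = 200
    tolerance_mm: float = 1e-5
    cutoff_mm: float = 10.0
    trim_fraction: float = 0.10
    max_points: int = 4000  # deterministic stride subsampling of the moving cloud

    def __post_init__(self):
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ValueError("trim fraction must be in [0, 0.5)")
        if self.tolerance_mm <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    residual: float
    iterations: int
    converged: bool
    trace: list = field(default_factory=list)

    def __post_init__(self):
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


def apply_transform(mesh: SurfaceMesh, t: RigidTransform, frame=None) -> SurfaceMesh:
    """Map every vertex ``v -> R v + t``; faces, scalars and labels unchanged."""
    out = mesh.copy()
    out.vertices = t.apply(mesh.vertices)
    out._tm = None
    out._query = None
    if frame is not None:
        out.frame = frame
    return out


def crop_reference_region(ramus: SurfaceMesh, excluded_planes: list[Plane]) -> SurfaceMesh:
    """Remove the half-spaces that must not bias the SBR alignment.

    Each plane's *positive* side is excluded — pass the C-plane oriented
    superiorly to strip the condylar head, and optionally an
    osteotomy-exclusion plane.  Vertices on a plane (tie rule: positive side)
    are excluded too, so the remaining vertex set is exactly the set strictly
    inside every kept half-space.  Faces touching an excluded vertex are
    dropped (no re-triangulation: this is a registration point set, not a
    closed solid).
    """
    if not excluded_planes:
        raise ValueError("at least one exclusion plane (the C-plane) is required")
    keep = np.ones(len(ramus.vertices), dtype=bool)
    for plane in excluded_planes:
        sd = plane.signed_distance(ramus.vertices)
        keep &= sd < -1e-9
    if keep.sum() < 0.05 * len(ramus.vertices):
        raise RegistrationError(
            f"cropping removed {100 * (1 - keep.mean()):.1f}% of vertices; "
            "reference region too small"
        )
    remap = np.full(len(ramus.vertices), -1, dtype=np.int64)
    remap[keep] = np.arange(keep.sum())
    fmask = keep[ramus.faces].all(axis=1)
    return SurfaceMesh(
        ramus.vertices[keep], remap[ramus.faces[fmask]], frame=ramus.frame, process=False
    )


# ---------------------------------------------------------------------------
# Surface-based registration (trimmed point-to-plane ICP)
# ---------------------------------------------------------------------------


def _centroid_init(moving: SurfaceMesh, fixed: SurfaceMesh) -> RigidTransform:
    return RigidTransform(
        np.eye(3), fixed.vertices.mean(axis=0) - moving.vertices.mean(axis=0)
    )


def _trimmed_rms(moving_pts, fixed: SurfaceMesh, params: ICPParams):
    """Trimmed point-to-surface correspondences and their RMS."""
    d, cp, fi = fixed._surface_query().query(moving_pts)
    ok = d <= params.cutoff_mm
    if not np.any(ok):
        raise RegistrationError("insufficient overlap: no correspondences within cutoff")
    idx = np.nonzero(ok)[0]
    if params.trim_fraction > 0:
        n_keep = max(3, int(np.ceil(len(idx) * (1.0 - params.trim_fraction))))
        order = np.argsort(d[idx], kind="stable")
        idx = idx[order[:n_keep]]
    rms = float(np.sqrt(np.mean(d[idx] ** 2)))
    return idx, cp, fi, rms


def icp_register(
    moving: SurfaceMesh,
    fixed: SurfaceMesh,
    init: RigidTransform | None = None,
    params: ICPParams | None = None,
) -> RegistrationResult:
    """Rigid transform minimizing the trimmed point-to-surface RMS.

    Correspondences are exact nearest points on the fixed surface; each
    iteration solves the linearized point-to-plane system, falling back to
    the closed-form point-to-point (Kabsch) update whenever the linearized
    step would increase the trimmed RMS.  The iteration trace is therefore
    non-increasing by construction and the procedure is fully deterministic
    (stride subsampling, no randomness).
    """
    if moving.is_empty() or fixed.is_empty():
        raise MeshError("cannot register empty meshes")
    params = params or ICPParams()
    T = init if init is not None else _centroid_init(moving, fixed)

    pts0 = moving.vertices
    if len(pts0) > params.max_points:
        stride = int(np.ceil(len(pts0) / params.max_points))
        pts0 = pts0[::stride]
    face_normals = fixed.face_normals

    pts = T.apply(pts0)
    idx, cp, fi, rms = _trimmed_rms(pts, fixed, params)
    trace = [rms]
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        p = pts[idx]
        q = cp[idx]
        n = face_normals[fi[idx]]
        # linearized point-to-plane: find (r, t) minimizing ((p + r x p + t - q).n)^2
        A = np.hstack([np.cross(p, n), n])
        b = ((q - p) * n).sum(axis=1)
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        dT = _small_rigid(x[:3], x[3:])
        cand = dT.compose(T)
        pts_c = cand.apply(pts0)
        idx_c, cp_c, fi_c, rms_c = _trimmed_rms(pts_c, fixed, params)
        if rms_c > trace[-1]:
            # point-to-point fallback on the same correspondences
            dT = _kabsch(p, q)
            cand = dT.compose(T)
            pts_c = cand.apply(pts0)
            idx_c, cp_c, fi_c, rms_c = _trimmed_rms(pts_c, fixed, params)
            if rms_c > trace[-1]:
                converged = True  # no admissible descent step left
                break
        T, pts, idx, cp, fi = cand, pts_c, idx_c, cp_c, fi_c
        improvement = trace[-1] - rms_c
        trace.append(rms_c)
        if improvement < params.tolerance_mm:
            converged = True
            break
    return RegistrationResult(T, trace[-1], it, converged, trace)


def _small_rigid(r: np.ndarray, t: np.ndarray) -> RigidTransform:
    """Exact rotation from an axis-angle vector (valid beyond small angles)."""
    angle = np.linalg.norm(r)
    if angle < 1e-15:
        return RigidTransform(np.eye(3), t)
    return RigidTransform.from_axis_angle(r / angle, np.rad2deg(angle), translation=t)


def _kabsch(p: np.ndarray, q: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping point set p onto q."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    H = (p - pc).T @ (q - qc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, qc - R @ pc)


# ---------------------------------------------------------------------------
# Voxel-based registration (SimpleITK)
# ---------------------------------------------------------------------------


def _to_sitk(vol: VoxelVolume):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.asarray(vol.data, dtype=np.float32).transpose(2, 1, 0))
    )
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def voxel_register(
    moving: VoxelVolume,
    fixed: VoxelVolume,
    mask: VoxelVolume,
    levels: int = 3,
    metric: str = "correlation",
) -> RegistrationResult:
    """Masked rigid intensity registration (multi-resolution).

    ``mask`` is a binary volume on the fixed grid selecting the anatomy
    assumed stable across surgery (anterior cranial base, zygomatic arches,
    forehead).  The similarity metric is normalized correlation by default —
    pre/post CBCT pairs are same-modality, where correlation is the more
    robust masked objective — with ``metric="mi"`` switching to Mattes
    mutual information (32 bins).  Dense metric sampling keeps the
    optimization deterministic.  The returned transform maps moving-space
    geometry into the fixed frame; ``residual`` stores the magnitude of the
    final similarity objective (not millimetres).
    """
    import SimpleITK as sitk

    if not np.any(np.asarray(mask.data) > 0):
        raise RegistrationError("registration mask is empty")
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)
    mask_img = _to_sitk(mask) > 0.5

    R = sitk.ImageRegistrationMethod()
    if metric == "mi":
        R.SetMetricAsMattesMutualInformation(32)
    elif metric == "correlation":
        R.SetMetricAsCorrelation()
    else:
        raise ValueError(f"unknown metric {metric!r}")
    R.SetMetricFixedMask(sitk.Cast(mask_img, sitk.sitkUInt8))
    R.SetInterpolator(sitk.sitkLinear)
    R.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=500,
        relaxationFactor=0.6,
    )
    R.SetOptimizerScalesFromPhysicalShift()
    levels = max(1, int(levels))
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    sigmas = [max(0, s // 2) for s in shrink]
    R.SetShrinkFactorsPerLevel(shrink)
    R.SetSmoothingSigmasPerLevel(sigmas)
    R.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    init = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    R.SetInitialTransform(sitk.Euler3DTransform(init), inPlace=True)
    out = R.Execute(f_img, m_img)

    e = sitk.Euler3DTransform(out)
    M = np.array(e.GetMatrix()).reshape(3, 3)
    c = np.array(e.GetCenter())
    t = np.array(e.GetTranslation())
    # sitk transform maps fixed-domain points into the moving domain;
    # the geometric aligning transform is its inverse
    fixed_to_moving = RigidTransform(M, c - M @ c + t)
    transform = fixed_to_moving.inverse()

    stop = R.GetOptimizerStopConditionDescription()
    converged = "Maximum number of iterations" not in stop
    if not converged:
        logger.warning("voxel_register: optimizer did not converge: %s", stop)
    residual = abs(float(R.GetMetricValue()))
    return RegistrationResult(transform, residual, int(R.GetOptimizerIteration()), converged)
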