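"""Morphovolumetric quantification: distance maps, volume change, joint space.

Sign convention for all surface-distance maps: the signed distance at a
reference vertex is the unsigned nearest distance to the target surface,
with the sign of ``outward_normal . (closest_point - vertex)``.  Positive
means the target lies outside the reference — bone apposition; negative
means resorption.  The reference is always the pre-operative structure and
distances run reference-vertex to target-surface (not symmetric Hausdorff).

The headline "mean surface distance" is the mean *absolute* distance (sign
cancellation would understate remodeling); the signed mean is always
reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_geometry import (
    MeshError,
    REGIONS,
    SurfaceMesh,
    WHOLE,
    mesh_volume,
    nearest_surface_point,
)
from .anatomy_partition import FossaPatch, face_labels

logger = logging.getLogger("tmj3d")


class FrameMismatchError(ValueError):
    """Two structures from different registration frames were combined."""


def _check_frames(a: SurfaceMesh, b: SurfaceMesh):
    if a.frame != b.frame:
        raise FrameMismatchError(
            f"frame mismatch: {a.frame!r} vs {b.frame!r}; condylar metrics live in "
            "the ramus (SBR) frame, fossa/joint-space metrics in the cranial (VBR) frame"
        )


@dataclass
class DistanceMap:
    """Per-vertex signed distances (mm) on a reference mesh."""

    reference: SurfaceMesh
    values: np.ndarray
    sign_convention: str = "outward-normal dot displacement; apposition positive"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.reference.vertices):
            raise ValueError("one distance per reference vertex required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance map contains non-finite values")


def distance_map(reference: SurfaceMesh, target: SurfaceMesh) -> DistanceMap:
    """Signed nearest-surface distance from every reference vertex to target."""
    if target.is_empty():
        raise MeshError("distance_map: empty target mesh")
    _check_frames(reference, target)
    d, cp, _ = nearest_surface_point(reference.vertices, target)
    disp = cp - reference.vertices
    sign = np.sign(np.einsum("ij,ij->i", reference.vertex_normals, disp))
    sign[sign == 0] = 1.0
    return DistanceMap(reference, sign * d)


def _region_mask(labels, region: str) -> np.ndarray:
    labels = np.asarray(labels)
    if region == WHOLE:
        return np.ones(len(labels), dtype=bool)
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}")
    return labels == region


def region_mean_distance(
    dmap: DistanceMap, labels, region: str, mode: str = "absolute"
) -> float:
    """Mean surface distance over one region; NaN flags an empty region."""
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    mask = _region_mask(labels, region)
    if not np.any(mask):
        logger.warning("region %r is empty; mean distance reported as missing", region)
        return float("nan")
    vals = dmap.values[mask]
    return float(np.mean(np.abs(vals) if mode == "absolute" else vals))


def region_rms_distance(dmap: DistanceMap, labels, region: str) -> float:
    """Root-mean-square signed surface distance over one region."""
    mask = _region_mask(labels, region)
    if not np.any(mask):
        logger.warning("region %r is empty; RMS distance reported as missing", region)
        return float("nan")
    return float(np.sqrt(np.mean(dmap.values[mask] ** 2)))


def volumetric_change(pre: SurfaceMesh, post: SurfaceMesh) -> float:
    """Volume change in percent: ``100 (V_post - V_pre) / V_pre``."""
    _check_frames(pre, post)
    v_pre = mesh_volume(pre)
    v_post = mesh_volume(post)
    if v_pre <= 0:
        raise MeshError("pre-operative volume must be positive")
    return 100.0 * (v_post - v_pre) / v_pre


def min_joint_space(
    condyle: SurfaceMesh, fossa: FossaPatch, region: str, pairing: str = "region"
) -> float:
    """Minimum osseous distance between condyle and fossa for one region.

    With ``pairing="region"`` (default) the condylar vertices of the region
    are measured against the fossa faces of the *same* region, attributing
    the gap anatomically; ``pairing="whole"`` measures against the entire
    fossa patch.  ``region="whole"`` is the minimum over all four regions.
    NaN flags a region empty on either side.
    """
    _check_frames(condyle, fossa.mesh)
    if condyle.labels is None or fossa.labels is None:
        raise ValueError("both condyle and fossa must carry region labels")
    if region == WHOLE:
        vals = [min_joint_space(condyle, fossa, r, pairing) for r in REGIONS]
        vals = [v for v in vals if np.isfinite(v)]
        return float(min(vals)) if vals else float("nan")
    cmask = _region_mask(condyle.labels, region)
    if not np.any(cmask):
        logger.warning("condylar region %r empty; joint space missing", region)
        return float("nan")
    if pairing == "whole":
        target = fossa.mesh
    elif pairing == "region":
        fl = face_labels(fossa.mesh)
        fmask = fl == region
        if not np.any(fmask):
            logger.warning("fossa region %r empty; joint space missing", region)
            return float("nan")
        target = SurfaceMesh(
            fossa.mesh.vertices, fossa.mesh.faces[fmask], frame=fossa.mesh.frame,
            process=False,
        )
    else:
        raise ValueError("pairing must be 'region' or 'whole'")
    d, _, _ = nearest_surface_point(condyle.vertices[cmask], target)
    return float(d.min())


def joint_space_change(pre_mm: float, post_mm: float) -> float:
    """Joint-space change: ``post - pre`` (positive = space widened)."""
    if pre_mm is None or post_mm is None or not (np.isfinite(pre_mm) and np.isfinite(post_mm)):
        return float("nan")
    return float(post_mm - pre_mm)


# ---------------------------------------------------------------------------
# Color-coded distance map export
# ---------------------------------------------------------------------------


def export_colormap(dmap: DistanceMap, scale: tuple[float, float], path) -> None:
    """Write the reference mesh as PLY with diverging colors and raw scalars.

    Blue = resorption (negative), white = no change, red = apposition
    (positive); values are clamped at the scale bounds.  The raw signed
    distances are stored in a per-vertex ``distance`` property so the map
    round-trips through :func:`tmj3d.core_geometry.read_mesh`.
    """
    vmin, vmax = scale
    if not (vmin < 0.0 < vmax):
        raise ValueError("scale must straddle zero: vmin < 0 < vmax")
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib import colormaps
    from matplotlib.colors import TwoSlopeNorm

    norm = TwoSlopeNorm(vcenter=0.0, vmin=vmin, vmax=vmax)
    rgba = colormaps["bwr"](norm(np.clip(dmap.values, vmin, vmax)))
    import trimesh

    tm = trimesh.Trimesh(dmap.reference.vertices, dmap.reference.faces, process=False)
    tm.visual.vertex_colors = (rgba * 255).astype(np.uint8)
    tm.vertex_attributes["distance"] = dmap.values.astype(np.float64)
    data = tm.export(file_type="ply", encoding="ascii")
    from pathlib import Path

    Path(path).write_bytes(data if isinstance(data, bytes) else data.encode())


# ---------------------------------------------------------------------------
# MorphometricReport
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = ["side", "structure", "region", "metric", "value", "unit", "frame"]


@dataclass
class MorphometricReport:
    """Tidy per-case measurement record.

    One row per structure x region x metric, mirroring the layout of the
    clinical result tables: volumetric change (%) and mean surface distances
    for condyle / head / neck, RMS distances for the fossa, and minimum
    joint-space pre / post / change, each for the whole structure and the
    four sub-regions.  ``frame`` records which registration frame produced
    the number.
    """

    rows: list = field(default_factory=list)
    sign_convention: str = "outward-normal dot displacement; apposition positive"

    def add(self, side, structure, region, metric, value, unit, frame):
        self.rows.append(
            {
                "side": side,
                "structure": structure,
                "region": region,
                "metric": metric,
                "value": float(value) if value is not None else float("nan"),
                "unit": unit,
                "frame": frame,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=_REPORT_COLUMNS)

    def value(self, structure, region, metric, side=None) -> float:
        df = self.to_frame()
        m = (df.structure == structure) & (df.region == region) & (df.metric == metric)
        if side is not None:
            m &= df.side == side
        hits = df[m]
        if len(hits) == 0:
            raise KeyError(f"no report row for {structure}/{region}/{metric}")
        return float(hits.value.iloc[0])

    def to_csv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# sign convention: {self.sign_convention}\n")
            df.to_csv(fh, index=False)

    def to_json(self, path) -> None:
        self.to_frame().to_json(path, orient="records", indent=1)
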