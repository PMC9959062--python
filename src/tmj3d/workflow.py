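"""End-to-end assessment pipeline and the two-observer reliability study.

Per joint side the pipeline runs, in order:

1. **VBR** — masked rigid intensity registration of the post-operative scan
   to the pre-operative scan on the stable cranial anatomy; the resulting
   transform maps all post-operative geometry into the *cranial* frame.
2. **Fossa analysis** (cranial frame) — traced-curve attachment, fossa
   patch extraction on pre and aligned post skulls, partition into four
   sub-regions, RMS surface distances.
3. **SBR** — two-pass trimmed ICP of the post ramus onto the pre ramus
   (coarse whole-ramus pass, then a refined pass on the reference region
   below the C-plane); the transform defines the *ramus* frame.
4. **Condylar analysis** (ramus frame) — condyle isolation at the C-plane,
   head/neck split, four sub-regions, volumetric change and mean surface
   distances.
5. **Joint space** (cranial frame) — minimum condyle-to-fossa distance per
   sub-region, pre and post, and their change.

Each mesh carries its frame tag, so metrics cannot mix frames by
construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_geometry import (
    LandmarkSet,
    REGIONS,
    SurfaceMesh,
    VoxelVolume,
    WHOLE,
    clip_by_plane,
    label_by_planes,
    mesh_volume,
    read_curve,
    read_mesh,
    read_volume,
)
from .registration import (
    ICPParams,
    apply_transform,
    crop_reference_region,
    icp_register,
    voxel_register,
)
from .anatomy_partition import (
    build_cut_planes,
    extract_fossa_patch,
    isolate_condyle,
    partition_fossa,
)
from .morphometrics import (
    MorphometricReport,
    distance_map,
    export_colormap,
    joint_space_change,
    min_joint_space,
    region_mean_distance,
    region_rms_distance,
    volumetric_change,
)

logger = logging.getLogger("tmj3d")


@dataclass
class CaseConfig:
    """File-based description of one joint side (all paths in mm units)."""

    pre_ramus: str
    post_ramus: str
    pre_skull: str
    post_skull: str
    pre_volume: str
    post_volume: str
    mask_volume: str
    landmarks: str
    fossa_curve: str
    fossa_seed_point: tuple
    side: str = "right"
    out_dir: str | None = None
    icp: ICPParams = field(default_factory=ICPParams)
    vbr_levels: int = 3
    vbr_metric: str = "correlation"
    joint_pairing: str = "region"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        icp = ICPParams(**raw.pop("icp", {}))
        base = Path(path).parent
        for key in (
            "pre_ramus", "post_ramus", "pre_skull", "post_skull",
            "pre_volume", "post_volume", "mask_volume", "landmarks", "fossa_curve",
        ):
            if key in raw and not Path(raw[key]).is_absolute():
                raw[key] = str(base / raw[key])
        cfg = cls(icp=icp, **raw)
        for key in (
            "pre_ramus", "post_ramus", "pre_skull", "post_skull",
            "pre_volume", "post_volume", "mask_volume", "landmarks", "fossa_curve",
        ):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"configured file missing: {key} -> {p}")
        return cfg


@dataclass
class CaseInputs:
    """In-memory inputs for one joint side (what :class:`CaseConfig` loads)."""

    pre_ramus: SurfaceMesh
    post_ramus: SurfaceMesh
    pre_skull: SurfaceMesh
    post_skull: SurfaceMesh
    pre_volume: VoxelVolume
    post_volume: VoxelVolume
    mask_volume: VoxelVolume
    landmarks: LandmarkSet
    fossa_curve: np.ndarray
    fossa_seed_point: np.ndarray
    side: str = "right"


@dataclass
class CaseResult:
    report: MorphometricReport
    sbr_transform: object
    vbr_transform: object
    sbr_residual: float
    diagnostics: dict = field(default_factory=dict)


def _load_inputs(cfg: CaseConfig) -> CaseInputs:
    return CaseInputs(
        pre_ramus=read_mesh(cfg.pre_ramus, frame="cranial"),
        post_ramus=read_mesh(cfg.post_ramus, frame="post-scan"),
        pre_skull=read_mesh(cfg.pre_skull, frame="cranial"),
        post_skull=read_mesh(cfg.post_skull, frame="post-scan"),
        pre_volume=read_volume(cfg.pre_volume),
        post_volume=read_volume(cfg.post_volume),
        mask_volume=read_volume(cfg.mask_volume),
        landmarks=LandmarkSet.from_json(cfg.landmarks),
        fossa_curve=read_curve(cfg.fossa_curve),
        fossa_seed_point=np.asarray(cfg.fossa_seed_point, dtype=float),
        side=cfg.side,
    )


def assess_case(config: CaseConfig) -> CaseResult:
    """Run the full per-joint assessment from a file-based config."""
    stage = "load inputs"
    try:
        inputs = _load_inputs(config)
        return assess_case_inputs(
            inputs,
            icp=config.icp,
            vbr_levels=config.vbr_levels,
            vbr_metric=config.vbr_metric,
            joint_pairing=config.joint_pairing,
            out_dir=config.out_dir,
        )
    except Exception as exc:
        raise RuntimeError(f"assessment aborted at stage '{stage}': {exc}") from exc


def _content_key(*arrays, extra=()) -> str:
    import hashlib

    h = hashlib.md5()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    for e in extra:
        h.update(repr(e).encode())
    return h.hexdigest()


def assess_case_inputs(
    inputs: CaseInputs,
    icp: ICPParams | None = None,
    vbr_levels: int = 3,
    vbr_metric: str = "correlation",
    joint_pairing: str = "region",
    out_dir=None,
    registration_cache: dict | None = None,
) -> CaseResult:
    """Run the pipeline on in-memory inputs.

    ``registration_cache`` (a plain dict, keyed by input content) lets
    repeated assessments of the same scans — e.g. two observers who differ
    only in landmarks and traced curves — reuse the automatic, deterministic
    registration results instead of recomputing them.
    """
    icp = icp or ICPParams()
    side = inputs.side
    report = MorphometricReport()
    diagnostics: dict = {"side": side}

    # ---- stage 1: VBR cranial alignment -------------------------------
    stage = "VBR cranial registration"
    try:
        vbr = None
        vbr_key = None
        if registration_cache is not None:
            vbr_key = _content_key(
                inputs.pre_volume.data, inputs.post_volume.data,
                inputs.mask_volume.data, extra=("vbr", vbr_levels, vbr_metric),
            )
            vbr = registration_cache.get(vbr_key)
        if vbr is None:
            vbr = voxel_register(
                inputs.post_volume, inputs.pre_volume, inputs.mask_volume,
                levels=vbr_levels, metric=vbr_metric,
            )
            if registration_cache is not None:
                registration_cache[vbr_key] = vbr
        t_vbr = vbr.transform
        post_skull_c = apply_transform(inputs.post_skull, t_vbr, frame="cranial")
        diagnostics["vbr_converged"] = vbr.converged
        diagnostics["vbr_iterations"] = vbr.iterations

        # ---- stage 2: planes from pre-operative landmarks --------------
        stage = "plane construction"
        planes = build_cut_planes(inputs.landmarks, condylar_mesh=inputs.pre_ramus)

        # ---- stage 3: fossa extraction + RMS metrics (cranial frame) ---
        stage = "fossa analysis"
        pre_patch = extract_fossa_patch(
            inputs.pre_skull, inputs.fossa_curve, inputs.fossa_seed_point,
            loop_is_indices=False,
        )
        post_patch = extract_fossa_patch(
            post_skull_c, inputs.fossa_curve, inputs.fossa_seed_point,
            loop_is_indices=False,
        )
        partition_fossa(pre_patch, planes.pole_plane, planes.mid_plane)
        partition_fossa(post_patch, planes.pole_plane, planes.mid_plane)
        fossa_map = distance_map(pre_patch.mesh, post_patch.mesh)
        for region in (WHOLE,) + REGIONS:
            report.add(
                side, "fossa", region, "rms_distance",
                region_rms_distance(fossa_map, pre_patch.labels, region),
                "mm", "cranial",
            )
            report.add(
                side, "fossa", region, "mean_abs_distance",
                region_mean_distance(fossa_map, pre_patch.labels, region, "absolute"),
                "mm", "cranial",
            )

        # ---- stage 4: SBR ramus alignment ------------------------------
        stage = "SBR ramus registration"
        coarse = None
        coarse_key = None
        if registration_cache is not None:
            coarse_key = _content_key(
                inputs.post_ramus.vertices, inputs.pre_ramus.vertices,
                extra=("icp-coarse", icp.max_iterations, icp.tolerance_mm,
                       icp.cutoff_mm, icp.trim_fraction, icp.max_points),
            )
            coarse = registration_cache.get(coarse_key)
        if coarse is None:
            coarse = icp_register(inputs.post_ramus, inputs.pre_ramus, params=icp)
            if registration_cache is not None:
                registration_cache[coarse_key] = coarse
        post_coarse = apply_transform(inputs.post_ramus, coarse.transform)
        pre_ref = crop_reference_region(inputs.pre_ramus, [planes.c_plane])
        post_ref = crop_reference_region(post_coarse, [planes.c_plane])
        from .core_geometry import RigidTransform

        fine = icp_register(post_ref, pre_ref, init=RigidTransform.identity(), params=icp)
        t_sbr = fine.transform.compose(coarse.transform)
        diagnostics["sbr_residual_mm"] = fine.residual
        diagnostics["sbr_iterations"] = coarse.iterations + fine.iterations
        diagnostics["sbr_trace_mm"] = {"coarse": coarse.trace, "fine": fine.trace}
        diagnostics["parameters"] = {
            "icp_max_iterations": icp.max_iterations,
            "icp_tolerance_mm": icp.tolerance_mm,
            "icp_cutoff_mm": icp.cutoff_mm,
            "icp_trim_fraction": icp.trim_fraction,
            "vbr_levels": vbr_levels,
            "vbr_metric": vbr_metric,
            "joint_pairing": joint_pairing,
        }

        pre_ramus_r = inputs.pre_ramus.with_frame("ramus")
        post_ramus_r = apply_transform(inputs.post_ramus, t_sbr, frame="ramus")

        # ---- stage 5: condylar metrics (ramus frame) -------------------
        stage = "condylar analysis"
        pre_condyle, pre_neck, pre_head = isolate_condyle(pre_ramus_r, planes)
        post_condyle, post_neck, post_head = isolate_condyle(post_ramus_r, planes)
        report.add(side, "condyle", WHOLE, "volumetric_change",
                   volumetric_change(pre_condyle, post_condyle), "%", "ramus")
        report.add(side, "head", WHOLE, "volumetric_change",
                   volumetric_change(pre_head, post_head), "%", "ramus")
        report.add(side, "neck", WHOLE, "volumetric_change",
                   volumetric_change(pre_neck, post_neck), "%", "ramus")
        for region, (v_pre, v_post) in _quadrant_volumes(
            pre_head, post_head, planes.pole_plane, planes.mid_plane
        ).items():
            change = 100.0 * (v_post - v_pre) / v_pre if v_pre > 0 else float("nan")
            report.add(side, "head", region, "volumetric_change", change, "%", "ramus")

        cond_map = distance_map(pre_condyle, post_condyle)
        labels = label_by_planes(pre_condyle, planes.pole_plane, planes.mid_plane)
        head_mask = planes.head_neck_plane.signed_distance(pre_condyle.vertices) >= 0
        for structure, mask in (
            ("condyle", np.ones(len(pre_condyle.vertices), dtype=bool)),
            ("head", head_mask),
            ("neck", ~head_mask),
        ):
            vals = cond_map.values[mask]
            report.add(side, structure, WHOLE, "mean_abs_distance",
                       float(np.mean(np.abs(vals))) if mask.any() else float("nan"),
                       "mm", "ramus")
            report.add(side, structure, WHOLE, "mean_signed_distance",
                       float(np.mean(vals)) if mask.any() else float("nan"),
                       "mm", "ramus")
        for region in REGIONS:
            mask = head_mask & (labels == region)
            vals = cond_map.values[mask]
            report.add(side, "head", region, "mean_abs_distance",
                       float(np.mean(np.abs(vals))) if mask.any() else float("nan"),
                       "mm", "ramus")
            report.add(side, "head", region, "mean_signed_distance",
                       float(np.mean(vals)) if mask.any() else float("nan"),
                       "mm", "ramus")
            report.add(side, "head", region, "peak_abs_distance",
                       float(np.max(np.abs(vals))) if mask.any() else float("nan"),
                       "mm", "ramus")

        # ---- stage 6: joint space (cranial frame) ----------------------
        stage = "joint-space analysis"
        pre_condyle_c, _, _ = isolate_condyle(inputs.pre_ramus, planes)
        post_ramus_c = apply_transform(inputs.post_ramus, t_vbr, frame="cranial")
        post_condyle_c, _, _ = isolate_condyle(post_ramus_c, planes)
        pre_condyle_c.labels = label_by_planes(
            pre_condyle_c, planes.pole_plane, planes.mid_plane
        )
        post_condyle_c.labels = label_by_planes(
            post_condyle_c, planes.pole_plane, planes.mid_plane
        )
        for region in (WHOLE,) + REGIONS:
            js_pre = min_joint_space(pre_condyle_c, pre_patch, region, joint_pairing)
            js_post = min_joint_space(post_condyle_c, post_patch, region, joint_pairing)
            report.add(side, "joint_space", region, "pre", js_pre, "mm", "cranial")
            report.add(side, "joint_space", region, "post", js_post, "mm", "cranial")
            report.add(side, "joint_space", region, "change",
                       joint_space_change(js_pre, js_post), "mm", "cranial")

        if out_dir is not None:
            stage = "artifact export"
            _export_case(
                out_dir, side, report, t_sbr, t_vbr, cond_map, fossa_map, diagnostics
            )
    except Exception as exc:
        raise RuntimeError(f"assessment aborted at stage '{stage}': {exc}") from exc

    return CaseResult(report, t_sbr, t_vbr, fine.residual, diagnostics)


def _quadrant_volumes(pre_head, post_head, pole_plane, mid_plane):
    """Closed quadrant solids of the head and their pre/post volumes."""
    out = {}
    for region, (s_ap, s_lm) in {
        REGIONS[0]: ("positive", "positive"),
        REGIONS[1]: ("positive", "negative"),
        REGIONS[2]: ("negative", "positive"),
        REGIONS[3]: ("negative", "negative"),
    }.items():
        vols = []
        for mesh in (pre_head, post_head):
            part = clip_by_plane(mesh, pole_plane, s_ap, cap=True)
            part = clip_by_plane(part, mid_plane, s_lm, cap=True)
            vols.append(mesh_volume(part) if not part.is_empty() else 0.0)
        out[region] = tuple(vols)
    return out


def _export_case(out_dir, side, report, t_sbr, t_vbr, cond_map, fossa_map, diagnostics):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / f"report_{side}.csv")
    report.to_json(out / f"report_{side}.json")
    (out / "transforms").mkdir(exist_ok=True)
    t_sbr.to_json(out / "transforms" / f"sbr_{side}.json")
    t_vbr.to_json(out / "transforms" / f"vbr_{side}.json")
    scale = max(0.5, float(np.percentile(np.abs(cond_map.values), 99)))
    export_colormap(cond_map, (-scale, scale), out / f"condyle_distance_{side}.ply")
    scale = max(0.5, float(np.percentile(np.abs(fossa_map.values), 99)))
    export_colormap(fossa_map, (-scale, scale), out / f"fossa_distance_{side}.ply")
    (out / f"log_{side}.json").write_text(json.dumps(diagnostics, indent=1, default=str))
    trace = diagnostics.get("sbr_trace_mm", {})
    with open(out / f"sbr_trace_{side}.csv", "w") as fh:
        fh.write("pass,iteration,trimmed_rms_mm\n")
        for name, values in trace.items():
            for i, v in enumerate(values):
                fh.write(f"{name},{i},{v:.9f}\n")


# ---------------------------------------------------------------------------
# Reliability study
# ---------------------------------------------------------------------------


def run_reliability(
    obs1_inputs: list, obs2_inputs: list, out_dir=None, **assess_kwargs
):
    """Assess each joint for both observers and tabulate the agreement.

    ``obs*_inputs`` are matched lists of :class:`CaseInputs` (or
    :class:`CaseConfig`); observers typically share scans but differ in
    landmarks and traced curves.  Returns the reliability table
    (one row per metric x structure x region) as a DataFrame.
    """
    from .reliability_stats import bland_altman_plot, reliability_study

    if len(obs1_inputs) != len(obs2_inputs):
        raise ValueError("observer case lists must be matched")
    if len(obs1_inputs) < 2:
        raise ValueError("a reliability study needs at least 2 joints (ICC undefined)")
    reports1, reports2 = [], []
    cache: dict = {}  # observers share scans; reuse their deterministic registrations
    for i, (c1, c2) in enumerate(zip(obs1_inputs, obs2_inputs)):
        logger.info("reliability study: joint %d / %d", i + 1, len(obs1_inputs))
        for obs, cases, reports in (("obs1", c1, reports1), ("obs2", c2, reports2)):
            if isinstance(cases, CaseConfig):
                result = assess_case(cases)
            else:
                result = assess_case_inputs(
                    cases, registration_cache=cache, **assess_kwargs
                )
            reports.append(result.report)
        cache.clear()  # scans differ between joints; keep memory bounded
    table = reliability_study(reports1, reports2)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "reliability.csv", index=False)
        df1 = _concat_values(reports1)
        df2 = _concat_values(reports2)
        for metric in ("volumetric_change", "mean_abs_distance", "rms_distance", "change"):
            x = df1[df1.metric == metric].value.to_numpy()
            y = df2[df2.metric == metric].value.to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 3:
                bland_altman_plot(
                    x[ok], y[ok], metric, out / f"bland_altman_{metric}.png"
                )
    return table, reports1, reports2


def _concat_values(reports):
    import pandas as pd

    return pd.concat([r.to_frame() for r in reports], ignore_index=True)


# ---------------------------------------------------------------------------
# Phantom-based study generation (used by the CLI and the validation suite)
# ---------------------------------------------------------------------------


def phantom_case_inputs(
    case, spacing: float | None = None, landmark_jitter_sd: float = 0.0,
    curve_jitter_sd: float = 0.0, rng: np.random.Generator | None = None,
    volumes=None,
) -> CaseInputs:
    """Package a :class:`~tmj3d.phantom.PhantomCase` as pipeline inputs.

    ``landmark_jitter_sd`` / ``curve_jitter_sd`` emulate observer variation
    in the manual steps (landmarking and curve tracing).  Pre-rasterized
    ``volumes`` may be passed so two observers share the same scans.
    """
    from .phantom import pseudo_ct_pair

    if volumes is None:
        volumes = pseudo_ct_pair(case, spacing)
    pre_vol, post_vol, mask_vol = volumes
    lm = case.landmarks
    curve = case.fossa_curve
    if landmark_jitter_sd > 0 or curve_jitter_sd > 0:
        rng = rng or np.random.default_rng(0)
        lm = lm.jittered(landmark_jitter_sd, rng)
        curve = curve + rng.normal(0.0, curve_jitter_sd, curve.shape)
    return CaseInputs(
        pre_ramus=case.pre_ramus.copy(frame="cranial"),
        post_ramus=case.post_ramus.copy(frame="post-scan"),
        pre_skull=case.pre_skull.copy(frame="cranial"),
        post_skull=case.post_skull.copy(frame="post-scan"),
        pre_volume=pre_vol,
        post_volume=post_vol,
        mask_volume=mask_vol,
        landmarks=lm,
        fossa_curve=curve,
        fossa_seed_point=case.fossa_seed_point,
    )


def make_reliability_phantoms(n_joints: int, seed: int):
    """A varied population of phantom joints for a two-observer study.

    Every reported cell receives genuine between-subject variance: condylar
    remodeling depths vary per region and subject, the neck and fossa
    remodel too, and the condylar positional shift varies in all three
    axes.
    """
    from .phantom import PhantomSpec, RemodelingSite, make_tmj_phantom

    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_joints):
        a = rng.uniform(9.0, 11.0)
        b = rng.uniform(4.5, 5.5)
        c = rng.uniform(5.5, 6.5)
        sites = [
            RemodelingSite(r, rng.uniform(0.15, 0.8), rng.uniform(2.0, 3.0))
            for r in REGIONS
        ]
        sites.append(
            RemodelingSite(
                "neck", rng.uniform(0.1, 0.5), 2.5,
                center=(0.0, -0.9 * b, -8.0),
            )
        )
        fossa_sites = [
            RemodelingSite(r, rng.uniform(0.05, 0.4), rng.uniform(2.0, 3.0))
            for r in REGIONS
        ]
        spec = PhantomSpec(
            condyle_semiaxes=(a, b, c),
            fossa_gap=rng.uniform(2.5, 3.5),
            remodeling_sites=sites,
            fossa_remodeling_sites=fossa_sites,
            condylar_shift=tuple(rng.uniform(-0.4, 0.4, 2)) + (rng.uniform(0.0, 0.5),),
            mandible_rotation_deg=rng.uniform(-4.0, 4.0),
            mandible_translation=tuple(rng.uniform(-2.0, 2.0, 3)),
            cranial_rotation_deg=rng.uniform(-4.0, 4.0),
            cranial_translation=tuple(rng.uniform(-2.0, 2.0, 3)),
            voxel_spacing=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases.append(make_tmj_phantom(spec))
    return cases
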