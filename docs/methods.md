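# Methods

This note documents the models, conventions, numerical choices and known
limitations of `tmj3d`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## The measurement model

The assessment treats a TMJ as three coupled but separately measured
processes between a pre-operative scan and a (typically two-year)
post-operative scan:

* **Condylar remodeling** is measured in the *ramus frame*: the
  post-operative ramus is rigidly aligned to the pre-operative ramus on the
  bone below the condyle, which is assumed stable; any residual surface
  discrepancy above the C-plane is then attributed to remodeling. Metrics:
  volumetric change `100·(V_post − V_pre)/V_pre` of condyle, head, neck and
  the four head sub-regions (closed quadrant solids cut by the two
  sub-region planes), and mean surface distances.
* **Fossa remodeling** is measured in the *cranial frame*: the post scan is
  aligned to the pre scan on the anterior cranial base (assumed unaffected
  by surgery), and the fossa patch — delimited by a traced curve snapped to
  the skull — is compared pre vs post by RMS signed surface distance.
* **Positional change** is the change of the minimum osseous distance
  between condyle and fossa per sub-region, also in the cranial frame, where
  the condyle's post-operative position relative to the cranium is
  physically meaningful.

Frames are enforced mechanically: every mesh carries a frame tag and every
two-mesh metric raises on a tag mismatch, so a condylar metric cannot
accidentally be computed across the cranial alignment or vice versa.

### Sign and tie conventions

* Signed surface distance at a pre-operative vertex: unsigned nearest
  distance to the post surface, signed by `outward_normal · (closest − v)`.
  Positive = apposition, negative = resorption. The convention is printed in
  every report header.
* "Mean surface distance" in the headline tables is the mean *absolute*
  distance; the signed mean is reported alongside. Pure sign conventions
  cancel in a signed mean and would understate remodeling.
* On-plane vertices belong to the anterior / lateral (positive) side of a
  cutting plane. This is an arbitrary but deterministic tie rule.
* Anatomical directions are defined by landmarks only (lateral pole →
  lateral positive side; anterior reference → anterior positive side), never
  by world axes, so left/right joints and arbitrarily oriented scans behave
  identically. The Frankfurt normal is oriented superiorly using the
  right-handed relation (anterior × subject-left = superior).

## Registration

**SBR** is trimmed point-to-plane ICP: exact nearest-point correspondences
on the fixed surface, a 10 mm correspondence cutoff, the worst 10% of
correspondences discarded each iteration, and the linearized point-to-plane
update with a closed-form point-to-point (Kabsch) fallback whenever the
linearized step would increase the trimmed RMS — so the residual trace is
non-increasing by construction and the procedure is deterministic (stride
subsampling to ≤ 4000 points, no randomness). Convergence: RMS improvement
below 1e-5 mm, at most 200 iterations. The pipeline runs a coarse
whole-ramus pass (centroid initialization) followed by a refined pass on the
reference region below the C-plane, mirroring validated ramus-superimposition
protocols in which the remodeling condyle is excluded from the fit.

**VBR** uses SimpleITK's rigid (Euler) registration with a fixed-image mask
over the stable cranial anatomy, multi-resolution (shrink 4/2/1), dense
metric sampling (deterministic), a geometry-centered initializer, and
regular-step gradient descent. The default similarity is normalized
correlation: pre/post CBCT pairs are same-modality, and in phantom trials
masked correlation converged to ~0.1 voxel while Mattes mutual information
(kept available via `metric="mi"`) occasionally stalled on a metric shoulder.
The registration `residual` field stores the magnitude of the final
similarity objective, not millimetres.

## Geometry primitives

* Nearest-surface queries are exact: a KD-tree over triangle centroids
  prunes candidates with the bound `d(q, tri) ≥ |q − centroid| − circumradius`
  (nearest-vertex distance as upper bound), and survivors are resolved with
  the vectorized point-to-triangle projection. Property tests check
  bit-level agreement with a brute-force scan over all faces. Oversized
  triangles (circumradius > 4× median) are always checked, keeping the bound
  tight on mixed-resolution meshes.
* Plane clipping re-triangulates crossing faces at the plane and, with
  `cap=True`, ear-clips the planar boundary loops so closed inputs stay
  closed. Because caps are exact planar triangulations, the two capped
  halves of a closed mesh sum to the whole volume to ~1e-12 relative,
  and head + neck volumes add to the condyle volume by construction.
  Ear clipping assumes simple (non-self-intersecting, hole-free) section
  loops, which anatomical cross-sections satisfy.
* Volumes use the divergence theorem on closed, outward-oriented meshes; an
  open mesh is a hard error (reporting the boundary-edge count) rather than
  a silent best-effort number, because volumetric change is a headline
  metric. An inward orientation is auto-corrected with a warning.
* Curve attachment snaps traced points to nearest surface vertices and joins
  them by discrete Dijkstra shortest paths along mesh edges — deterministic
  and sufficient at sub-millimetre CBCT mesh resolution; exact geodesics are
  not needed. Accidental sub-cycles are excised so the loop stays simple.
* Fossa patch extraction removes the loop's edges from the face-adjacency
  graph and keeps the connected component nearest a seed point; a loop that
  fails to separate the surface is an error.
* The segmentation stand-in `volume_to_mesh` is marching cubes at a global
  threshold plus largest-connected-component selection. Interactive
  commercial segmentation protocols are out of scope; the threshold is a
  required, reported parameter.

## Reliability statistics

ICC(1,1) comes from the one-way ANOVA mean squares; its 95% CI is the exact
F-quantile interval (lower/upper pivots `F/F_{1−α/2}(n−1, n(k−1))` and
`F·F_{1−α/2}(n(k−1), n−1)`). Negative estimates are reported, not truncated.
"MAD (SD)" is the mean absolute difference between observers and the sample
SD *of the absolute differences* (configurable to signed differences).
Bland-Altman limits are bias ± 1.96·sd of signed differences. Cicchetti
bands: poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent, with
"reliable" meaning good or excellent (> 0.60). The sample-size routine is
the Fisher-z one-sample correlation formula
`n = ceil(((z_{1−α/2} + z_{power}) / atanh(ρ))² + 3)` (floored at 4), which
yields n = 20 fossae at ρ = 0.6, α = 0.05, power 0.8 — this is the
convention consistent with that printed figure; other sample-size
conventions do not reproduce it.

The reliability table defaults to the clinical-table metric set (volumetric
change, mean absolute surface distance, fossa RMS distance, joint-space
change). Diagnostic metrics recorded per case (e.g. the per-region *peak*
distance, a max statistic used for depth-recovery checks) can be tabulated
by passing `metrics=None`, but are not part of the headline agreement report.

## The phantom

The phantom trades anatomical realism for analytic ground truth:

* condylar head: an ellipsoid with semi-axes 10 × 5 × 6 mm (lateral ×
  anterior × superior — condylar dimensions in the adult range), its poles
  exactly at (±a, 0, 0) and guaranteed to be mesh vertices; the head blends
  into a neck/ramus shaft (45 mm) forming one closed parametric surface.
* glenoid fossa: the constant-distance offset surface of the head at gap
  g (default 3 mm, a normal joint space), thickened to a 2 mm shell. Because
  an offset of a convex surface is exactly g away everywhere, the true
  minimum joint space is g in every sub-region.
* cranial base: a slab with three asymmetric blocks, pre-tilted 8° about a
  generic axis. The tilt matters: an axis-aligned slab rasterizes with
  voxel-quantized edges and biases intensity registration by up to half a
  voxel whenever the post pose includes rotation; a generic pose
  staircase-averages instead, and VBR recovery is ~0.1 voxel.
* remodeling: Gaussian dimples along outward normals — peak displacement
  equals the stated depth (σ = the stated radius); sites can be placed on
  head sub-regions, the neck, or the fossa.
* posing: post anatomy = remodel → condylar shift + segment motion relative
  to the cranium → one shared scanner pose. VBR must undo the scanner pose;
  SBR the scanner pose composed with the segment motion.
* pseudo-CT: voxel-center parity rasterization (exact for closed meshes,
  with a sub-voxel origin jitter so rays avoid edge degeneracies), bone
  1200 / air 0, Gaussian PSF of 1 voxel, additive noise σ = 10. Default
  spacing is 0.75 mm for tests (0.3 mm isotropic, matching CBCT, is
  supported and used in the rasterization accuracy tests; the coarser grids
  keep registration test times in seconds).
* observer simulation: isotropic Gaussian jitter of landmarks and traced
  curve points (σ = 0.3 mm, a realistic landmarking precision) models the
  manual steps; scans and meshes are shared between observers, as in a real
  re-measurement study. Rating tables with known true ICC are generated from
  the two-level normal model (between-subject SD, rater-error SD).

What the phantom does *not* model: anatomical shape variation (no statistical
shape model), CBCT physics (beam hardening, scatter, metal artifacts),
segmentation error (meshes are exact), soft tissue, and non-rigid change.
Passing phantom tests therefore demonstrates the correctness and internal
consistency of the measurement chain — registration, partitioning,
quantification, statistics — not robustness to segmentation quality or
imaging artifacts on clinical data.

## Study-scale choices

The validation suite and `scripts/acceptance.py` use: 20 joints in the
reliability study (matching the sample-size calculation), two observers with
0.3 mm jitter, phantom populations with per-region remodeling depths varied
in 0.15–0.8 mm, fossa remodeling 0.05–0.4 mm, condylar shifts up to 0.5 mm,
scanner poses up to ±4°/2 mm, and 1.0 mm voxels for the study's pseudo-CT
(0.75 mm elsewhere); ICC calibration uses 500–1000 simulated tables at n=20,
k=2. These sizes make the full suite run in minutes on one CPU while leaving
every recovery margin comfortably clear of its tolerance. Within a
reliability study the two observers share the same scans, and the automatic
registration steps are deterministic functions of those scans, so their
results are computed once per joint and reused for both observers (the
manual, jittered steps — landmarks and curve tracing — are always
re-assessed per observer).

## Known limitations

* The head/neck divider is not anatomically standardized; the default —
  midway between the C-point and the superior-most condylar vertex, parallel
  to Frankfurt — is deterministic but an assumption, and is overridable.
* Pre-operative cutting planes are reused for the post-operative anatomy
  after alignment, so sub-regions correspond across time; genuine pole
  migration would shift the partition.
* The minimum joint space pairs condylar regions with same-region fossa
  faces by default (`pairing="whole"` measures against the entire fossa);
  regional attribution is cleaner, but values near region boundaries can
  differ between the two pairings.
* ICP assumes the initial pose is within the basin of the centroid + coarse
  pass; grossly wrong initial orientations (> ~45°) are not handled.
* NIfTI support is limited to axis-aligned (diagonal-affine) volumes; DICOM
  series assembly and non-rigid registration are out of scope.
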