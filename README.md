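# tmj3d — holistic 3D assessment of the temporomandibular joint

`tmj3d` quantifies how the temporomandibular joint (TMJ) changes after
orthognathic surgery, from pre- and post-operative 3D reconstructions
(CBCT-derived meshes and volumes). It measures, per joint, the three adaptive
processes that together determine the final mandibular position:

1. **condylar remodeling** — volumetric change (%) and mean surface distance
   (mm) of the condyle, its head and neck, and four head sub-regions;
2. **glenoid fossa remodeling** — RMS surface distance (mm) of the fossa and
   its four sub-regions;
3. **condylar positional change** — the pre-to-post change of the minimum
   joint-space distance (mm) per sub-region.

It is aimed at craniofacial imaging researchers who need reproducible,
scriptable TMJ morphometry, and it ships a two-observer reliability toolkit
(ICC, MAD/SD, Bland-Altman) for validating the semi-automatic steps.

## Method

Two rigid alignment frames are maintained and never mixed:

* **SBR (surface-based registration)** — trimmed point-to-plane ICP aligns
  the post-operative ramus to the pre-operative ramus on the stable region
  below the condyle; condylar metrics are computed in this frame.
* **VBR (voxel-based registration)** — masked rigid intensity registration
  aligns the post-operative scan to the pre-operative scan on the anterior
  cranial base; fossa and joint-space metrics are computed in this frame.

Anatomy is partitioned by landmark-defined planes: the Frankfurt horizontal
(porion right/left + orbitale), the **C-plane** through the deepest point of
the mandibular notch (isolates the condyle from the ramus), a **pole plane**
through the lateral and medial condylar poles perpendicular to Frankfurt
(anterior/posterior divider), and an orthogonal **mid-plane** through the
pole midpoint (lateral/medial divider). The glenoid fossa is delimited by a
traced curve snapped to the skull surface and partitioned by the same two
cutting planes, so condyle and fossa sub-regions correspond.

Surface change is encoded as signed distance maps on the pre-operative
surface: sign = outward-normal · (closest post-operative point − vertex), so
apposition is positive and resorption negative. Reliability uses the
one-way random-effects single-measure intraclass correlation ICC(1,1) =
(MSB − MSW) / (MSB + (k−1)·MSW) with its exact F confidence interval, MAD
(SD) of paired observer differences, Bland-Altman limits of agreement
(bias ± 1.96 sd), Cicchetti interpretation bands (reliable when ICC > 0.60),
and the Fisher-z one-sample correlation sample-size formula.

A synthetic phantom module generates complete TMJ cases (condyle + ramus,
offset fossa shell, cranial base, pseudo-CT volumes, landmarks, traced
curves) with analytic ground truth for every metric, and drives the test
suite and reliability studies.

## Worked example

Generate a phantom joint with a 0.5 mm anterior-lateral resorption dimple, a
0.4 mm superior condylar shift, and a post-scan pose change, then assess it:

```python
from tmj3d import PhantomSpec, make_tmj_phantom
from tmj3d.phantom import RemodelingSite
from tmj3d.workflow import assess_case_inputs, phantom_case_inputs

spec = PhantomSpec(
    remodeling_sites=[RemodelingSite("anterior-lateral", 0.5, 2.5)],
    condylar_shift=(0.0, 0.0, 0.4),
    cranial_rotation_deg=5.0, cranial_translation=(2.0, -1.0, 3.0),
    seed=7,
)
case = make_tmj_phantom(spec)
result = assess_case_inputs(phantom_case_inputs(case))
rep = result.report
print(f"condylar volumetric change: {rep.value('condyle','whole','volumetric_change'):+.2f} %")
print(f"anterior-lateral peak depth: {rep.value('head','anterior-lateral','peak_abs_distance'):.3f} mm")
print(f"fossa RMS distance:          {rep.value('fossa','whole','rms_distance'):.3f} mm")
print(f"joint-space change:          {rep.value('joint_space','whole','change'):+.3f} mm")
```

Output:

```
condylar volumetric change: -1.02 %
anterior-lateral peak depth: 0.484 mm
fossa RMS distance:          0.005 mm
joint-space change:          -0.421 mm
```

The carved dimple removes ~1% of condylar volume and is recovered at its
imposed 0.5 mm depth in the correct sub-region; the fossa (unchanged in this
phantom) reads near zero after VBR; the 0.4 mm superior shift appears as a
−0.4 mm joint-space change.

The same pipeline is available from the shell:

```bash
tmj phantom --out case_dir          # synthetic case + ground truth + config
tmj assess --config case_dir/case.yaml
tmj reliability --out study_dir --n-joints 20 --jitter-sd 0.3
```

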