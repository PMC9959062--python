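"""Shared fixtures: analytic meshes and phantom cases.

Heavy objects (phantom cases, assessed pipelines) are session-scoped and
treated as read-only by the tests that share them.
"""

import numpy as np
import pytest
import trimesh

from tmj3d.core_geometry import SurfaceMesh
from tmj3d.phantom import PhantomSpec, RemodelingSite, make_tmj_phantom


@pytest.fixture(scope="session")
def sphere10():
    """Icosphere radius 10 mm, 4 subdivisions (volume within 1% of analytic)."""
    ico = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return SurfaceMesh(ico.vertices, ico.faces)


@pytest.fixture(scope="session")
def sphere5_coarse():
    ico = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    return SurfaceMesh(ico.vertices, ico.faces)


@pytest.fixture(scope="session")
def unit_cube():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(box.vertices, box.faces)


@pytest.fixture(scope="session")
def default_case():
    """Plain phantom: no remodeling, no motion, no pose change."""
    return make_tmj_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def remodeled_case():
    """Phantom with one 0.5 mm anterior-lateral dimple, a 0.4 mm superior
    condylar shift, and non-trivial scanner poses for both frames."""
    spec = PhantomSpec(
        remodeling_sites=[RemodelingSite("anterior-lateral", 0.5, 2.5)],
        condylar_shift=(0.0, 0.0, 0.4),
        mandible_rotation_deg=0.0,
        cranial_rotation_deg=5.0,
        cranial_translation=(2.0, -1.0, 3.0),
        seed=7,
    )
    return make_tmj_phantom(spec)


@pytest.fixture(scope="session")
def assessed_remodeled(remodeled_case):
    """Full pipeline result on the remodeled phantom (shared, read-only)."""
    from tmj3d.workflow import assess_case_inputs, phantom_case_inputs

    return assess_case_inputs(phantom_case_inputs(remodeled_case))
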