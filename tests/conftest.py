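from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from jawstrain.fe import recover_strains, solve_static
from jawstrain.loads import build_chewing_case
from jawstrain.materials import CalibrationModel, assign_cortical, make_variant
from jawstrain.pipeline import quantity_fields
from jawstrain.synth import PhantomSpec, default_muscles, make_grayscale, make_phantom

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A minimal valid phantom: one tooth per side, coarse but PDL-conforming."""
    return PhantomSpec(
        corpus_length=45.0, corpus_height=10.0, corpus_width=11.25,
        arch_radius=13.0, n_sockets_per_side=1, socket_width=1.25,
        socket_depth=2.5, pdl_thickness=3, edge_length=1.25,
        post_height=5.0, seed=0,
    )


@pytest.fixture(scope="session")
def small_mesh(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def small_solution(small_spec, small_mesh):
    """PDL-variant solve on the small phantom, shared across tests."""
    gv = make_grayscale(small_mesh, seed=small_spec.seed)
    cortical = assign_cortical(small_mesh, gv, CalibrationModel())
    load = build_chewing_case(small_mesh, default_muscles(small_spec))
    mat = make_variant(small_mesh, cortical, "PDL")
    disp, info = solve_static(small_mesh, mat, load)
    strains = recover_strains(small_mesh, disp)
    return {"disp": disp, "info": info, "strains": strains, "load": load}


@pytest.fixture(scope="session")
def phantom_study():
    """The full sensitivity study on the default phantom: all PDL-stiffness
    variants solved under the chewing scenario (the expensive shared fixture)."""
    spec = PhantomSpec()
    mesh = make_phantom(spec)
    gv = make_grayscale(mesh, seed=spec.seed)
    cortical = assign_cortical(mesh, gv, CalibrationModel())
    load = build_chewing_case(mesh, default_muscles(spec))
    fields, infos = {}, {}
    for variant in ("MODEL_1", "MODEL_2", "MODEL_3", "MODEL_4", "PDL", "NO_PDL"):
        mat = make_variant(mesh, cortical, variant)
        disp, info = solve_static(mesh, mat, load)
        fields[variant] = quantity_fields(recover_strains(mesh, disp))
        infos[variant] = info
    return {"spec": spec, "mesh": mesh, "fields": fields, "infos": infos}


@pytest.fixture()
def tiny_spec(small_spec) -> PhantomSpec:
    """Alias kept distinct so pipeline tests can shrink further if needed."""
    return dataclasses.replace(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
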