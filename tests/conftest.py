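"""Shared fixtures: expensive geometry products are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from noseforge import design as dz
from noseforge import shape_model as sm
from noseforge import synthetic as syn
from noseforge.mesh_core import LandmarkSet
from noseforge.primitives import open_hemisphere, plane_patch


@pytest.fixture(scope="session")
def toy_design():
    """Hemisphere-on-plane toy case run through the full design protocol."""
    params = dz.DesignParams()
    nm = open_hemisphere(20.0, n_theta=64, n_rings=32)
    fm = plane_patch(90.0, 45)
    nm_blend = dz.blend_border(nm, fm, params)
    pm = dz.build_prosthesis_solid(nm_blend, fm, params)
    mold = dz.generate_mold(pm, params)
    return {
        "params": params,
        "nm": nm,
        "fm": fm,
        "nm_blend": nm_blend,
        "pm": pm,
        "mold": mold,
        "radius": 20.0,
    }


@pytest.fixture(scope="session")
def population():
    return syn.generate_population(40, seed=42)


@pytest.fixture(scope="session")
def face_model(population):
    model = sm.build_model(population)
    model.landmarks = syn.landmark_vertex_ids()
    model.nose_vertex_ids = syn.prosthesis_crop_region().indices
    return model


@pytest.fixture(scope="session")
def augmented_model(face_model):
    return sm.augment_model(face_model, sm.SmoothDeformationKernel())


@pytest.fixture(scope="session")
def model_landmarks(face_model):
    return LandmarkSet(face_model.landmark_points())


@pytest.fixture(scope="session")
def default_case():
    """The default synthetic fixture: mean-parameter face + rhinectomy."""
    face, mask, lms = syn.generate_face(syn.FaceParams())
    fm = syn.simulate_rhinectomy(face, mask, margin=5.0, noise_sd=0.1, seed=0)
    return {"face": face, "mask": mask, "landmarks": lms, "fm": fm}
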