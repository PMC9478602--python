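"""Shared fixtures: one default phantom pipeline, built once per session."""

import numpy as np
import pytest

import bolusqa as bq
from bolusqa import bolus as bolus_mod


@pytest.fixture(scope="session")
def phantom_default():
    ct, masks = bq.make_chest_phantom()
    return ct, masks


@pytest.fixture(scope="session")
def body_and_skin(phantom_default):
    ct, _ = phantom_default
    return bq.extract_body_surface(ct)


@pytest.fixture(scope="session")
def area_mark():
    return bq.AreaMark()


@pytest.fixture(scope="session")
def bolus_design(body_and_skin, area_mark):
    body, _ = body_and_skin
    return bq.design_bolus(body, bq.BolusSpec(thickness=5.0, area_mark=area_mark))


@pytest.fixture(scope="session")
def dose_with_bolus(phantom_default, bolus_design):
    ct, masks = phantom_default
    bolus_mask, _ = bolus_design
    return bq.make_dose_grid(
        ct, masks, bq.BeamSpec(), bolus_mask=bolus_mask, normalization="d95"
    )


@pytest.fixture(scope="session")
def dose_without_bolus(phantom_default):
    ct, masks = phantom_default
    return bq.make_dose_grid(ct, masks, bq.BeamSpec(), normalization="d95")


@pytest.fixture(scope="session")
def small_spec():
    """A coarse phantom small enough for exhaustive (brute-force) oracles."""
    return bq.PhantomSpec(
        chest_half_axes=(40.0, 30.0),
        axial_length=36.0,
        wall_thickness=10.0,
        ptv_margin=5.0,
        voxel_spacing=(6.0, 6.0, 6.0),
    )


def skin_sample_with_normals(skin_mesh, mark, n, seed=0):
    """Marked-area skin points plus outward normals (shared by film tests)."""
    pts = bolus_mod.sample_skin_points(skin_mesh, n, area_mark=mark, seed=seed)
    normals = bolus_mod._outward_normals(skin_mesh.to_trimesh(), pts)
    return pts, normals
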