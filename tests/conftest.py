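"""Shared fixtures: phantoms and their measurement runs.

Heavy geometry (the composite knee phantom, the spherical shell) is built
once per session; individual tests slice what they need.
"""
from __future__ import annotations

import numpy as np
import pytest

from cartithick.phantoms import KneePhantomSpec, make_knee_phantom, make_shell_phantom, make_slab_phantom
from cartithick.regions import SubregionLabeling, parcellate_knee
from cartithick.surfaces import extract_surfaces_femur, extract_surfaces_tibia
from cartithick.volume_io import (
    FEMORAL_CARTILAGE,
    TIBIAL_CARTILAGE,
    extract_structure_points,
)


def trivial_labeling(points, structure: str, subregion: str) -> SubregionLabeling:
    """Labeling that puts a whole structure into one subregion."""
    n = len(points)
    return SubregionLabeling(
        indices=points.indices,
        spacing=points.spacing,
        subregion=np.full(n, subregion),
        structure=np.full(n, structure),
    )


@pytest.fixture(scope="session")
def knee_phantom():
    return make_knee_phantom()


@pytest.fixture(scope="session")
def knee_labeling(knee_phantom):
    return parcellate_knee(knee_phantom.volume)


@pytest.fixture(scope="session")
def knee_points(knee_phantom):
    vol = knee_phantom.volume
    return (
        extract_structure_points(vol, TIBIAL_CARTILAGE),
        extract_structure_points(vol, FEMORAL_CARTILAGE),
    )


@pytest.fixture(scope="session")
def knee_surfaces(knee_points, knee_labeling):
    tibia, femur = knee_points
    sub, _ = knee_labeling.assign(femur.coords, structure="femur")
    post = np.isin(sub, ["pLF", "pMF"])
    return extract_surfaces_tibia(tibia), extract_surfaces_femur(femur, post)


@pytest.fixture(scope="session")
def slab_phantom():
    """20 x 20 mm flat plate, t = 2.0 mm, study spacing."""
    return make_slab_phantom(thickness=2.0, extent=(20.0, 20.0))


@pytest.fixture(scope="session")
def slab_points(slab_phantom):
    return extract_structure_points(slab_phantom.volume, TIBIAL_CARTILAGE)


@pytest.fixture(scope="session")
def slab_labeling(slab_points):
    return trivial_labeling(slab_points, "tibia", "cLT")


@pytest.fixture(scope="session")
def shell_phantom():
    """Spherical shell, R = 20 mm, t = 2.0 mm, 60-degree cap, study spacing."""
    return make_shell_phantom(radius=20.0, thickness=2.0, cap_deg=60.0)


@pytest.fixture(scope="session")
def shell_points(shell_phantom):
    return extract_structure_points(shell_phantom.volume, FEMORAL_CARTILAGE)


@pytest.fixture(scope="session")
def shell_labeling(shell_points):
    return trivial_labeling(shell_points, "femur", "ccLF")
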