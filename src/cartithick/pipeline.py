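"""End-to-end measurement pipeline for one segmented knee.

Wires parcellation, surface extraction and the selected thickness methods
into the standard workflow: parcellate -> extract surfaces/meshes -> measure
-> summarize.  This is what the CLI ``measure`` subcommand and the test
fixtures call.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .regions import SubregionLabeling, parcellate_knee
from .stats import summarize
from .surfaces import (
    SurfacePair,
    build_mesh,
    extract_surfaces_femur,
    extract_surfaces_tibia,
)
from .thickness import (
    METHODS,
    ThicknessMap,
    place_ray_spheres,
    thickness_centerline_2d,
    thickness_mesh_normals,
    thickness_nearest_neighbors,
    thickness_ray_tracing,
    thickness_surface_normals_2d,
)
from .volume_io import (
    FEMORAL_CARTILAGE,
    TIBIAL_CARTILAGE,
    LabelVolume,
    extract_structure_points,
)

log = logging.getLogger(__name__)

_POSTERIOR = ("pLF", "pMF")


def femur_posterior_mask(points, labeling: SubregionLabeling) -> np.ndarray:
    sub, _ = labeling.assign(points.coords, structure="femur")
    return np.isin(sub, _POSTERIOR)


def _mesh_pair(surfaces: SurfacePair):
    """Distal/proximal meshes per extraction frame (unrotated + rotated)."""
    pairs = []
    for rot in (False, True):
        dmask = surfaces.rotated_distal == rot
        pmask = surfaces.rotated_proximal == rot
        if dmask.sum() < 3 or pmask.sum() < 3:
            continue
        proj = "yz" if rot else "xy"
        from .volume_io import VoxelPointSet

        d = VoxelPointSet(surfaces.distal.indices[dmask], surfaces.distal.spacing)
        p = VoxelPointSet(surfaces.proximal.indices[pmask], surfaces.proximal.spacing)
        pairs.append((build_mesh(d, proj), build_mesh(p, proj)))
    return pairs


def measure_knee(
    vol: LabelVolume,
    methods: tuple[str, ...] = METHODS,
    knee_id: str = "knee",
    *,
    medial_side: str = "high-y",
    sphere_kwargs: dict | None = None,
) -> tuple[list[ThicknessMap], SubregionLabeling, pd.DataFrame]:
    """Measure one knee with the selected methods.

    Returns (thickness maps, the parcellation, the per-knee summary table).
    """
    bad = set(methods) - set(METHODS)
    if bad:
        raise ConfigurationError(f"unknown methods: {sorted(bad)}")
    if not methods:
        raise ConfigurationError("at least one method must be selected")

    labeling = parcellate_knee(vol, medial_side=medial_side)
    tibia = extract_structure_points(vol, TIBIAL_CARTILAGE)
    femur = extract_structure_points(vol, FEMORAL_CARTILAGE)
    tib_surf = extract_surfaces_tibia(tibia)
    fem_surf = extract_surfaces_femur(femur, femur_posterior_mask(femur, labeling))

    maps: list[ThicknessMap] = []

    def add(m: ThicknessMap):
        m.knee_id = knee_id
        maps.append(m)
        log.info(
            "%s %s: %d samples, counts=%s", m.method, m.structure, len(m), m.counts
        )

    if "3D-MN" in methods:
        for structure, surf in (("tibia", tib_surf), ("femur", fem_surf)):
            parts = _mesh_pair(surf)
            merged = None
            for dmesh, pmesh in parts:
                m = thickness_mesh_normals(dmesh, pmesh, labeling, structure)
                merged = m if merged is None else _concat_maps(merged, m)
            add(merged)
    if "3D-NN" in methods:
        add(thickness_nearest_neighbors(tib_surf, labeling))
        add(thickness_nearest_neighbors(fem_surf, labeling))
    if "3D-RT" in methods:
        config = place_ray_spheres(tibia, femur, labeling, fem_surf, **(sphere_kwargs or {}))
        add(thickness_ray_tracing(tibia, labeling, config, "tibia"))
        add(thickness_ray_tracing(femur, labeling, config, "femur"))
    if "2D-CN" in methods:
        add(thickness_centerline_2d(tibia, labeling, "tibia"))
        add(thickness_centerline_2d(femur, labeling, "femur"))
    if "2D-SN" in methods:
        add(thickness_surface_normals_2d(tibia, labeling, "tibia"))
        add(thickness_surface_normals_2d(femur, labeling, "femur"))

    summary = summarize(maps, knee_id=knee_id)
    return maps, labeling, summary


def _concat_maps(a: ThicknessMap, b: ThicknessMap) -> ThicknessMap:
    counts = dict(a.counts)
    for k, v in b.counts.items():
        counts[k] = counts.get(k, 0) + v
    return ThicknessMap(
        method=a.method,
        structure=a.structure,
        origins=np.vstack([a.origins, b.origins]),
        values=np.concatenate([a.values, b.values]),
        subregions=np.concatenate([a.subregions, b.subregions]),
        counts=counts,
        knee_id=a.knee_id,
    )
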