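"""3D nearest neighbors (3D-NN).

For every distal surface voxel, thickness is the Euclidean distance (in
physical units) to its exact nearest proximal surface voxel, found with a
KD-tree over all proximal surface voxels.  By construction this is the
minimum over the whole proximal surface, which makes 3D-NN the lower bound
among the normal-based estimates at matched origins.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..errors import MethodFailureError
from ..regions import SubregionLabeling
from ..surfaces import SurfacePair
from .base import MAX_PLAUSIBLE_THICKNESS_MM, ThicknessMap, apply_thickness_cap


def thickness_nearest_neighbors(
    surfaces: SurfacePair,
    labeling: SubregionLabeling,
    *,
    max_thickness: float = MAX_PLAUSIBLE_THICKNESS_MM,
) -> ThicknessMap:
    if len(surfaces.proximal) == 0 or len(surfaces.distal) == 0:
        raise MethodFailureError("3D-NN requires non-empty distal and proximal surfaces")
    counts: dict = {}
    origins = surfaces.distal.coords
    tree = cKDTree(surfaces.proximal.coords)
    values, _ = tree.query(origins)
    keep = apply_thickness_cap(values, counts, max_thickness)
    values, origins = values[keep], origins[keep]
    sub, n_un = labeling.assign(origins, structure=surfaces.structure)
    if n_un:
        counts["unassigned"] = n_un
    return ThicknessMap(
        method="3D-NN",
        structure=surfaces.structure,
        origins=origins,
        values=values,
        subregions=sub,
        counts=counts,
    )
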