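"""3D mesh normals (3D-MN).

Thickness at every distal mesh vertex is the length of the vertex-normal ray
from its origin on the distal mesh to its first intersection with the
proximal mesh.  Normals are area-weighted per-vertex normals of the Delaunay
height-field mesh, oriented distal -> proximal, so a single forward ray cast
suffices.  Individual measurements are unweighted (no mesh-element-area
weighting) and non-intersecting normals produce no sample but are counted.
"""
from __future__ import annotations

import numpy as np

from .._geometry import first_ray_mesh_hits
from ..errors import MethodFailureError
from ..regions import SubregionLabeling
from ..surfaces import TriangleMesh, vertex_normals
from .base import MAX_PLAUSIBLE_THICKNESS_MM, ThicknessMap, apply_thickness_cap


def thickness_mesh_normals(
    distal_mesh: TriangleMesh,
    proximal_mesh: TriangleMesh,
    labeling: SubregionLabeling,
    structure: str,
    *,
    max_thickness: float = MAX_PLAUSIBLE_THICKNESS_MM,
) -> ThicknessMap:
    counts: dict = {}
    normals, n_zero = vertex_normals(distal_mesh)
    if n_zero:
        counts["zero_normal"] = n_zero
    valid = np.linalg.norm(normals, axis=1) > 0.5
    origins = distal_mesh.vertices[valid]
    dirs = normals[valid]
    hits = first_ray_mesh_hits(
        origins, dirs, proximal_mesh.vertices, proximal_mesh.faces, max_thickness
    )
    ok = np.isfinite(hits)
    counts["no_intersection"] = int((~ok).sum())
    values = hits[ok]
    origins = origins[ok]
    keep = apply_thickness_cap(values, counts, max_thickness)
    values, origins = values[keep], origins[keep]
    if len(values) == 0:
        raise MethodFailureError("3D-MN produced zero intersections")
    sub, n_un = labeling.assign(origins, structure=structure)
    if n_un:
        counts["unassigned"] = n_un
    return ThicknessMap(
        method="3D-MN",
        structure=structure,
        origins=origins,
        values=values,
        subregions=sub,
        counts=counts,
    )
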