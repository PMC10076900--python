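"""Cartilage surface extraction and height-field meshing.

Surfaces are extracted column-wise on the voxel grid: for each occupied
(x, y) column, the voxel with the highest z is a distal-surface voxel and
the voxel with the lowest z a proximal-surface voxel.  Under the package's
axis convention (z head-to-feet) the distal surface is the cartilage-bone
interface for the tibia and the articular (cartilage-synovia) surface for
the femur — the standard naming where the roles of the two interfaces swap
between the bones.

Because vertical lines regularly pierce the curved posterior femoral
condyles twice, the posterior subregions are rotated 90 degrees about the
y-axis (an exact index swap of the x and z axes) before column-wise
extraction, and the surface voxels are mapped back afterwards.

Meshes are 2D Delaunay triangulations of a surface's projection, lifted to
3D — a single-valued height field over the projection plane, which makes
normal orientation a pure sign convention (distal -> proximal points against
the height axis, since distal is the max-height voxel of each column).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from ._geometry import column_runs
from .errors import EmptyStructureError, MeshError
from .volume_io import VoxelPointSet

#: projection plane -> (in-plane axes, height axis)
PROJECTIONS = {"xy": ((0, 1), 2), "yz": ((1, 2), 0)}


@dataclass(frozen=True)
class SurfacePair:
    """Distal and proximal surface voxel sets of one cartilage structure.

    ``rotated_distal`` / ``rotated_proximal`` flag the voxels that were
    extracted in the rotated (posterior-femur) frame; the indices themselves
    are always in the original frame.
    """

    distal: VoxelPointSet
    proximal: VoxelPointSet
    structure: str
    rotated_distal: np.ndarray = field(default=None)
    rotated_proximal: np.ndarray = field(default=None)
    skipped_columns: int = 0

    def __post_init__(self):
        for name in ("rotated_distal", "rotated_proximal"):
            flags = getattr(self, name)
            target = self.distal if name == "rotated_distal" else self.proximal
            if flags is None:
                object.__setattr__(self, name, np.zeros(len(target), dtype=bool))
            else:
                object.__setattr__(self, name, np.asarray(flags, dtype=bool))


@dataclass(frozen=True)
class TriangleMesh:
    """Triangulated height-field surface in physical (mm) coordinates."""

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray  # (m, 3) vertex indices
    projection: str = "xy"

    @property
    def height_axis(self) -> int:
        return PROJECTIONS[self.projection][1]


def _column_extremes(indices: np.ndarray, *, max_runs: int | None = None):
    """Per-(i, j) column min/max k rows; optionally skip many-run columns.

    Returns (distal_rows, proximal_rows, n_skipped) where distal = max k.
    """
    order = np.lexsort((indices[:, 2], indices[:, 1], indices[:, 0]))
    s = indices[order]
    new_col = np.empty(len(s), bool)
    new_col[0] = True
    new_col[1:] = (np.diff(s[:, 0]) != 0) | (np.diff(s[:, 1]) != 0)
    starts = np.flatnonzero(new_col)
    ends = np.r_[starts[1:], len(s)]
    distal, proximal = [], []
    skipped = 0
    for a, b in zip(starts, ends):
        ks = s[a:b, 2]
        if max_runs is not None and column_runs(ks) > max_runs:
            skipped += 1
            continue
        proximal.append(s[a])
        distal.append(s[b - 1])
    return np.asarray(distal), np.asarray(proximal), skipped


def extract_surfaces_tibia(points: VoxelPointSet) -> SurfacePair:
    """Tibial surfaces: per column, max-z voxel distal, min-z voxel proximal."""
    if len(points) == 0:
        raise EmptyStructureError("tibial point set is empty")
    distal, proximal, _ = _column_extremes(points.indices)
    return SurfacePair(
        distal=VoxelPointSet(distal, points.spacing),
        proximal=VoxelPointSet(proximal, points.spacing),
        structure="tibia",
    )


def rotate_posterior(indices: np.ndarray) -> np.ndarray:
    """90-degree rotation about y, realized as the exact (x, z) index swap.

    An involution on the grid: applying it twice restores the input.  For
    column-wise surface extraction the accompanying in-plane flip is
    irrelevant, so this is the cheapest exact form of the rotation.
    """
    return np.asarray(indices)[:, [2, 1, 0]]


def extract_surfaces_femur(points: VoxelPointSet, posterior_mask: np.ndarray) -> SurfacePair:
    """Femoral surfaces with posterior 90-degree rotation.

    Anterior + central voxels are processed column-wise like the tibia
    (distal = articular = max z per column).  Posterior voxels are rotated
    about y first, extracted column-wise in the rotated frame (distal = max
    along the rotated height axis = max x), and mapped back.  Columns that
    intersect the volume in more than two disjoint runs after rotation are
    skipped and counted.
    """
    if len(points) == 0:
        raise EmptyStructureError("femoral point set is empty")
    posterior_mask = np.asarray(posterior_mask, dtype=bool)
    if posterior_mask.shape != (len(points),):
        raise ValueError("posterior_mask must align with the point set")
    d_parts, p_parts, d_rot, p_rot = [], [], [], []
    skipped = 0
    ant = points.indices[~posterior_mask]
    if len(ant):
        d, p, sk = _column_extremes(ant, max_runs=2)
        skipped += sk
        if len(d):
            d_parts.append(d)
            p_parts.append(p)
            d_rot.append(np.zeros(len(d), bool))
            p_rot.append(np.zeros(len(p), bool))
    post = points.indices[posterior_mask]
    if len(post):
        d, p, sk = _column_extremes(rotate_posterior(post), max_runs=2)
        skipped += sk
        if len(d):
            d_parts.append(rotate_posterior(d))
            p_parts.append(rotate_posterior(p))
            d_rot.append(np.ones(len(d), bool))
            p_rot.append(np.ones(len(p), bool))
    if not d_parts:
        raise EmptyStructureError("femoral surface extraction yielded no columns")
    return SurfacePair(
        distal=VoxelPointSet(np.vstack(d_parts), points.spacing),
        proximal=VoxelPointSet(np.vstack(p_parts), points.spacing),
        structure="femur",
        rotated_distal=np.concatenate(d_rot),
        rotated_proximal=np.concatenate(p_rot),
        skipped_columns=skipped,
    )


def build_mesh(surface: VoxelPointSet, projection: str = "xy") -> TriangleMesh:
    """2D Delaunay triangulation of the projected surface, lifted to 3D."""
    if projection not in PROJECTIONS:
        raise ValueError(f"unknown projection {projection!r}")
    coords = surface.coords
    if len(coords) < 3:
        raise MeshError(f"need >= 3 surface points, got {len(coords)}")
    plane = coords[:, list(PROJECTIONS[projection][0])]
    try:
        tri = Delaunay(plane)
    except QhullError as exc:
        raise MeshError(f"Delaunay triangulation failed: {exc}") from exc
    if len(tri.simplices) == 0:
        raise MeshError("degenerate (collinear) surface points")
    return TriangleMesh(vertices=coords, faces=tri.simplices.copy(), projection=projection)


def vertex_normals(mesh: TriangleMesh, orientation: float = -1.0) -> tuple[np.ndarray, int]:
    """Area-weighted per-vertex unit normals, oriented distal -> proximal.

    Face normals (cross products, magnitude = 2x area, i.e. inherently
    area-weighted) are flipped so their component along the mesh's height
    axis has the sign of ``orientation``, then accumulated per vertex and
    normalized.  With the distal = max-height-per-column convention, the
    proximal surface always lies against the height axis, so the default
    orientation of -1 yields distal-to-proximal normals; pass +1 when the
    roles are swapped.  Returns (normals, n_zero) where vertices with a zero
    accumulated normal (isolated vertices) are counted and left as zero
    vectors for the caller to exclude.
    """
    v = mesh.vertices
    f = mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    h = mesh.height_axis
    flip = np.sign(fn[:, h]) != np.sign(orientation)
    fn[flip] *= -1.0
    acc = np.zeros_like(v)
    for c in range(3):
        np.add.at(acc, f[:, c], fn)
    norms = np.linalg.norm(acc, axis=1)
    zero = norms < 1e-12
    out = np.zeros_like(acc)
    out[~zero] = acc[~zero] / norms[~zero, None]
    return out, int(zero.sum())
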