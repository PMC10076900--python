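"""3D ray tracing (3D-RT).

Eight origin spheres are placed inside the bones: one centrally below each
tibial plate (LT, MT) and one near the center of curvature ("focal point")
of each femoral group (aLF, aMF, cLF, cMF, pLF, pMF), found by least-squares
sphere fits to the group's distal surface.  Each sphere is tessellated as a
UV sphere with 60 polar and 60 azimuthal vertex subdivisions, giving
2 + 60*(60-2) = 3482 outward rays.  Every ray is marched in fixed steps; the
first entry into and first subsequent exit from the target (sub)region's
voxel set bound one chord, whose Euclidean length is the thickness sample,
allocated by the entry point.  Rays that never enter within the step cap
contribute no sample.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .._geometry import fit_sphere, uv_sphere_directions
from ..errors import ConfigurationError, MethodFailureError
from ..regions import SubregionLabeling
from ..surfaces import SurfacePair
from ..volume_io import VoxelPointSet
from .base import MAX_PLAUSIBLE_THICKNESS_MM, ThicknessMap, apply_thickness_cap

log = logging.getLogger(__name__)

#: sphere name -> (structure, target subregions)
SPHERE_TARGETS: dict[str, tuple[str, tuple[str, ...]]] = {
    "LT": ("tibia", ("cLT", "eLT", "iLT", "aLT", "pLT")),
    "MT": ("tibia", ("cMT", "eMT", "iMT", "aMT", "pMT")),
    "aLF": ("femur", ("aLF",)),
    "aMF": ("femur", ("aMF",)),
    "cLF": ("femur", ("icLF", "ccLF", "ecLF")),
    "cMF": ("femur", ("icMF", "ccMF", "ecMF")),
    "pLF": ("femur", ("pLF",)),
    "pMF": ("femur", ("pMF",)),
}


@dataclass
class RaySphereConfig:
    """Placement and tessellation of the eight ray-origin spheres."""

    centers: dict[str, np.ndarray]
    radius: float = 2.0
    n_polar: int = 60
    n_azimuthal: int = 60
    max_steps: int = 100
    step_mm: float = 0.18

    def __post_init__(self):
        if self.n_polar < 3 or self.n_azimuthal < 3:
            raise ConfigurationError("sphere subdivisions must be >= 3")
        if self.step_mm <= 0:
            raise ConfigurationError("step length must be positive")

    @property
    def rays_per_sphere(self) -> int:
        return 2 + self.n_azimuthal * (self.n_polar - 2)


def place_ray_spheres(
    tibia: VoxelPointSet,
    femur: VoxelPointSet,
    labeling: SubregionLabeling,
    femur_surfaces: SurfacePair,
    *,
    bone_offset_mm: float = 10.0,
    radius_mm: float = 2.0,
    n_polar: int = 60,
    n_azimuthal: int = 60,
    max_steps: int = 100,
    step_mm: float | None = None,
) -> RaySphereConfig:
    """Position all eight ray-origin spheres for one knee.

    Tibial centers are the plate centroids offset bone-ward (+z) by
    ``bone_offset_mm``; femoral centers are least-squares sphere centers
    fitted to each group's distal surface voxels, falling back (with a
    warning) to the surface centroid pushed ``bone_offset_mm`` toward the
    proximal side when the fit is degenerate (flat region).
    """
    if step_mm is None:
        step_mm = 0.5 * min(tibia.spacing)
    centers: dict[str, np.ndarray] = {}
    tib_sub, _ = labeling.assign(tibia.coords, structure="tibia")
    for name in ("LT", "MT"):
        mask = np.isin(tib_sub, SPHERE_TARGETS[name][1])
        if not mask.any():
            raise ConfigurationError(f"tibial region {name} is empty")
        c = tibia.coords[mask].mean(axis=0)
        centers[name] = c + np.array([0.0, 0.0, bone_offset_mm])

    dist_sub, _ = labeling.assign(femur_surfaces.distal.coords, structure="femur")
    prox_coords = femur_surfaces.proximal.coords
    prox_sub, _ = labeling.assign(prox_coords, structure="femur")
    for name in ("aLF", "aMF", "cLF", "cMF", "pLF", "pMF"):
        targets = SPHERE_TARGETS[name][1]
        mask = np.isin(dist_sub, targets)
        if not mask.any():
            raise ConfigurationError(f"femoral group {name} has no distal surface voxels")
        pts = femur_surfaces.distal.coords[mask]
        try:
            center, _radius = fit_sphere(pts)
            centers[name] = center
        except np.linalg.LinAlgError:
            pmask = np.isin(prox_sub, targets)
            ref = prox_coords[pmask].mean(axis=0) if pmask.any() else pts.mean(axis=0)
            u = ref - pts.mean(axis=0)
            nu = np.linalg.norm(u)
            u = u / nu if nu > 0 else np.array([0.0, 0.0, -1.0])
            centers[name] = pts.mean(axis=0) + bone_offset_mm * u
            warnings.warn(f"sphere fit degenerate for {name}; using centroid + offset")
    return RaySphereConfig(
        centers=centers,
        radius=radius_mm,
        n_polar=n_polar,
        n_azimuthal=n_azimuthal,
        max_steps=max_steps,
        step_mm=float(step_mm),
    )


def sphere_ray_bundle(config: RaySphereConfig) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(origins, unit directions) of the ray bundle of every sphere."""
    dirs = uv_sphere_directions(config.n_polar, config.n_azimuthal)
    return {
        name: (np.asarray(c, float) + config.radius * dirs, dirs)
        for name, c in config.centers.items()
    }


def _occupancy(labeling: SubregionLabeling, subregions: tuple[str, ...], shape):
    grid = np.zeros(shape, dtype=bool)
    mask = labeling.select(subregions)
    grid[tuple(labeling.indices[mask].T)] = True
    return grid


def thickness_ray_tracing(
    points: VoxelPointSet,
    labeling: SubregionLabeling,
    config: RaySphereConfig,
    structure: str,
    *,
    max_thickness: float = MAX_PLAUSIBLE_THICKNESS_MM,
) -> ThicknessMap:
    """Run the ray-tracing measurement for one structure (tibia or femur)."""
    spacing = np.asarray(points.spacing)
    shape = tuple(points.indices.max(axis=0) + 2)
    bundles = sphere_ray_bundle(config)
    exit_cap = int(np.ceil(max_thickness / config.step_mm)) + 1
    n_march = config.max_steps + 1 + exit_cap

    counts: dict = {"rays_fired": 0, "no_entry": 0, "no_exit": 0}
    all_origins, all_values, all_subs = [], [], []
    for name, (origins, dirs) in bundles.items():
        tgt_structure, targets = SPHERE_TARGETS[name]
        if tgt_structure != structure:
            continue
        occ = _occupancy(labeling, targets, shape)
        counts["rays_fired"] += len(origins)
        s = np.arange(n_march) * config.step_mm
        pts = origins[:, None, :] + s[None, :, None] * dirs[:, None, :]
        vox = np.rint(pts / spacing).astype(np.int64)
        inb = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=2)
        inside = np.zeros(inb.shape, dtype=bool)
        if inb.any():
            v = vox[inb]
            inside[inb] = occ[v[:, 0], v[:, 1], v[:, 2]]

        entry_window = inside[:, : config.max_steps + 1]
        has_entry = entry_window.any(axis=1)
        counts["no_entry"] += int((~has_entry).sum())
        if not has_entry.any():
            counts[f"empty:{name}"] = 1
            log.warning("3D-RT: no ray entered %s", name)
            continue
        e = np.argmax(entry_window, axis=1)
        idxs = np.arange(n_march)
        after = (idxs[None, :] > e[:, None]) & ~inside
        has_exit = after.any(axis=1) & has_entry
        counts["no_exit"] += int((has_entry & ~has_exit).sum())
        x = np.argmax(after, axis=1)
        sel = has_exit
        chord = (x[sel] - e[sel]) * config.step_mm
        entry_pts = origins[sel] + (e[sel] * config.step_mm)[:, None] * dirs[sel]
        keep = apply_thickness_cap(chord, counts, max_thickness)
        chord, entry_pts = chord[keep], entry_pts[keep]
        if len(chord) == 0:
            counts[f"empty:{name}"] = 1
            continue
        sub, n_un = labeling.assign(entry_pts, structure=structure)
        if n_un:
            counts["unassigned"] = counts.get("unassigned", 0) + n_un
        all_origins.append(entry_pts)
        all_values.append(chord)
        all_subs.append(sub)

    if not all_values:
        raise MethodFailureError(f"3D-RT produced zero samples for {structure}")
    return ThicknessMap(
        method="3D-RT",
        structure=structure,
        origins=np.vstack(all_origins),
        values=np.concatenate(all_values),
        subregions=np.concatenate(all_subs),
        counts=counts,
    )
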