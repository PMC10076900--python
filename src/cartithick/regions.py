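"""Standardized femorotibial subregion parcellation.

The tibial cartilage is split into medial/lateral plates at the midpoint of
the occupied y-range, the femoral cartilage at the trochlear sulcus.  Each
tibial plate is divided into a central subregion (a cylinder about the plate
center of gravity, z-axis aligned, sized to hold 20% of the plate volume)
and anterior/posterior/internal/external quadrants; each femoral plate into
anterior/central/posterior bands along x, with the central band sitting
vis-a-vis (sharing the x-interval of) the corresponding central tibial
subregion and further cut into three equal-width mediolateral thirds
(internal-central, central-central, external-central).

That yields the 20 standard subregion acronyms (cLT, eLT, iLT, aLT, pLT and
medial counterparts; aLF, pLF, icLF, ccLF, ecLF and medial counterparts).
Internal always means toward the intercondylar midline.  Medial is on the
high-y side by default (a laterality convention, overridable).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, EmptyStructureError, TooSmallError
from .volume_io import LabelVolume, VoxelPointSet, extract_structure_points
from .volume_io import FEMORAL_CARTILAGE, TIBIAL_CARTILAGE

log = logging.getLogger(__name__)

TIBIAL_SUBREGIONS = ("c", "e", "i", "a", "p")
FEMORAL_SUBREGIONS = ("a", "p", "ic", "cc", "ec")
REGIONS = ("LT", "MT", "LF", "MF")

#: Canonical subregion -> integer table used for label-volume export.
SUBREGION_CODES: dict[str, int] = {
    f"{pre}{reg}": i + 1
    for i, (pre, reg) in enumerate(
        [(p, r) for r in ("LT", "MT") for p in TIBIAL_SUBREGIONS]
        + [(p, r) for r in ("LF", "MF") for p in FEMORAL_SUBREGIONS]
    )
}


def region_of(subregion: str) -> str:
    """Region acronym (LT/MT/LF/MF) of a subregion acronym."""
    return subregion[-2:]


@dataclass
class SubregionLabeling:
    """Per-voxel subregion assignment for one or more cartilage structures."""

    indices: np.ndarray  # (n, 3) voxel indices
    spacing: tuple[float, float, float]
    subregion: np.ndarray  # (n,) acronym strings
    structure: np.ndarray  # (n,) "tibia" | "femur"
    meta: dict = field(default_factory=dict)
    _tree: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64).reshape(-1, 3)
        self.subregion = np.asarray(self.subregion, dtype="<U4")
        self.structure = np.asarray(self.structure, dtype="<U5")
        if not (len(self.indices) == len(self.subregion) == len(self.structure)):
            raise ValueError("inconsistent labeling array lengths")

    @property
    def coords(self) -> np.ndarray:
        return self.indices * np.asarray(self.spacing)

    @property
    def region(self) -> np.ndarray:
        return np.array([region_of(s) for s in self.subregion], dtype="<U2")

    def counts(self) -> pd.Series:
        return pd.Series(self.subregion).value_counts().sort_index()

    def select(self, subregions: Iterable[str]) -> np.ndarray:
        """Boolean mask of voxels belonging to any of the given subregions."""
        want = set(subregions)
        return np.isin(self.subregion, list(want))

    def assign(
        self, points: np.ndarray, structure: str | None = None, max_dist_voxels: float = 2.0
    ) -> tuple[np.ndarray, int]:
        """Subregion of the nearest labeled voxel for each physical point.

        Points farther than ``max_dist_voxels`` voxel diagonals from any
        labeled voxel are left unassigned (empty string) and counted.
        """
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        key = structure or "__all__"
        if key not in self._tree:
            mask = (
                np.ones(len(self.indices), bool)
                if structure is None
                else self.structure == structure
            )
            self._tree[key] = (cKDTree(self.coords[mask]), np.flatnonzero(mask))
        tree, sel = self._tree[key]
        dist, nearest = tree.query(points)
        limit = max_dist_voxels * max(self.spacing)
        out = self.subregion[sel[nearest]].copy()
        bad = dist > limit
        out[bad] = ""
        n_bad = int(bad.sum())
        if n_bad:
            log.warning("%d points unassigned (farther than %.2f mm)", n_bad, limit)
        return out, n_bad


class TibiaSplit(NamedTuple):
    medial: VoxelPointSet
    lateral: VoxelPointSet
    midline_y: float


class FemurSplit(NamedTuple):
    medial: VoxelPointSet
    lateral: VoxelPointSet
    sulcus_y: float
    fallback_used: bool


def split_tibia_plates(tibia: VoxelPointSet, *, medial_side: str = "high-y") -> TibiaSplit:
    """Split tibial cartilage into medial/lateral at the central y-coordinate.

    The boundary is the midpoint of the occupied physical y-range.  An empty
    plate on either side is an error (degenerate input), logged and raised.
    """
    if len(tibia) == 0:
        raise EmptyStructureError("tibial point set is empty")
    y = tibia.coords[:, 1]
    mid = 0.5 * (y.min() + y.max())
    # epsilon keeps voxels sitting exactly on the midline on the low side
    # regardless of floating-point noise (translation invariance)
    high = tibia.indices[y > mid + 1e-9]
    low = tibia.indices[y <= mid + 1e-9]
    if len(high) == 0 or len(low) == 0:
        log.error("tibial medial/lateral split produced an empty plate (mid y=%.2f)", mid)
        raise EmptyStructureError("one tibial plate is empty after medial/lateral split")
    high_ps = VoxelPointSet(high, tibia.spacing)
    low_ps = VoxelPointSet(low, tibia.spacing)
    if medial_side == "high-y":
        return TibiaSplit(medial=high_ps, lateral=low_ps, midline_y=mid)
    return TibiaSplit(medial=low_ps, lateral=high_ps, midline_y=mid)


def _sulcus_profile(femur: VoxelPointSet, smooth: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean distal column height (mm) per occupied sagittal slice.

    Uses the anterior half of the plate (x below the median) so the posterior
    wrap-around of the condyles does not bias the profile.
    """
    idx = femur.indices
    x_med = np.median(idx[:, 0])
    ant = idx[idx[:, 0] <= x_med]
    if len(ant) == 0:
        ant = idx
    # per (i, j) column: max k; then mean over columns per j
    order = np.lexsort((ant[:, 2], ant[:, 0], ant[:, 1]))
    s = ant[order]
    col_change = np.empty(len(s), bool)
    col_change[0] = True
    col_change[1:] = (np.diff(s[:, 1]) != 0) | (np.diff(s[:, 0]) != 0)
    starts = np.flatnonzero(col_change)
    ends = np.r_[starts[1:], len(s)]
    col_j = s[starts, 1]
    col_max_k = np.maximum.reduceat(s[:, 2], starts)
    js = np.unique(col_j)
    prof = np.array([col_max_k[col_j == j].mean() for j in js], dtype=float)
    prof *= femur.spacing[2]
    if smooth > 1 and len(prof) > smooth:
        kernel = np.ones(smooth) / smooth
        prof = np.convolve(np.pad(prof, smooth // 2, mode="edge"), kernel, mode="valid")[
            : len(js)
        ]
    return js, prof


def split_femur_plates(
    femur: VoxelPointSet, *, medial_side: str = "high-y", smooth: int = 5
) -> FemurSplit:
    """Split femoral cartilage into medial/lateral at the trochlear sulcus.

    The sulcus is located as the interior minimum of the smoothed per-slice
    mean distal-column-height profile.  A profile with no interior minimum
    (e.g. a perfectly flat or monotone femur) falls back to the midpoint of
    the occupied y-range, with a warning.
    """
    if len(femur) == 0:
        raise EmptyStructureError("femoral point set is empty")
    js, prof = _sulcus_profile(femur, smooth)
    fallback = False
    if len(js) < 5:
        fallback = True
    else:
        interior = slice(1, len(js) - 1)
        amin = 1 + int(np.argmin(prof[interior]))
        if prof[amin] < prof[0] - 1e-9 and prof[amin] < prof[-1] - 1e-9:
            sulcus_y = js[amin] * femur.spacing[1]
        else:
            fallback = True
    if fallback:
        y = femur.coords[:, 1]
        sulcus_y = 0.5 * (y.min() + y.max())
        warnings.warn("trochlear sulcus detection failed; falling back to mid-y split")
    y = femur.coords[:, 1]
    high = femur.indices[y > sulcus_y + 1e-9]
    low = femur.indices[y <= sulcus_y + 1e-9]
    if len(high) == 0 or len(low) == 0:
        raise EmptyStructureError("one femoral plate is empty after sulcus split")
    high_ps = VoxelPointSet(high, femur.spacing)
    low_ps = VoxelPointSet(low, femur.spacing)
    if medial_side == "high-y":
        return FemurSplit(medial=high_ps, lateral=low_ps, sulcus_y=float(sulcus_y), fallback_used=fallback)
    return FemurSplit(medial=low_ps, lateral=high_ps, sulcus_y=float(sulcus_y), fallback_used=fallback)


def partition_tibial_plate(
    plate: VoxelPointSet, side: str, midline_y: float
) -> SubregionLabeling:
    """Parcellate one tibial plate into the central + four outer subregions.

    The central subregion is the smallest z-axis cylinder about the plate's
    x-y center of gravity enclosing at least 20% of the plate voxels (the
    20th-percentile in-plane radius, ties included).  The outer ring is cut
    by the +-45 degree diagonals through the cylinder center: anterior faces
    -x, posterior +x, internal faces the intercondylar midline, external
    faces away from it.
    """
    if side not in ("LT", "MT"):
        raise ConfigurationError(f"invalid tibial side {side!r}")
    n = len(plate)
    if n < 5:
        raise TooSmallError(f"tibial plate {side} has only {n} voxels")
    xy = plate.coords[:, :2]
    center = xy.mean(axis=0)
    d = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
    k = int(np.ceil(0.2 * n))
    radius = float(np.partition(d, k - 1)[k - 1])
    # 1e-9 mm absorbs floating-point noise so distance ties are classified
    # consistently under whole-volume translation
    central = d <= radius + 1e-9

    dx = xy[:, 0] - center[0]
    dy = xy[:, 1] - center[1]
    toward_mid = np.sign(midline_y - center[1]) or 1.0
    sub = np.empty(n, dtype="<U4")
    sub[central] = f"c{side}"
    outer = ~central
    ap = np.abs(dy) <= np.abs(dx)  # anterior/posterior sectors (ties to a/p)
    sub[outer & ap & (dx < 0)] = f"a{side}"
    sub[outer & ap & (dx >= 0)] = f"p{side}"
    ie = outer & ~ap
    sub[ie & (dy * toward_mid > 0)] = f"i{side}"
    sub[ie & (dy * toward_mid <= 0)] = f"e{side}"
    meta = {
        "cylinder": {side: {"center_xy": center, "radius": radius}},
        "midline_y": float(midline_y),
    }
    return SubregionLabeling(
        indices=plate.indices,
        spacing=plate.spacing,
        subregion=sub,
        structure=np.full(n, "tibia"),
        meta=meta,
    )


def partition_femoral_plate(
    plate: VoxelPointSet,
    side: str,
    matching_tibial_central: SubregionLabeling,
    midline_y: float,
) -> SubregionLabeling:
    """Parcellate one femoral plate into a/p + the three central thirds.

    The central femoral band shares the x-interval occupied by the central
    tibial subregion of the same compartment ("vis-a-vis"); smaller x is
    anterior, larger x posterior.  The central band is split into three
    equal-width y-thirds; the third nearest the intercondylar midline is
    internal-central, the farthest external-central.
    """
    if side not in ("LF", "MF"):
        raise ConfigurationError(f"invalid femoral side {side!r}")
    if len(plate) == 0:
        raise EmptyStructureError(f"femoral plate {side} is empty")
    t_side = "LT" if side == "LF" else "MT"
    cmask = matching_tibial_central.subregion == f"c{t_side}"
    if not cmask.any():
        raise ConfigurationError(f"empty tibial central reference for {side}")
    cx = matching_tibial_central.coords[cmask, 0]
    x_lo, x_hi = float(cx.min()), float(cx.max())

    n = len(plate)
    x = plate.coords[:, 0]
    y = plate.coords[:, 1]
    sub = np.empty(n, dtype="<U4")
    anterior = x < x_lo
    posterior = x > x_hi
    central = ~anterior & ~posterior
    sub[anterior] = f"a{side}"
    sub[posterior] = f"p{side}"
    if central.any():
        yc = y[central]
        y_lo, y_hi = yc.min(), yc.max()
        w = max(y_hi - y_lo, 1e-9)
        third = np.clip(np.floor(3.0 * (yc - y_lo) / w).astype(int), 0, 2)
        toward_mid = 1.0 if midline_y >= 0.5 * (y_lo + y_hi) else -1.0
        # ascending-y thirds; orientation depends on which side the midline is
        names_up = ["ec", "cc", "ic"] if toward_mid > 0 else ["ic", "cc", "ec"]
        csub = np.array([f"{names_up[t]}{side}" for t in third], dtype="<U4")
        sub[central] = csub
        thirds_meta = {"y_lo": float(y_lo), "y_hi": float(y_hi)}
    else:
        log.warning("femoral plate %s: central band empty (no voxels in [%.2f, %.2f])", side, x_lo, x_hi)
        thirds_meta = None
    meta = {
        "central_x_interval": {side: (x_lo, x_hi)},
        "central_thirds": {side: thirds_meta},
        "midline_y": float(midline_y),
    }
    return SubregionLabeling(
        indices=plate.indices,
        spacing=plate.spacing,
        subregion=sub,
        structure=np.full(n, "femur"),
        meta=meta,
    )


def merge_labelings(*labelings: SubregionLabeling) -> SubregionLabeling:
    """Concatenate per-plate labelings into one joint-level labeling."""
    if not labelings:
        raise ValueError("nothing to merge")
    meta: dict = {}
    for lab in labelings:
        for k, v in lab.meta.items():
            if isinstance(v, dict) and isinstance(meta.get(k), dict):
                meta[k].update(v)
            else:
                meta[k] = v if not isinstance(v, dict) else dict(v)
    return SubregionLabeling(
        indices=np.vstack([l.indices for l in labelings]),
        spacing=labelings[0].spacing,
        subregion=np.concatenate([l.subregion for l in labelings]),
        structure=np.concatenate([l.structure for l in labelings]),
        meta=meta,
    )


def parcellate_knee(vol: LabelVolume, *, medial_side: str = "high-y") -> SubregionLabeling:
    """Full parcellation of a segmented knee into the 20 subregions."""
    tibia = extract_structure_points(vol, TIBIAL_CARTILAGE)
    femur = extract_structure_points(vol, FEMORAL_CARTILAGE)
    tsplit = split_tibia_plates(tibia, medial_side=medial_side)
    fsplit = split_femur_plates(femur, medial_side=medial_side)
    lt = partition_tibial_plate(tsplit.lateral, "LT", tsplit.midline_y)
    mt = partition_tibial_plate(tsplit.medial, "MT", tsplit.midline_y)
    lf = partition_femoral_plate(fsplit.lateral, "LF", lt, tsplit.midline_y)
    mf = partition_femoral_plate(fsplit.medial, "MF", mt, tsplit.midline_y)
    merged = merge_labelings(lt, mt, lf, mf)
    merged.meta["sulcus_y"] = fsplit.sulcus_y
    merged.meta["tibia_midline_y"] = tsplit.midline_y
    return merged


def parcellation_to_volume(labeling: SubregionLabeling, shape: tuple[int, int, int]) -> LabelVolume:
    """Export a labeling as an integer label volume (see SUBREGION_CODES)."""
    grid = np.zeros(shape, dtype=np.int16)
    codes = np.array([SUBREGION_CODES.get(s, 0) for s in labeling.subregion], dtype=np.int16)
    grid[tuple(labeling.indices.T)] = codes
    return LabelVolume(grid=grid, spacing=labeling.spacing, label_map=dict(SUBREGION_CODES))
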