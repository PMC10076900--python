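"""Synthetic label-volume phantoms with analytically known thickness.

These phantoms emulate OAI-ZIB-style segmented knee volumes: tibia-like flat
plates and femur-like curved shells, voxelized at the study resolution of
(0.36, 0.7, 0.36) mm per voxel along (x, y, z) — sagittal slices are indexed
by y, so the 0.7 mm through-plane step lies on the mediolateral axis.  Every
phantom carries a queryable ground-truth thickness field, which is what makes
all five measurement methods testable without any external download.

Voxelization rule: a voxel belongs to the solid iff its *center* lies inside
the continuous geometry (unbiased, and consistent with the package-wide
voxel-center coordinate convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import DataError
from .volume_io import (
    DEFAULT_LABEL_MAP,
    FEMORAL_CARTILAGE,
    TIBIAL_CARTILAGE,
    LabelVolume,
)

DEFAULT_SPACING = (0.36, 0.7, 0.36)

ThicknessField = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class Phantom:
    """A voxelized phantom plus its analytic ground truth.

    ``truth`` maps structure name -> callable returning the true local
    thickness (mm) at arbitrary physical query points of shape (n, 3).
    ``params`` records the construction geometry (centers, radii, extents).
    """

    volume: LabelVolume
    truth: dict[str, ThicknessField] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def _axes(shape, spacing):
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def _grid_shape(extent_mm, spacing):
    return tuple(int(np.floor(e / s)) + 1 for e, s in zip(extent_mm, spacing))


def make_slab_phantom(
    thickness: float = 2.0,
    extent: tuple[float, float] = (40.0, 30.0),
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    tilt_deg: float = 0.0,
    *,
    structure: str = TIBIAL_CARTILAGE,
    margin_mm: float = 2.0,
) -> Phantom:
    """Flat (optionally tilted) plate of constant normal thickness.

    The plate normal is tilted by ``tilt_deg`` about the y-axis; the in-plane
    extent is ``extent = (along-x', along-y)`` mm.  The truth field returns
    ``thickness`` everywhere.
    """
    t = float(thickness)
    if t < 2.0 * max(spacing):
        raise DataError(
            f"thickness {t} mm below resolvable limit 2*max(spacing)={2*max(spacing):.2f} mm"
        )
    tau = np.deg2rad(tilt_deg)
    n_hat = np.array([np.sin(tau), 0.0, np.cos(tau)])
    u_hat = np.array([np.cos(tau), 0.0, -np.sin(tau)])
    p0 = np.array([margin_mm + abs(t * np.sin(tau)), margin_mm, margin_mm + abs(extent[0] * np.sin(tau))])

    ex_x = extent[0] * abs(np.cos(tau)) + t * abs(np.sin(tau)) + 2 * margin_mm
    ex_y = extent[1] + 2 * margin_mm
    ex_z = extent[0] * abs(np.sin(tau)) + t * abs(np.cos(tau)) + 2 * margin_mm
    shape = _grid_shape((ex_x, ex_y, ex_z), spacing)
    xs, ys, zs = _axes(shape, spacing)

    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    dx = X - p0[0]
    dz = Z - p0[2]
    s = dx * n_hat[0] + dz * n_hat[2]
    u = dx * u_hat[0] + dz * u_hat[2]
    mask = (
        (s >= 0.0)
        & (s <= t)
        & (u >= 0.0)
        & (u <= extent[0])
        & (Y >= margin_mm)
        & (Y <= margin_mm + extent[1])
    )
    label = DEFAULT_LABEL_MAP[structure]
    grid = np.zeros(shape, dtype=np.int16)
    grid[np.broadcast_to(mask, shape)] = label
    vol = LabelVolume(grid=grid, spacing=spacing)
    truth = {structure: lambda pts, t=t: np.full(np.asarray(pts).reshape(-1, 3).shape[0], t)}
    params = {
        "thickness": t,
        "extent": tuple(extent),
        "tilt_deg": float(tilt_deg),
        "normal": n_hat,
        "origin": p0,
        "structure": structure,
    }
    return Phantom(volume=vol, truth=truth, params=params)


def make_shell_phantom(
    radius: float = 20.0,
    thickness: float = 2.0,
    cap_deg: float = 60.0,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    *,
    structure: str = FEMORAL_CARTILAGE,
    margin_mm: float = 1.0,
    trim: str = "cylinder",
) -> Phantom:
    """Spherical-shell sector of constant radial thickness (femur-like).

    The shell occupies radii ``[radius, radius + thickness]`` within polar
    angle ``cap_deg`` of the +z axis (the cap opens toward the feet, like a
    femoral condyle facing the tibia).  The outer surface is the articular
    (distal) one.

    ``trim`` selects how the sector is cut: ``"cylinder"`` (default) trims
    at the cylinder ``rho <= radius*sin(cap)`` parallel to the z columns, so
    every surface column ends on the true spherical surfaces and the truth
    field (constant radial thickness) is valid at every measured point;
    ``"cone"`` trims at the radial cone ``polar <= cap``, whose cut wall is
    itself picked up as surface by column-wise extraction near the rim (the
    local thickness there is not the radial one).
    """
    R, t = float(radius), float(thickness)
    if R <= t:
        raise DataError("shell radius must exceed thickness")
    if not (0.0 < cap_deg <= 150.0):
        raise DataError("degenerate shell sector")
    if trim not in ("cylinder", "cone"):
        raise DataError(f"unknown trim {trim!r}")
    cap = np.deg2rad(cap_deg)
    Ro = R + t
    half_xy = Ro * np.sin(min(cap, np.pi / 2)) + margin_mm
    z_lo = R * np.cos(cap) if cap <= np.pi / 2 else Ro * np.cos(cap)
    center = np.array([half_xy, half_xy, margin_mm - z_lo])
    ex_z = center[2] + Ro + margin_mm
    shape = _grid_shape((2 * half_xy, 2 * half_xy, ex_z), spacing)
    xs, ys, zs = _axes(shape, spacing)
    dx = (xs - center[0])[:, None, None]
    dy = (ys - center[1])[None, :, None]
    dz = (zs - center[2])[None, None, :]
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    mask = (r >= R) & (r <= Ro)
    if trim == "cylinder":
        rho = np.sqrt(dx**2 + dy**2)
        mask &= (rho <= R * np.sin(min(cap, np.pi / 2))) & (dz > 0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            polar = np.arccos(np.clip(dz / np.where(r == 0, 1.0, r), -1.0, 1.0))
        mask &= polar <= cap
    if not mask.any():
        raise DataError("shell voxelization produced an empty volume")
    grid = np.zeros(shape, dtype=np.int16)
    grid[mask] = DEFAULT_LABEL_MAP[structure]
    vol = LabelVolume(grid=grid, spacing=spacing)
    truth = {structure: lambda pts, t=t: np.full(np.asarray(pts).reshape(-1, 3).shape[0], t)}
    params = {
        "radius": R,
        "thickness": t,
        "cap_deg": float(cap_deg),
        "center": center,
        "structure": structure,
        "trim": trim,
    }
    return Phantom(volume=vol, truth=truth, params=params)


@dataclass(frozen=True)
class KneePhantomSpec:
    """Geometry of the composite knee phantom.

    Two flat tibia-like plates of distinct constant thickness plus a
    femur-like double-dome shell whose height profile has an interior trough
    (the synthetic trochlear sulcus) at ``sulcus_frac`` of the femoral
    mediolateral span.  Defaults voxelize at the study resolution to roughly
    a million voxels.  ``roughness_mm`` adds seeded per-column jitter to the
    tibial proximal surface height (0 = perfectly smooth plates).
    """

    spacing: tuple[float, float, float] = DEFAULT_SPACING
    tibia_thickness_lateral: float = 1.5
    tibia_thickness_medial: float = 2.5
    tibia_x: tuple[float, float] = (8.0, 32.0)
    tibia_y_lateral: tuple[float, float] = (6.0, 30.0)
    tibia_y_medial: tuple[float, float] = (40.0, 64.0)
    tibia_top_z: float = 29.0
    femur_radius: float = 16.0
    femur_thickness: float = 2.0
    femur_y: tuple[float, float] = (6.0, 64.0)
    femur_center_x: float = 20.0
    femur_center_z: float = 10.0
    sulcus_depth: float = 3.0
    sulcus_frac: float = 0.5
    anterior_deg: float = 70.0
    posterior_deg: float = 110.0
    extent: tuple[float, float, float] = (40.0, 70.0, 33.0)
    roughness_mm: float = 0.0
    seed: int = 0


def make_knee_phantom(spec: KneePhantomSpec | None = None) -> Phantom:
    """Composite knee phantom: two tibial plates + double-dome femoral shell.

    The femoral shell is, per sagittal slice y, an annular arc of radial
    thickness ``femur_thickness`` about a center whose z position dips by
    ``sulcus_depth`` at the sulcus; medial/lateral domes therefore sit higher
    (larger z reach) than the trough, giving the parcellation a detectable
    interior minimum.  Medial is on the high-y side.
    """
    sp = spec or KneePhantomSpec()
    spacing = sp.spacing
    shape = _grid_shape(sp.extent, spacing)
    xs, ys, zs = _axes(shape, spacing)
    grid = np.zeros(shape, dtype=np.int16)
    rng = np.random.default_rng(sp.seed)

    # --- tibial plates (lateral = low y, medial = high y) ---
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    in_x = (X >= sp.tibia_x[0]) & (X <= sp.tibia_x[1])
    for (y_lo, y_hi), t in (
        (sp.tibia_y_lateral, sp.tibia_thickness_lateral),
        (sp.tibia_y_medial, sp.tibia_thickness_medial),
    ):
        if sp.roughness_mm > 0:
            jitter = rng.uniform(-sp.roughness_mm, sp.roughness_mm, size=(len(xs), len(ys)))
            top = sp.tibia_top_z + jitter[:, :, None]
        else:
            top = sp.tibia_top_z
        mask = in_x & (Y >= y_lo) & (Y <= y_hi) & (Z >= top) & (Z <= top + t)
        grid[np.broadcast_to(mask, shape)] = DEFAULT_LABEL_MAP[TIBIAL_CARTILAGE]

    # --- femoral double-dome shell ---
    y1, y2 = sp.femur_y
    y_star = y1 + sp.sulcus_frac * (y2 - y1)
    zc = np.full(len(ys), sp.femur_center_z)
    in_span = (ys >= y1) & (ys <= y2)
    left = in_span & (ys <= y_star)
    right = in_span & (ys > y_star)
    zc[left] -= sp.sulcus_depth * np.sin(
        0.5 * np.pi * (ys[left] - y1) / max(y_star - y1, 1e-9)
    ) ** 2
    zc[right] -= sp.sulcus_depth * np.sin(
        0.5 * np.pi * (y2 - ys[right]) / max(y2 - y_star, 1e-9)
    ) ** 2
    R, tf = sp.femur_radius, sp.femur_thickness
    dxf = X - sp.femur_center_x
    dzf = Z - zc[None, :, None]
    r = np.sqrt(dxf**2 + dzf**2)
    theta = np.arctan2(dxf, dzf)  # angle from +z toward +x (posterior)
    fmask = (
        (r >= R)
        & (r <= R + tf)
        & (theta >= -np.deg2rad(sp.anterior_deg))
        & (theta <= np.deg2rad(sp.posterior_deg))
        & (Y >= y1)
        & (Y <= y2)
    )
    fmask = np.broadcast_to(fmask, shape)
    if (grid[fmask] != 0).any():
        raise DataError("knee phantom construction error: overlapping structures")
    grid[fmask] = DEFAULT_LABEL_MAP[FEMORAL_CARTILAGE]

    vol = LabelVolume(grid=grid, spacing=spacing)
    mid_y = 0.5 * (sp.tibia_y_lateral[1] + sp.tibia_y_medial[0])

    def tibia_truth(pts, sp=sp, mid_y=mid_y):
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        return np.where(
            pts[:, 1] >= mid_y, sp.tibia_thickness_medial, sp.tibia_thickness_lateral
        )

    truth = {
        TIBIAL_CARTILAGE: tibia_truth,
        FEMORAL_CARTILAGE: lambda pts, t=tf: np.full(
            np.asarray(pts).reshape(-1, 3).shape[0], t
        ),
    }
    params = {
        "spec": sp,
        "sulcus_y": y_star,
        "tibia_mid_y": mid_y,
        "femur_center_x": sp.femur_center_x,
        "femur_center_z_profile": zc,
        "femur_radius": R,
    }
    return Phantom(volume=vol, truth=truth, params=params)
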