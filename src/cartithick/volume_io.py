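"""Reading and writing segmented knee label volumes.

The in-memory convention is fixed throughout the package:

* ``grid[i, j, k]`` is the label of the voxel with 0-based index ``(i, j, k)``
  along the (x, y, z) axes, where x runs anteroposterior, y mediolateral and
  z head-to-feet (so for the tibia, larger z is closer to the bone).
* the physical coordinate of a voxel is ``index * spacing`` (voxel-center
  convention), with spacing in mm per voxel.

Two on-disk dialects are supported: MetaImage (.mhd/.raw, the OAI-ZIB
distribution format) through SimpleITK and NIfTI (.nii/.nii.gz) through
nibabel.  SimpleITK hands arrays back in (z, y, x) index order; they are
transposed on the way in and out so the rest of the package never sees that
ordering.

The default label encoding follows the published OAI-ZIB release
(femoral bone 1, femoral cartilage 2, tibial bone 3, tibial cartilage 4);
it is an overridable assumption, since label integers vary between
segmentation pipelines.
"""
from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import EmptyStructureError, FormatError, MetadataError

log = logging.getLogger(__name__)

FEMORAL_CARTILAGE = "femoral cartilage"
TIBIAL_CARTILAGE = "tibial cartilage"

#: Assumed OAI-ZIB integer encoding; override via ``LabelVolume.label_map``.
DEFAULT_LABEL_MAP: dict[str, int] = {
    "femoral bone": 1,
    FEMORAL_CARTILAGE: 2,
    "tibial bone": 3,
    TIBIAL_CARTILAGE: 4,
}

Spacing = tuple[float, float, float]


@dataclass(frozen=True)
class VoxelPointSet:
    """A set of labeled voxels of one structure.

    ``indices`` is an (n, 3) integer array of (i, j, k) voxel indices; the
    physical coordinates in mm are ``indices * spacing``.
    """

    indices: np.ndarray
    spacing: Spacing

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64).reshape(-1, 3)
        object.__setattr__(self, "indices", idx)
        if len(idx) != len(np.unique(idx, axis=0)):
            raise ValueError("duplicate voxel indices in point set")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def coords(self) -> np.ndarray:
        """Physical voxel-center coordinates, shape (n, 3), in mm."""
        return self.indices * np.asarray(self.spacing, dtype=float)


@dataclass(frozen=True)
class LabelVolume:
    """A segmented 3D label volume with voxel spacing and label encoding."""

    grid: np.ndarray
    spacing: Spacing
    label_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValueError("grid must hold integer labels")
        object.__setattr__(self, "grid", grid)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        object.__setattr__(self, "spacing", sp)
        known = set(self.label_map.values()) | {0}
        present = set(np.unique(grid).tolist())
        unknown = present - known
        if unknown:
            warnings.warn(
                f"volume contains labels not in label_map: {sorted(unknown)} (retained)",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)


def extract_structure_points(
    vol: LabelVolume, structure: str, *, allow_empty: bool = False
) -> VoxelPointSet:
    """Voxel indices of one named structure.

    Raises ``KeyError`` for a structure missing from the label map and
    ``EmptyStructureError`` when the structure has no voxels (downstream
    measurement methods require non-empty input), unless ``allow_empty``.
    """
    code = vol.label_map[structure]
    idx = np.argwhere(vol.grid == code)
    if len(idx) == 0 and not allow_empty:
        raise EmptyStructureError(f"structure {structure!r} (label {code}) has no voxels")
    return VoxelPointSet(indices=idx, spacing=vol.spacing)


def _infer_dialect(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".mhd") or p.endswith(".mha"):
        return "metaimage"
    if p.endswith(".nii") or p.endswith(".nii.gz"):
        return "nifti"
    raise FormatError(f"cannot infer dialect from extension of {path!r}")


def read_label_volume(
    path: str,
    dialect: str | None = None,
    label_map: Mapping[str, int] | None = None,
) -> LabelVolume:
    """Read a segmented label volume from MetaImage or NIfTI.

    Spacing is taken from the file header and the axis order is normalized to
    the package's (x, y, z) convention.  A missing spacing entry raises
    ``MetadataError``; an unparsable file raises ``FormatError``.
    """
    dialect = dialect or _infer_dialect(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    lm = dict(label_map) if label_map is not None else dict(DEFAULT_LABEL_MAP)
    if dialect == "metaimage":
        grid, spacing = _read_metaimage(path)
    elif dialect == "nifti":
        grid, spacing = _read_nifti(path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    log.info("read %s: shape=%s spacing=%s", path, grid.shape, spacing)
    return LabelVolume(grid=grid, spacing=spacing, label_map=lm)


def _read_metaimage(path: str):
    import SimpleITK as sitk

    # SimpleITK silently defaults a missing ElementSpacing to 1.0; check the
    # (plain-text) header ourselves so missing metadata is a hard error.
    try:
        with open(path, "rb") as fh:
            header = fh.read(4096).decode("latin-1")
    except OSError as exc:
        raise FormatError(f"cannot open {path}: {exc}") from exc
    keys = {line.split("=")[0].strip() for line in header.splitlines() if "=" in line}
    if not ({"ElementSpacing", "ElementSize"} & keys):
        raise MetadataError(f"{path}: MetaImage header lacks ElementSpacing")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # noqa: BLE001 - SimpleITK raises bare RuntimeError
        raise FormatError(f"cannot read MetaImage {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got ndim={arr.ndim}")
    grid = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.int64)
    spacing = tuple(float(s) for s in img.GetSpacing())  # already (x, y, z)
    return grid, spacing


def _read_nifti(path: str):
    import nibabel as nib

    try:
        img = nib.load(path)
        arr = np.asanyarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got ndim={arr.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MetadataError(f"{path}: NIfTI header lacks positive voxel spacing")
    grid = np.ascontiguousarray(np.rint(arr).astype(np.int64))
    return grid, tuple(float(z) for z in zooms)


def write_label_volume(vol: LabelVolume, path: str, dialect: str | None = None) -> None:
    """Write a label volume; re-reading yields identical grid and spacing."""
    dialect = dialect or _infer_dialect(path)
    if dialect == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(
            np.ascontiguousarray(vol.grid.transpose(2, 1, 0)).astype(np.uint8)
            if vol.grid.max(initial=0) < 256 and vol.grid.min(initial=0) >= 0
            else np.ascontiguousarray(vol.grid.transpose(2, 1, 0)).astype(np.int32)
        )
        img.SetSpacing(tuple(vol.spacing))
        try:
            sitk.WriteImage(img, path)
        except Exception as exc:  # noqa: BLE001
            raise OSError(f"cannot write {path}: {exc}") from exc
    elif dialect == "nifti":
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        img = nib.Nifti1Image(vol.grid.astype(np.int16), affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    log.info("wrote %s (%s)", path, dialect)


def label_partition_counts(vol: LabelVolume) -> dict[int, int]:
    """Voxel count per label present in the grid (including background 0)."""
    labels, counts = np.unique(vol.grid, return_counts=True)
    return dict(zip(labels.tolist(), counts.tolist()))
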