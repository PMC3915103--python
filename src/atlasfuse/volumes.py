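"""Core image containers, NIfTI I/O and warping.

Three grid types are used throughout the pipeline:

``VolumeImage``
    A 3-D scalar intensity volume with voxel spacing (mm) and origin.
``LabelVolume``
    A 3-D non-negative integer label map (0 = background) on the same kind
    of grid.
``DisplacementField``
    A per-voxel 3-vector field ``u(x)`` defined on the FIXED image grid, in
    voxel units of that grid, using the pull-back convention

        output(x) = moving(x + u(x)).

    The identity transform is the zero field.  This convention is stated
    prominently because warped atlas labels must land on the subject grid:
    a field registered with the subject as the fixed image directly pulls
    atlas data onto subject voxels.

All similarity and graph computations operate in voxel space; spacing and
origin are carried for I/O fidelity and for physical-unit surface metrics.
Out-of-bounds samples map to 0 (background) rather than clamping, so edge
labels are never smeared across the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ValidationError

__all__ = [
    "VolumeImage",
    "LabelVolume",
    "DisplacementField",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "warp",
]


def _check_geometry(spacing, origin) -> tuple[np.ndarray, np.ndarray]:
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,):
        raise ValidationError("spacing and origin must be 3-vectors")
    if not np.all(spacing > 0):
        raise ValidationError(f"voxel spacing must be positive, got {spacing}")
    return spacing, origin


@dataclass
class VolumeImage:
    """3-D scalar intensity grid with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"expected a 3-D grid, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("intensities must be finite")
        self.spacing, self.origin = _check_geometry(self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """3-D non-negative integer label grid; 0 is background."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValidationError(f"expected a 3-D grid, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            bad = ~np.isclose(data, rounded, atol=1e-6) | ~np.isfinite(data)
            if np.any(bad):
                idx = tuple(int(i) for i in np.argwhere(bad)[0])
                raise ValidationError(
                    f"label volume contains non-integer value {data[idx]} at voxel {idx}"
                )
            data = rounded.astype(np.int32)
        if np.any(data < 0):
            idx = tuple(int(i) for i in np.argwhere(data < 0)[0])
            raise ValidationError(f"negative label {data[idx]} at voxel {idx}")
        self.data = data.astype(np.int32)
        self.spacing, self.origin = _check_geometry(self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted array of distinct label values present (including 0)."""
        return np.unique(self.data)


@dataclass
class DisplacementField:
    """Per-voxel displacement 3-vectors on the fixed grid, voxel units.

    ``data`` has shape ``(nx, ny, nz, 3)``; component ``c`` displaces along
    axis ``c`` of the grid.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValidationError(
                f"displacement field must have shape (nx, ny, nz, 3), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("displacement components must be finite")
        self.spacing, self.origin = _check_geometry(self.spacing, self.origin)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.data**2).sum(axis=-1)).max())


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _geometry_from(img: nib.Nifti1Image) -> tuple[np.ndarray, np.ndarray]:
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return spacing, origin


def read_volume(path: str | os.PathLike, as_labels: bool = False) -> VolumeImage | LabelVolume:
    """Read a NIfTI scalar volume; with ``as_labels`` values are cast-checked to integers."""
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing, origin = _geometry_from(img)
    if as_labels:
        return LabelVolume(data, spacing, origin)
    return VolumeImage(data.astype(np.float64), spacing, origin)


def write_volume(vol: VolumeImage | LabelVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1; labels as int32, intensities as float64."""
    if os.path.isdir(os.fspath(path)):
        raise IsADirectoryError(f"cannot write volume to directory {path}")
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.int32)
    else:
        data = vol.data.astype(np.float64)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, os.fspath(path))


def read_field(path: str | os.PathLike) -> DisplacementField:
    """Read a displacement field stored as a 3-component vector NIfTI."""
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 5:
        if data.shape[3] != 1:
            raise ValidationError(f"{path}: unexpected 5-D layout {data.shape}")
        data = data[:, :, :, 0, :]
    if data.ndim != 4:
        raise ValidationError(f"{path}: expected a vector volume, got shape {data.shape}")
    if data.shape[-1] != 3:
        raise ValidationError(
            f"{path}: displacement field must have 3 components per voxel, got {data.shape[-1]}"
        )
    spacing, origin = _geometry_from(img)
    return DisplacementField(data, spacing, origin)


def write_field(fld: DisplacementField, path: str | os.PathLike) -> None:
    """Write a displacement field as NIfTI with dim[5]=3 and vector intent."""
    if os.path.isdir(os.fspath(path)):
        raise IsADirectoryError(f"cannot write field to directory {path}")
    data = fld.data[:, :, :, np.newaxis, :]  # (x, y, z, 1, 3) per NIfTI vector layout
    img = nib.Nifti1Image(data.astype(np.float64), _affine(fld.spacing, fld.origin))
    img.header.set_intent("vector")
    nib.save(img, os.fspath(path))


def _sample(data: np.ndarray, field_data: np.ndarray, order: int) -> np.ndarray:
    shape = field_data.shape[:3]
    coords = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(np.float64)
    coords += np.moveaxis(field_data, -1, 0)
    return map_coordinates(data, coords, order=order, mode="constant", cval=0.0)


def warp(
    vol: VolumeImage | LabelVolume,
    fld: DisplacementField,
    interpolation: str = "linear",
) -> VolumeImage | LabelVolume:
    """Resample ``vol`` through ``fld``: ``out(x) = vol(x + u(x))``.

    The output lives on the field's (fixed) grid.  Intensities use trilinear
    interpolation; label volumes must use nearest-neighbour so no new label
    values are invented.  Samples falling outside the moving grid become 0.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    if isinstance(vol, LabelVolume):
        if interpolation != "nearest":
            raise ValidationError("label volumes must be warped with nearest interpolation")
        out = _sample(vol.data.astype(np.float64), fld.data, order=0)
        return LabelVolume(np.rint(out).astype(np.int32), fld.spacing, fld.origin)
    order = 1 if interpolation == "linear" else 0
    out = _sample(vol.data, fld.data, order=order)
    return VolumeImage(out, fld.spacing, fld.origin)
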