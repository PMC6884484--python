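"""Volume containers and NIfTI I/O.

All volumes are 3-D scalar grids with per-axis voxel spacing in mm.  The
slice (axial) axis is the last array axis; the physical position of slice
``k`` is ``k * spacing[2]`` mm, matching IBSR-style acquisitions with a
fixed 1.5 mm slice pitch.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "IntensityVolume",
    "LabelVolume",
    "Atlas",
    "VolumeShapeError",
    "DegenerateRangeError",
    "read_volume",
    "read_label",
    "write_volume",
    "normalize_intensity",
    "binarize_label",
]


class VolumeShapeError(ValueError):
    """Raised when a volume is not 3-D or grids do not match."""


class DegenerateRangeError(ValueError):
    """Raised when intensity normalization has no dynamic range to stretch."""


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3:
        raise VolumeShapeError(f"spacing must have 3 entries, got {len(sp)}")
    if any(s <= 0 for s in sp):
        raise VolumeShapeError(f"spacing entries must be positive, got {sp}")
    return sp


@dataclasses.dataclass(frozen=True)
class IntensityVolume:
    """A 3-D scalar image with voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise VolumeShapeError(f"expected a 3-D volume, got ndim={data.ndim}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def axial_positions(self) -> np.ndarray:
        """Physical position (mm) of each axial slice: ``k * slice_spacing``."""
        return np.arange(self.data.shape[2], dtype=np.float64) * self.spacing[2]


@dataclasses.dataclass(frozen=True)
class LabelVolume:
    """A binary 3-D label image; 1 marks the target organization."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeShapeError(f"expected a 3-D label volume, got ndim={data.ndim}")
        vals = np.unique(data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"label values must be in {{0, 1}}, found {vals[:10]}")
        object.__setattr__(self, "data", data.astype(np.uint8))
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def axial_positions(self) -> np.ndarray:
        return np.arange(self.data.shape[2], dtype=np.float64) * self.spacing[2]


@dataclasses.dataclass(frozen=True)
class Atlas:
    """A warped atlas: an intensity image paired with its binary label image."""

    id: str
    intensity: IntensityVolume
    label: LabelVolume

    def __post_init__(self) -> None:
        if self.intensity.shape != self.label.shape:
            raise VolumeShapeError(
                f"atlas {self.id!r}: intensity shape {self.intensity.shape} "
                f"!= label shape {self.label.shape}"
            )
        if not np.allclose(self.intensity.spacing, self.label.spacing):
            raise VolumeShapeError(
                f"atlas {self.id!r}: intensity and label spacing differ"
            )


def _load_nifti(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeShapeError(f"{path}: expected a 3-D image, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing  # type: ignore[return-value]


def read_volume(path: str | os.PathLike) -> IntensityVolume:
    """Read a 3-D NIfTI intensity image; spacing comes from the header zooms."""
    data, spacing = _load_nifti(path)
    return IntensityVolume(np.asarray(data, dtype=np.float64), spacing)


def read_label(path: str | os.PathLike, structure_code: int | None = None) -> LabelVolume:
    """Read a NIfTI label image.

    Parameters
    ----------
    structure_code
        When given, select this label code into a binary mask (multi-label
        files such as IBSR segmentations); otherwise the file must already
        be binary.
    """
    data, spacing = _load_nifti(path)
    if structure_code is not None:
        data = (np.asarray(data) == structure_code).astype(np.uint8)
    return LabelVolume(np.asarray(data), spacing)


def write_volume(vol: IntensityVolume | LabelVolume, path: str | os.PathLike,
                 descrip: str = "") -> None:
    """Write a volume as NIfTI-1; labels are stored as unsigned 8-bit voxels."""
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float64)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def binarize_label(vol: LabelVolume | np.ndarray, spacing=None,
                   structure_code: int = 1) -> LabelVolume:
    """Select one structure code of a (possibly multi-label) image into {0,1}."""
    if isinstance(vol, LabelVolume):
        return vol
    data = (np.asarray(vol) == structure_code).astype(np.uint8)
    return LabelVolume(data, spacing if spacing is not None else (1.0, 1.0, 1.0))


def normalize_intensity(vol: IntensityVolume,
                        mask: LabelVolume | np.ndarray | None = None) -> IntensityVolume:
    """Min–max rescale in-mask intensities to [0, 1]; out-of-mask voxels are 0.

    With no mask the foreground (nonzero voxels) is used.  Raises
    :class:`DegenerateRangeError` when the in-mask range is constant.
    """
    data = vol.data
    if mask is None:
        m = data != 0
    else:
        marr = mask.data if isinstance(mask, LabelVolume) else np.asarray(mask)
        if marr.shape != data.shape:
            raise VolumeShapeError("mask grid does not match the volume")
        m = marr.astype(bool)
    if not m.any():
        raise DegenerateRangeError("mask selects no voxels")
    lo = data[m].min()
    hi = data[m].max()
    if hi <= lo:
        raise DegenerateRangeError("constant in-mask intensities; cannot normalize")
    out = np.zeros_like(data)
    out[m] = (data[m] - lo) / (hi - lo)
    return IntensityVolume(out, vol.spacing)
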