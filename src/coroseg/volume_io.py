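"""NIfTI volume and label-map I/O with a fixed internal axis convention.

The in-memory convention is a 0-based ``(i, j, k)`` grid where axis ``k`` runs
inferior → superior, so ``data[:, :, k]`` is the k-th axial slice.  Volumes are
reoriented to the closest RAS-canonical orientation on load, which pins axis 2
to the superior direction; the halfway-plane construction of the classifier
relies on this.  Intensities are stored as 32-bit float, labels as unsigned
8-bit restricted to {0 background, 1 aortic root, 2 coronary artery}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import (
    HeaderError,
    InvalidLabelValueError,
    MissingFileError,
    NotA3DVolumeError,
    ShapeMismatchError,
)

VALID_LABELS = (0, 1, 2)


@dataclass
class IntensityVolume:
    """A 3D grid of Hounsfield-unit intensities with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise NotA3DVolumeError(
                f"intensity grid must be 3D, got {self.data.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise HeaderError(f"spacing must be three positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D integer grid over {0 background, 1 aortic root, 2 coronary}."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise NotA3DVolumeError(f"label grid must be 3D, got {arr.ndim}D")
        _check_label_values(arr)
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def paired_with(self, vol: IntensityVolume) -> None:
        """Raise unless this label map matches ``vol`` voxel-for-voxel."""
        if self.shape != vol.shape:
            raise ShapeMismatchError(
                f"label shape {self.shape} != intensity shape {vol.shape}"
            )


def _check_label_values(arr: np.ndarray) -> None:
    bad = np.setdiff1d(np.unique(arr), VALID_LABELS)
    if bad.size:
        raise InvalidLabelValueError(
            f"invalid label value {bad[0]!r}; labels must be in {set(VALID_LABELS)}"
        )


def _load_canonical(path) -> nib.Nifti1Image:
    if not os.path.exists(path):
        raise MissingFileError(f"no such file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several distinct types here
        raise HeaderError(f"unreadable image header in {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise NotA3DVolumeError(
            f"not a 3D volume: {path} has shape {tuple(img.shape)}"
        )
    # Reorient so data axis 2 points superior (axial index k).
    return nib.as_closest_canonical(img)


def read_volume(path) -> IntensityVolume:
    """Read a 3D NIfTI intensity image into the canonical (i, j, k) order."""
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return IntensityVolume(data=data, spacing=spacing)


def write_volume(vol: IntensityVolume, path) -> None:
    """Write an IntensityVolume as float32 NIfTI; round-trips exactly."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_labels(path) -> LabelVolume:
    """Read an integer-typed NIfTI label map; values must lie in {0, 1, 2}."""
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    _check_label_values(data)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(data=data.astype(np.uint8), spacing=spacing)


def write_labels(lv: LabelVolume, path) -> None:
    """Write a LabelVolume as uint8 NIfTI; round-trips exactly."""
    affine = np.diag(list(lv.spacing) + [1.0])
    img = nib.Nifti1Image(lv.data.astype(np.uint8), affine)
    img.header.set_zooms(lv.spacing)
    nib.save(img, str(path))
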