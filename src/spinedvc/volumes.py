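"""Greyscale volume container and file round-trip.

The whole pipeline operates on 3D scalar lattices with an isotropic voxel
size given in micrometres.  Array axes follow the study convention
``data[x, y, z]`` with

* ``x`` — left–right (increasing towards the specimen's right),
* ``y`` — posterior → anterior,
* ``z`` — caudal → cranial.

Supported on-disk formats are NIfTI (``.nii``/``.nii.gz``, via nibabel),
TIFF stacks (``.tif``/``.tiff``, via tifffile, stored slice-major as
``(z, y, x)``) and MetaImage (``.mhd``/``.mha``, via SimpleITK).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

DEFAULT_VOXEL_SIZE_UM = 39.0


@dataclass
class GreyVolume:
    """A 3D greyscale image with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities.  Finite values only.
    voxel_size : float
        Isotropic voxel edge length in micrometres (default 39 μm, the
        in vivo microCT protocol emulated by the phantom generator).
    """

    data: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def copy(self) -> "GreyVolume":
        return GreyVolume(self.data.copy(), self.voxel_size)

    def astype(self, dtype) -> "GreyVolume":
        return GreyVolume(self.data.astype(dtype), self.voxel_size)


@dataclass
class BinaryMask:
    """A boolean lattice tied to a volume's shape.

    ``role`` records what the mask delimits: ``body`` (whole vertebral
    body including the cortical shell), ``nocort`` (body minus shell, the
    morphometry VOI), ``scan_mask`` (merged registration mask) or
    ``voi_dvc`` (scan mask eroded to exclude boundary nodes).
    """

    data: np.ndarray
    role: str = "body"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())


def _nifti_affine(voxel_size_um: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_um / 1000.0  # NIfTI is mm
    return aff


def read_volume(path: str | os.PathLike) -> GreyVolume:
    """Read a volume from NIfTI, TIFF stack or MetaImage.

    The voxel size is recovered from the file header (mm converted back
    to μm for NIfTI/MetaImage); TIFF stacks carry no physical spacing, so
    the study default of 39 μm is assumed.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        return GreyVolume(data, float(zooms[0]) * 1000.0)
    if lower.endswith((".tif", ".tiff")):
        import tifffile

        stack = tifffile.imread(path)  # (z, y, x)
        if stack.ndim != 3:
            raise ValueError(f"TIFF stack in {path} is not 3D")
        return GreyVolume(np.ascontiguousarray(stack.transpose(2, 1, 0)))
    if lower.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        spacing = img.GetSpacing()[0]  # mm
        return GreyVolume(np.ascontiguousarray(data.transpose(2, 1, 0)), spacing * 1000.0)
    raise ValueError(f"unsupported volume format: {path}")


def write_volume(vol: GreyVolume, path: str | os.PathLike) -> None:
    """Write a volume; the format follows the file extension."""
    path = os.fspath(path)
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.Nifti1Image(np.asarray(vol.data), _nifti_affine(vol.voxel_size))
        img.header.set_zooms((vol.voxel_size / 1000.0,) * 3)
        nib.save(img, path)
        return
    if lower.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
        return
    if lower.endswith((".mhd", ".mha")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
        img.SetSpacing((vol.voxel_size / 1000.0,) * 3)
        sitk.WriteImage(img, path)
        return
    raise ValueError(f"unsupported volume format: {path}")


def read_mask(path: str | os.PathLike, role: str = "body") -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0.5, role=role)


def write_mask(mask: BinaryMask, path: str | os.PathLike,
               voxel_size: float = DEFAULT_VOXEL_SIZE_UM) -> None:
    write_volume(GreyVolume(mask.data.astype(np.uint8), voxel_size), path)
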