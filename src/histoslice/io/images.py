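"""Readers and writers for volumes (NIfTI) and photographs (PNG/TIFF)."""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import tifffile
from PIL import Image

from ..core import ImageDomain, TensorImage
from ..errors import ConfigurationError

__all__ = [
    "VolumeHandle",
    "load_volume",
    "save_volume",
    "load_photo",
    "save_photo",
    "LUMA_WEIGHTS",
]

#: ITU-R BT.601 luma weights used for grayscale conversion
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class VolumeHandle:
    """3-D data grid plus its voxel-to-physical affine (mm)."""

    data: np.ndarray
    affine: np.ndarray
    header: object = None

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ConfigurationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ConfigurationError("volume affine is not invertible")

    def to_tensor_image(self) -> TensorImage:
        domain = ImageDomain.from_affine(self.data.shape, self.affine)
        return TensorImage(np.asarray(self.data, dtype=float), domain)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def load_volume(path) -> VolumeHandle:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ConfigurationError(f"expected a 3-D volume, got shape {data.shape}")
    return VolumeHandle(data, img.affine, img.header)


def save_volume(handle_or_image, path):
    """Atomic NIfTI write (temp file + rename)."""
    if isinstance(handle_or_image, VolumeHandle):
        data, affine = handle_or_image.data, handle_or_image.affine
    else:
        img = handle_or_image
        affine = np.eye(4)
        member = img.domain.internal.members[0]
        affine[:3, :3] = member.matrix
        affine[:3, 3] = member.offset
        data = img.data
    tmp = str(path) + ".tmp.nii"
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), tmp)
    os.replace(tmp, str(path))


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        w = np.asarray(LUMA_WEIGHTS)
        return arr[..., :3] @ w
    raise ConfigurationError(f"unsupported photo shape {arr.shape}")


def load_photo(path, mm_per_pixel=None, grayscale: bool = True) -> TensorImage:
    """Load a PNG/TIFF photo, normalise to [0, 1] and attach resolution.

    Pixel (0, 0) is the top-left corner; axis 0 increases downward.  The
    image is never flipped or rotated on load."""
    if mm_per_pixel is None:
        raise ConfigurationError(
            "photographs carry no physical resolution; pass mm_per_pixel"
        )
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = np.asarray(tifffile.imread(path))
    else:
        arr = np.asarray(Image.open(path))
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if grayscale:
        arr = _to_grayscale(arr)
    return TensorImage(arr, resolution=float(mm_per_pixel))


def save_photo(image: TensorImage, path, bit_depth: int = 16):
    """Atomic 8/16-bit grayscale PNG/TIFF write with [0, 1] rescaling."""
    data = np.asarray(image.data, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    scale = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    if bit_depth == 8:
        out = (scale * 255).round().astype(np.uint8)
    elif bit_depth == 16:
        out = (scale * 65535).round().astype(np.uint16)
    else:
        raise ConfigurationError("bit_depth must be 8 or 16")
    path = str(path)
    tmp = path + ".tmp" + os.path.splitext(path)[1]
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(tmp, out)
    else:
        Image.fromarray(out).save(tmp, format="PNG")
    os.replace(tmp, path)
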