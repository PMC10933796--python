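"""FSL FLIRT matrix import/export.

FLIRT matrices act between *scaled-voxel* coordinates: voxel indices
multiplied by voxel size, with the x axis flipped (``x' = (nx-1-i) dx``)
for volumes whose voxel-to-world affine has positive determinant
(neurological orientation).  Import converts a FLIRT matrix into the
physical-mm affine of this package's convention so it can be appended to
a transformation chain.
"""

from __future__ import annotations

import numpy as np

from ..core import Affine3D
from ..errors import ConfigurationError
from .images import VolumeHandle

__all__ = ["import_flirt", "export_flirt", "read_flirt_matrix",
           "write_flirt_matrix"]


def read_flirt_matrix(path) -> np.ndarray:
    mat = np.loadtxt(path)
    if mat.shape != (4, 4):
        raise ConfigurationError(f"FLIRT matrix must be 4x4, got {mat.shape}")
    return mat


def write_flirt_matrix(mat: np.ndarray, path):
    np.savetxt(path, np.asarray(mat, dtype=float), fmt="%.10g")


def _scaled_voxel_transform(volume: VolumeHandle) -> np.ndarray:
    """Voxel-index -> FLIRT scaled-voxel coordinate homogeneous matrix."""
    sizes = volume.voxel_sizes
    mat = np.diag([sizes[0], sizes[1], sizes[2], 1.0])
    if np.linalg.det(volume.affine[:3, :3]) > 0:
        nx = volume.data.shape[0]
        mat[0, 0] = -sizes[0]
        mat[0, 3] = sizes[0] * (nx - 1)
    return mat


def _world_to_scaled(volume: VolumeHandle) -> np.ndarray:
    vox_to_world = volume.affine
    vox_to_scaled = _scaled_voxel_transform(volume)
    return vox_to_scaled @ np.linalg.inv(vox_to_world)


def import_flirt(matrix, source: VolumeHandle, target: VolumeHandle) -> Affine3D:
    """Convert a FLIRT source->target matrix into a physical-mm affine.

    The result maps source-volume world coordinates to target-volume
    world coordinates, suitable for appending after a chain that ends in
    the source volume's physical space."""
    if isinstance(matrix, (str, bytes)) or hasattr(matrix, "__fspath__"):
        matrix = read_flirt_matrix(matrix)
    mat = np.asarray(matrix, dtype=float)
    if mat.shape != (4, 4):
        raise ConfigurationError("FLIRT matrix must be 4x4")
    if abs(np.linalg.det(mat[:3, :3])) < 1e-12:
        raise ConfigurationError("FLIRT matrix is not invertible")
    src = _world_to_scaled(source)
    tgt = _world_to_scaled(target)
    world = np.linalg.inv(tgt) @ mat @ src
    return Affine3D.from_homogeneous(world)


def export_flirt(affine: Affine3D, source: VolumeHandle,
                 target: VolumeHandle) -> np.ndarray:
    """Inverse of :func:`import_flirt` (world-mm affine -> FLIRT matrix)."""
    src = _world_to_scaled(source)
    tgt = _world_to_scaled(target)
    return tgt @ affine.homogeneous @ np.linalg.inv(src)
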