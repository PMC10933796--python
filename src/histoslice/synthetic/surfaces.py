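"""Analytically defined slice surfaces and pose perturbation.

A slice surface is ``z = f(u, v)`` in a tilted slab frame: the frame is
the volume frame rotated by the surface's tilt angles, with the origin at
``base + offset * normal``.  Order-1 surfaces are planes (f = 0); order-2
surfaces add a bounded quadratic deflection along the normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from ..core import (
    Embed2Dto3D,
    ImageDomain,
    Rotation3D,
    TensorImage,
    TransformChain,
    Translation,
    euler_matrix,
    euler_angles_from_matrix,
)
from ..errors import ConfigurationError
from .phantom import PhantomTruth

__all__ = ["SliceSurface", "sample_surface_slices", "perturb_pose"]


@dataclass
class SliceSurface:
    """Planar (order 1) or quadratic (order 2) slice surface.

    ``coefficients`` are ``(c_uu, c_uv, c_vv)`` of
    ``f(u, v) = c_uu u^2 + c_uv u v + c_vv v^2`` (mm input, mm output);
    ``tilt`` are Euler angles (degrees) rotating the base slab frame;
    ``offset`` shifts the surface along its normal (mm)."""

    order: int = 1
    coefficients: tuple = (0.0, 0.0, 0.0)
    tilt: tuple = (0.0, 0.0, 0.0)
    offset: float = 0.0
    max_deflection: float = 3.0

    def __post_init__(self):
        if self.order not in (1, 2):
            raise ConfigurationError("surface order must be 1 or 2")
        if self.order == 1:
            self.coefficients = (0.0, 0.0, 0.0)

    def deflection(self, u, v):
        cuu, cuv, cvv = self.coefficients
        return cuu * u**2 + cuv * u * v + cvv * v**2

    def check_deflection(self, half_extent):
        hu, hv = half_extent
        uu = np.linspace(-hu, hu, 101)
        vv = np.linspace(-hv, hv, 101)
        grid = np.abs(self.deflection(uu[:, None], vv[None, :]))
        peak = float(grid.max())
        if peak > self.max_deflection:
            raise ConfigurationError(
                f"surface deflection {peak:.2f} mm exceeds the stated "
                f"maximum {self.max_deflection} mm"
            )
        return peak

    def frame(self):
        """Rotation matrix whose columns are (e_u, e_v, normal) expressed
        in volume axes.  The base slab frame maps u, v to volume axes 1
        and 2 and the normal to axis 0."""
        rot = euler_matrix(self.tilt)
        base = np.array([
            [0.0, 0.0, 1.0],
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
        ])
        return rot @ base


def sample_surface_slices(volume: TensorImage, surfaces, spacing: float = 10.0,
                          centre=None, slice_shape=None, resolution=None,
                          interpolation_order: int = 1):
    """Resample a volume onto a series of analytic surfaces.

    Surfaces with ``offset == 0`` are distributed symmetrically at
    ``spacing`` millimetres along the (untilted) slab normal; explicit
    offsets win.  Returns a list of ``(slice_image, truth)`` pairs where
    ``truth.points`` holds the exact mm position of every slice pixel in
    the volume frame and, for planar surfaces, ``truth.chain`` is the
    exact slice-to-volume chain."""
    surfaces = list(surfaces)
    if centre is None:
        centre = np.zeros(3)
    centre = np.asarray(centre, dtype=float)
    res = float(resolution if resolution is not None else max(volume.resolution))
    if slice_shape is None:
        extent = (np.asarray(volume.shape)[1:] * volume.resolution[1:]) * 0.75
        slice_shape = tuple(int(round(e / res)) for e in extent)

    offsets = [s.offset for s in surfaces]
    if all(o == 0.0 for o in offsets) and len(surfaces) > 1:
        k = len(surfaces)
        offsets = [(i - (k - 1) / 2.0) * spacing for i in range(k)]

    out = []
    vol_half = (np.asarray(volume.shape) - 1) / 2.0 * volume.resolution
    for surf, off in zip(surfaces, offsets):
        frame = surf.frame()
        e_u, e_v, normal = frame[:, 0], frame[:, 1], frame[:, 2]
        base = centre + off * normal
        domain = ImageDomain.centred(slice_shape, res)
        uv = domain.physical_points(external=False)
        half_extent = ((slice_shape[0] - 1) / 2.0 * res,
                       (slice_shape[1] - 1) / 2.0 * res)
        surf.check_deflection(half_extent)
        z = surf.deflection(uv[:, 0], uv[:, 1])
        pts = base + uv[:, 0, None] * e_u + uv[:, 1, None] * e_v + z[:, None] * normal
        if np.any(np.abs(pts) > vol_half + 1e-6):
            raise ConfigurationError(
                f"surface at offset {off} mm exits the volume extent"
            )
        idx = volume.domain.physical_to_index(pts, external=False)
        from ..core.image import snap_coords
        idx = snap_coords(idx)
        data = map_coordinates(volume.data, idx.T, order=interpolation_order,
                               mode="nearest").reshape(slice_shape)
        image = TensorImage(data, domain)
        chain = None
        if surf.order == 1:
            chain = TransformChain([
                Embed2Dto3D(),
                Rotation3D(euler_angles_from_matrix(frame), centre=(0.0, 0.0, 0.0)),
                Translation(base),
            ])
        truth = PhantomTruth(
            chain=chain,
            points=pts.reshape(slice_shape + (3,)),
            meta={"surface": surf, "offset": off, "frame": frame,
                  "base": base, "centre": centre},
        )
        out.append((image, truth))
    return out


def perturb_pose(chain: TransformChain, rotation_range_deg: float = 0.0,
                 inplane_range_mm: float = 0.0, normal_range_mm: float = 0.0,
                 seed: int = 0) -> TransformChain:
    """Seeded uniform perturbation of the rigid part of a slice chain.

    Rotation angles receive uniform draws in ``+/-rotation_range_deg``;
    the 3-D translation is shifted by uniform in-plane components and a
    uniform offset along the slice normal (the rotated z axis).  Zero
    ranges leave the chain unchanged."""
    for r in (rotation_range_deg, inplane_range_mm, normal_range_mm):
        if r < 0:
            raise ConfigurationError("perturbation ranges must be non-negative")
    rng = np.random.default_rng(seed)
    out = chain.copy()
    rot = next((m for m in out if isinstance(m, Rotation3D)), None)
    tra = next(
        (m for m in out if isinstance(m, Translation) and m.offset.size == 3), None
    )
    if rot is None or tra is None:
        raise ConfigurationError("chain has no 3-D rigid part to perturb")
    frame = rot.matrix  # columns: slice axes in volume space
    d_rot = rng.uniform(-rotation_range_deg, rotation_range_deg, 3)
    d_in = rng.uniform(-inplane_range_mm, inplane_range_mm, 2)
    d_n = rng.uniform(-normal_range_mm, normal_range_mm)
    rot.angles = rot.angles + d_rot
    tra.offset = (
        tra.offset + d_in[0] * frame[:, 0] + d_in[1] * frame[:, 1] + d_n * frame[:, 2]
    )
    return out
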