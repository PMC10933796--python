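"""Image containers and grid-level operations.

An :class:`ImageDomain` couples a pixel/voxel grid with two transformation
chains: the *internal* chain is fixed and encodes resolution and padding
offsets (grid index -> physical mm); the *external* chain holds the
optimisable transformations attached during registration.  Grid indices
are 0-based and pixel-centred; array axis order is preserved throughout.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from ..errors import ConfigurationError
from .chain import TransformChain
from .transforms import Affine2D, Affine3D, Translation

__all__ = [
    "ImageDomain",
    "TensorImage",
    "resample",
    "gaussian_downsample",
    "pad_image",
    "FWHM_TO_SIGMA",
]

#: FWHM / sigma ratio of a Gaussian: sqrt(8 ln 2)
FWHM_TO_SIGMA = math.sqrt(8.0 * math.log(2.0))

_ORDER = {"nearest": 0, "linear": 1, "spline": 3}


def snap_coords(coords: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Snap near-integer sampling coordinates to exact integers.

    Guards against floating-point drift pushing on-grid samples across
    interpolation-boundary thresholds (and makes identity resampling
    bit-exact)."""
    rounded = np.round(coords)
    return np.where(np.abs(coords - rounded) < tol, rounded, coords)


def _diag_affine(resolution, offset):
    resolution = np.asarray(resolution, dtype=float)
    d = resolution.size
    cls = {2: Affine2D, 3: Affine3D}.get(d)
    if cls is None:
        raise ConfigurationError(f"unsupported dimensionality {d}")
    return cls(np.diag(resolution), offset)


class ImageDomain:
    """Grid shape plus internal (fixed) and external (optimisable) chains."""

    def __init__(self, shape, internal: TransformChain, external: TransformChain | None = None,
                 resolution=None):
        self.shape = tuple(int(s) for s in shape)
        if any(s <= 0 for s in self.shape):
            raise ConfigurationError(f"invalid domain shape {self.shape}")
        self.internal = internal
        self.external = external if external is not None else TransformChain()
        if resolution is None:
            resolution = self._infer_resolution()
        self.resolution = np.asarray(resolution, dtype=float).ravel()
        self._grid_cache = None

    def _infer_resolution(self):
        d = len(self.shape)
        jac = self.internal.jacobian(np.zeros((1, d)))[0]
        return np.sqrt((jac**2).sum(axis=0))

    @classmethod
    def centred(cls, shape, resolution) -> "ImageDomain":
        """Domain whose geometric centre sits at the physical origin."""
        shape = tuple(int(s) for s in shape)
        res = np.broadcast_to(np.asarray(resolution, dtype=float).ravel(), (len(shape),))
        offset = -(np.asarray(shape, dtype=float) - 1.0) / 2.0 * res
        return cls(shape, TransformChain([_diag_affine(res, offset)]), resolution=res)

    @classmethod
    def from_affine(cls, shape, affine4x4) -> "ImageDomain":
        """3-D domain with a NIfTI-style voxel-to-mm homogeneous affine."""
        aff = np.asarray(affine4x4, dtype=float)
        member = Affine3D(aff[:3, :3], aff[:3, 3])
        res = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
        return cls(shape, TransformChain([member]), resolution=res)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def full_chain(self) -> TransformChain:
        return self.internal + self.external

    def grid_indices(self) -> np.ndarray:
        if self._grid_cache is None or self._grid_cache.shape[0] != int(np.prod(self.shape)):
            axes = [np.arange(s, dtype=float) for s in self.shape]
            mesh = np.meshgrid(*axes, indexing="ij")
            self._grid_cache = np.stack([m.ravel() for m in mesh], axis=1)
        return self._grid_cache

    def physical_points(self, external: bool = True) -> np.ndarray:
        chain = self.full_chain() if external else self.internal
        return chain.apply(self.grid_indices())

    def index_to_physical(self, indices, external: bool = True) -> np.ndarray:
        chain = self.full_chain() if external else self.internal
        return chain.apply(indices)

    def physical_to_index(self, points, external: bool = True) -> np.ndarray:
        chain = self.full_chain() if external else self.internal
        return chain.inverse_apply(points)

    def centre_physical(self) -> np.ndarray:
        centre_idx = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.internal.apply(centre_idx[None])[0]

    def copy(self, external: TransformChain | None = None) -> "ImageDomain":
        return ImageDomain(
            self.shape,
            self.internal.copy(),
            self.external.copy() if external is None else external,
            resolution=self.resolution.copy(),
        )

    def __repr__(self):  # pragma: no cover
        return f"ImageDomain(shape={self.shape}, res={self.resolution})"


class TensorImage:
    """Gridded scalar (or vector) image with mm resolution, optional mask
    and an attached transformation chain (via its domain)."""

    def __init__(self, data, domain: ImageDomain | None = None, mask=None,
                 resolution=None, vector: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.vector = bool(vector)
        spatial = self.data.shape[:-1] if vector else self.data.shape
        if domain is None:
            if resolution is None:
                raise ConfigurationError("either domain or resolution required")
            domain = ImageDomain.centred(spatial, resolution)
        if tuple(spatial) != tuple(domain.shape):
            raise ConfigurationError(
                f"data shape {spatial} does not match domain shape {domain.shape}"
            )
        self.domain = domain
        if mask is not None:
            mask = np.asarray(mask, dtype=float)
            if mask.shape != tuple(spatial):
                raise ConfigurationError("mask shape does not match image shape")
        self.mask = mask

    @property
    def shape(self):
        return self.domain.shape

    @property
    def resolution(self):
        return self.domain.resolution

    @property
    def chain(self) -> TransformChain:
        return self.domain.external

    @chain.setter
    def chain(self, value: TransformChain):
        self.domain.external = value

    def copy(self) -> "TensorImage":
        return TensorImage(
            self.data.copy(),
            self.domain.copy(),
            None if self.mask is None else self.mask.copy(),
            vector=self.vector,
        )

    def foreground_mask(self, relative_threshold: float = 0.1) -> np.ndarray:
        """Binary mask of pixels above a fraction of the image maximum."""
        peak = float(self.data.max())
        if peak <= 0:
            return np.zeros(self.shape, dtype=bool)
        return self.data > relative_threshold * peak

    def __repr__(self):  # pragma: no cover
        return f"TensorImage(shape={self.shape}, res={self.resolution})"


def resample(source: TensorImage, target_domain: ImageDomain,
             interpolation: str = "linear", fill: float = 0.0,
             mapping=None) -> TensorImage:
    """Sample ``source`` on the grid of ``target_domain``.

    Each target grid index is pushed to physical mm through the target's
    full chain, then pulled back to source grid coordinates through the
    inverse of the source's full chain (or a supplied ``mapping`` from
    physical mm to source grid indices).
    """
    try:
        order = _ORDER[interpolation]
    except KeyError:
        raise ConfigurationError(f"unknown interpolation '{interpolation}'") from None
    phys = target_domain.physical_points()
    if not np.all(np.isfinite(phys)):
        raise ConfigurationError("target chain produced non-finite coordinates")
    if mapping is None:
        coords = source.domain.physical_to_index(phys)
    else:
        coords = np.asarray(mapping(phys), dtype=float)
    if order <= 1:
        coords = snap_coords(coords)
    data = map_coordinates(
        source.data, coords.T, order=order, mode="constant", cval=fill
    ).reshape(target_domain.shape)
    mask = None
    if source.mask is not None:
        mask = map_coordinates(
            source.mask, coords.T, order=min(order, 1), mode="constant", cval=0.0
        ).reshape(target_domain.shape)
    return TensorImage(data, target_domain.copy(), mask)


def gaussian_downsample(image: TensorImage, fwhm: float,
                        target_resolution) -> TensorImage:
    """Gaussian smoothing (sigma = FWHM / sqrt(8 ln 2), reflect boundary)
    followed by resampling onto a coarser grid covering the same physical
    extent.  The external chain is carried over unchanged."""
    if fwhm <= 0:
        raise ConfigurationError("fwhm must be positive")
    src_res = image.resolution
    tgt_res = np.broadcast_to(
        np.asarray(target_resolution, dtype=float).ravel(), src_res.shape
    )
    if np.any(tgt_res < src_res - 1e-12):
        raise ConfigurationError(
            "target resolution finer than source; upsampling is not "
            "this operation's contract"
        )
    sigma = fwhm / FWHM_TO_SIGMA
    # zero-background boundary: photographs live on a black background, so
    # smoothing against zero keeps padded and unpadded copies of the same
    # scene consistent
    smoothed = gaussian_filter(image.data, sigma=sigma, mode="constant", cval=0.0)
    new_shape = tuple(
        max(1, int(round(s * r / t)))
        for s, r, t in zip(image.shape, src_res, tgt_res)
    )
    centre = image.domain.centre_physical()
    offset = centre - (np.asarray(new_shape, dtype=float) - 1.0) / 2.0 * tgt_res
    # snap the new grid onto the lattice of multiples of the target
    # resolution, so independently downsampled images share sample
    # positions exactly (alignment cost of an identical pair is ~0)
    offset = tgt_res * np.round(offset / tgt_res)
    internal = TransformChain([_diag_affine(tgt_res, offset)])
    new_domain = ImageDomain(new_shape, internal, image.domain.external.copy(),
                             resolution=tgt_res)
    coords = image.domain.physical_to_index(
        new_domain.index_to_physical(new_domain.grid_indices(), external=False),
        external=False,
    )
    coords = snap_coords(coords)
    data = map_coordinates(smoothed, coords.T, order=1, mode="constant",
                           cval=0.0).reshape(new_shape)
    mask = None
    if image.mask is not None:
        mask = map_coordinates(
            image.mask, coords.T, order=1, mode="constant", cval=0.0
        ).reshape(new_shape)
    return TensorImage(data, new_domain, mask)


def pad_image(image: TensorImage, fraction_per_edge: float,
              value: float = 0.0) -> TensorImage:
    """Pad every spatial edge by ``round(fraction * dim)`` pixels.

    The internal chain is shifted so that pre-existing pixels keep their
    physical coordinates exactly; masks are padded with zeros."""
    if fraction_per_edge < 0:
        raise ConfigurationError("padding fraction must be non-negative")
    pads = [int(round(fraction_per_edge * s)) for s in image.shape]
    if all(p == 0 for p in pads):
        return image.copy()
    pad_spec = [(p, p) for p in pads]
    data = np.pad(image.data, pad_spec, constant_values=value)
    internal = TransformChain(
        [Translation([-float(p) for p in pads])] + image.domain.internal.copy().members
    )
    domain = ImageDomain(data.shape, internal, image.domain.external.copy(),
                         resolution=image.resolution.copy())
    mask = None
    if image.mask is not None:
        mask = np.pad(image.mask, pad_spec, constant_values=0.0)
    return TensorImage(data, domain, mask)
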