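"""Modality-independent neighbourhood descriptors and the registration
cost built on them.

For a 2-D image the descriptor at pixel ``x`` is the 8-vector

    M_r(x) = exp(-Dp(x, x + r) / V(x)),   r in the 8 immediate neighbours,

where ``Dp`` is the patch-based squared intensity distance (3x3 uniform
patch by default) and ``V(x)`` a local variance estimate (mean of the 8
patch distances, floored).  Each descriptor is rescaled so its largest
component equals 1, which makes it exactly invariant to positive affine
intensity rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from ..core import ImageDomain, TensorImage, resample
from ..errors import ConfigurationError, DegenerateInputError

__all__ = ["MINDImage", "mind_descriptor", "mind_cost", "NEIGHBOUR_OFFSETS"]

#: the 8 immediate-neighbour offsets (2-D), row-major order
NEIGHBOUR_OFFSETS = tuple(
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
)

#: variance floor, as a fraction of the squared image intensity range
VARIANCE_FLOOR_FRACTION = 1e-6


@dataclass
class MINDImage:
    """Per-pixel descriptor stack with a validity mask.

    ``descriptors`` has shape ``(H, W, 8)``; ``valid`` flags pixels whose
    full descriptor neighbourhood lies inside the image."""

    descriptors: np.ndarray
    valid: np.ndarray
    domain: ImageDomain | None = None
    weights: np.ndarray | None = field(default=None)

    @property
    def n_components(self) -> int:
        return self.descriptors.shape[-1]


def _shift(padded: np.ndarray, dy: int, dx: int, shape) -> np.ndarray:
    h, w = shape
    return padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]


def mind_descriptor(image, mask=None, patch_size: int = 3) -> MINDImage:
    """Compute the 8-component MIND stack of a single-channel 2-D image.

    ``image`` may be a :class:`TensorImage` or a plain 2-D array.  Masked
    or border pixels are flagged invalid and excluded from costs."""
    domain = None
    weights = None
    if isinstance(image, TensorImage):
        domain = image.domain
        if mask is None:
            mask = image.mask
        data = image.data
    else:
        data = np.asarray(image, dtype=float)
    if data.ndim != 2:
        raise ConfigurationError("MIND descriptor requires a 2-D scalar image")
    if min(data.shape) < 3:
        raise ConfigurationError("image must have at least 3 pixels per axis")

    padded = np.pad(data, 1, mode="reflect")
    dp = np.empty(data.shape + (len(NEIGHBOUR_OFFSETS),))
    for k, (dy, dx) in enumerate(NEIGHBOUR_OFFSETS):
        diff2 = (data - _shift(padded, dy, dx, data.shape)) ** 2
        dp[..., k] = uniform_filter(diff2, size=patch_size, mode="reflect")

    rng = float(data.max() - data.min())
    floor = max(VARIANCE_FLOOR_FRACTION * rng**2, np.finfo(float).tiny)
    variance = np.maximum(dp.mean(axis=-1), floor)
    desc = np.exp(-dp / variance[..., None])
    desc /= desc.max(axis=-1, keepdims=True)

    valid = np.zeros(data.shape, dtype=bool)
    valid[2:-2, 2:-2] = True
    if mask is not None:
        weights = np.asarray(mask, dtype=float)
        valid &= weights > 0
    return MINDImage(desc, valid, domain, weights)


def mind_cost(fixed: MINDImage, moving: TensorImage,
              evaluation_domain: ImageDomain | None = None,
              mask=None, reduction: str = "mean",
              return_residuals: bool = False):
    """MIND dissimilarity between a fixed descriptor image and a moving
    intensity image pulled through its chain.

    The moving image is resampled onto ``evaluation_domain`` (default:
    the fixed image's domain, whose external chain holds the current
    transformation), its descriptors are recomputed on the resampled grid
    and compared with the fixed descriptors by pixelwise Euclidean
    distance.  With ``reduction='mean'`` the result is normalised by the
    unmasked pixel count so pyramid levels are comparable; ``'sum'``
    reproduces the raw summed distance."""
    if evaluation_domain is None:
        if fixed.domain is None:
            raise ConfigurationError("no evaluation domain available")
        evaluation_domain = fixed.domain
    warped = resample(moving, evaluation_domain, "linear")
    moving_mind = mind_descriptor(warped)

    weights = (fixed.valid & moving_mind.valid).astype(float)
    if fixed.weights is not None:
        weights *= fixed.weights
    if moving_mind.weights is not None:
        weights *= moving_mind.weights
    if mask is not None:
        weights *= np.asarray(mask, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise DegenerateInputError("empty unmasked overlap between images")

    dist = np.sqrt(((fixed.descriptors - moving_mind.descriptors) ** 2).sum(-1))
    if reduction == "mean":
        value = float((dist * weights).sum() / total)
    elif reduction == "sum":
        value = float((dist * weights).sum())
    else:
        raise ConfigurationError(f"unknown reduction '{reduction}'")
    if return_residuals:
        return value, dist, weights
    return value


def descriptor_distance(a: MINDImage, b: MINDImage, mask=None,
                        reduction: str = "mean") -> float:
    """Distance between two descriptor stacks already on the same grid."""
    weights = (a.valid & b.valid).astype(float)
    for m in (a.weights, b.weights, mask):
        if m is not None:
            weights = weights * np.asarray(m, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise DegenerateInputError("empty unmasked overlap between images")
    dist = np.sqrt(((a.descriptors - b.descriptors) ** 2).sum(-1))
    if reduction == "mean":
        return float((dist * weights).sum() / total)
    return float((dist * weights).sum())
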