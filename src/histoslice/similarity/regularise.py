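"""Diffusion regularisation of displacement fields."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import DenseDisplacementField
from ..errors import ConfigurationError

__all__ = ["RegularisationSpec", "diffusion_penalty"]


@dataclass
class RegularisationSpec:
    """Relative weight of the diffusion term in the non-linear cost."""

    alpha: float = 0.35

    def __post_init__(self):
        if self.alpha < 0:
            raise ConfigurationError("alpha must be non-negative")


def diffusion_penalty(field, spec: RegularisationSpec, spacing=None):
    """Squared-forward-difference penalty on a displacement field.

    Returns ``(value, gradient)`` where

        value = alpha * sum_{axes a, components c, pixels}
                ((u_c[i + e_a] - u_c[i]) / h_a)^2

    and ``gradient`` is d(value)/d(u), same shape as the field vectors.
    Spatially constant fields score zero.
    """
    if isinstance(field, DenseDisplacementField):
        vectors = field.vectors
        spacing = field.spacing if spacing is None else np.asarray(spacing, float)
    else:
        vectors = np.asarray(field, dtype=float)
        if spacing is None:
            spacing = np.ones(vectors.ndim - 1)
        spacing = np.broadcast_to(np.asarray(spacing, float).ravel(),
                                  (vectors.ndim - 1,))
    ndim = vectors.ndim - 1
    value = 0.0
    grad = np.zeros_like(vectors)
    for a in range(ndim):
        d = np.diff(vectors, axis=a) / spacing[a]
        value += float((d**2).sum())
        contrib = 2.0 * d / spacing[a]
        lo = [slice(None)] * (ndim + 1)
        hi = [slice(None)] * (ndim + 1)
        lo[a] = slice(0, -1)
        hi[a] = slice(1, None)
        grad[tuple(hi)] += contrib
        grad[tuple(lo)] -= contrib
    return spec.alpha * value, spec.alpha * grad
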