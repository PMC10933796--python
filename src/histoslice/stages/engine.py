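"""Shared cost-evaluation machinery for the stage drivers.

A :class:`ChainEvaluator` scores a transformation chain by pulling the
fixed image (photo or volume) onto the moving image's grid through the
chain and comparing MIND descriptors.  The moving image's descriptors are
cached per pyramid level; the warped fixed descriptors are recomputed at
every evaluation (resample-then-describe).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import map_coordinates

from ..core import TensorImage, TransformChain
from ..core.image import snap_coords
from ..errors import DegenerateInputError
from ..similarity import mind_descriptor
from ..optim import at_resolution

__all__ = ["ChainEvaluator", "safe_cost"]

log = logging.getLogger("histoslice.stages")


class ChainEvaluator:
    """MIND cost of a chain mapping the moving grid into the fixed frame.

    ``moving`` is 2-D; ``fixed`` may be 2-D or 3-D (its full chain maps
    grid indices to the common physical frame).  ``resolution`` sets the
    working pyramid level for the moving side."""

    def __init__(self, moving: TensorImage, fixed: TensorImage,
                 resolution: float, moving_mask=None, fixed_mask=None,
                 reduction: str = "mean"):
        # both sides are brought to the working resolution so that a
        # perfectly aligned pair scores (near) zero at every level
        if fixed_mask is not None:
            fixed = TensorImage(fixed.data, fixed.domain.copy(),
                                np.asarray(fixed_mask, float))
        self.fixed = at_resolution(fixed, resolution)
        fixed_mask = self.fixed.mask
        self.reduction = reduction
        mov = moving if moving_mask is None else TensorImage(
            moving.data, moving.domain.copy(), np.asarray(moving_mask, float)
        )
        self.moving = at_resolution(mov, resolution)
        self.mind_moving = mind_descriptor(self.moving)
        self.grid_phys = self.moving.domain.physical_points(external=False)
        self.base_weight = self.mind_moving.valid.astype(float)
        if self.moving.mask is not None:
            self.base_weight *= self.moving.mask
        self._fixed_mask = fixed_mask
        self._fixed_shape = np.asarray(self.fixed.shape, dtype=float)

    @property
    def shape(self):
        return self.moving.shape

    def warp_fixed(self, chain: TransformChain):
        """Fixed image sampled on the moving grid through ``chain``."""
        target = chain.apply(self.grid_phys)
        idx = snap_coords(self.fixed.domain.physical_to_index(target))
        inb = np.all(
            (idx >= -0.5) & (idx <= self._fixed_shape - 0.5), axis=1
        ).reshape(self.shape)
        data = map_coordinates(
            self.fixed.data, idx.T, order=1, mode="constant", cval=0.0
        ).reshape(self.shape)
        weight = inb.astype(float)
        if self._fixed_mask is not None:
            weight *= map_coordinates(
                np.asarray(self._fixed_mask, dtype=float), idx.T, order=1,
                mode="constant", cval=0.0,
            ).reshape(self.shape)
        return data, weight

    def cost(self, chain: TransformChain) -> float:
        data, fixed_weight = self.warp_fixed(chain)
        warped_mind = mind_descriptor(data)
        weight = self.base_weight * fixed_weight * warped_mind.valid
        total = weight.sum()
        if total <= 0:
            raise DegenerateInputError("empty unmasked overlap (degenerate pose)")
        dist = np.sqrt(
            ((self.mind_moving.descriptors - warped_mind.descriptors) ** 2).sum(-1)
        )
        if self.reduction == "sum":
            return float((dist * weight).sum())
        return float((dist * weight).sum() / total)


def safe_cost(evaluator: ChainEvaluator, chain: TransformChain) -> float:
    """Evaluator cost with degenerate poses mapped to +inf (so bounded
    optimisers and grid searches can skip them)."""
    try:
        return evaluator.cost(chain)
    except DegenerateInputError:
        return float("inf")
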