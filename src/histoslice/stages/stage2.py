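"""Stage 2: block-to-slab registration with automatic site matching.

The block is initialised at every candidate sampling site over a grid of
rotations and translations; the best few initialisations per site are
refined by bounded minimisation, the global winner fixes the sampling-site
offset and starting rotation, and registration then proceeds through the
stage-1 rigid/affine/non-linear sequence with automatic 10%-threshold
masks on both inputs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from ..core import (
    Affine2D,
    IsotropicScale,
    Rotation2D,
    TensorImage,
    TransformChain,
    Translation,
)
from ..errors import DegenerateInputError
from ..optim import OptimisationGroup, bounded_minimise, grid_search_rank
from .config import Stage2Config
from .engine import ChainEvaluator, safe_cost
from .sites import SamplingSite
from .stage1 import linear_registration, nonlinear_registration

__all__ = ["Stage2Result", "stage2_register"]

log = logging.getLogger("histoslice.stages")


@dataclass
class Stage2Result:
    chain: TransformChain
    site: SamplingSite
    cost_trace: list = field(default_factory=list)
    initial_cost: float = np.nan
    final_cost: float = np.nan
    site_costs: list = field(default_factory=list)


def _auto_mask(image: TensorImage, threshold: float) -> np.ndarray:
    return image.foreground_mask(threshold).astype(float)


def stage2_register(block_photo: TensorImage, slab_photo: TensorImage,
                    sites, config: Stage2Config | None = None) -> Stage2Result:
    """Register a tissue-block photo onto a slab photo given candidate
    sampling sites; returns the optimised chain and the chosen site."""
    config = config or Stage2Config()
    sites = list(sites)
    if not sites:
        raise DegenerateInputError("no sampling sites supplied")

    block_mask = _auto_mask(block_photo, config.mask_threshold)
    slab_mask = _auto_mask(slab_photo, config.mask_threshold)

    chain = TransformChain([
        Rotation2D(0.0, centre=(0.0, 0.0)),
        IsotropicScale(1.0),
        Translation((0.0, 0.0)),   # fixed sampling-site offset
        Translation((0.0, 0.0)),   # variable translation
        Affine2D(),
    ])
    rot, _, site_offset, var_trans, _ = chain.members

    coarse = ChainEvaluator(block_photo, slab_photo, config.grid_resolution,
                            block_mask, slab_mask)

    angles = np.arange(0.0, 360.0, config.rotation_step)
    shifts = np.arange(-config.translation_range,
                       config.translation_range + 1e-9, config.translation_step)
    grid = [(a, dy, dx) for a in angles for dy in shifts for dx in shifts]

    def init_cost(params):
        a, dy, dx = params
        rot.angle = float(a)
        var_trans.offset = np.array([dy, dx])
        return safe_cost(coarse, chain)

    site_best = []
    for si, site in enumerate(sites):
        site_offset.offset = np.asarray(site.centroid, dtype=float)
        top = grid_search_rank(grid, init_cost, keep=config.refine_keep)
        refined = []
        for cand in top:
            a, dy, dx = cand.parameters

            def refine_cost(x):
                rot.angle = float(x[0])
                var_trans.offset = np.array([x[1], x[2]])
                return safe_cost(coarse, chain)

            group = OptimisationGroup(
                initial=[a, dy, dx],
                lower=[a - config.rotation_step, dy - config.translation_step,
                       dx - config.translation_step],
                upper=[a + config.rotation_step, dy + config.translation_step,
                       dx + config.translation_step],
                tolerance=config.tolerance,
            )
            best, cost = bounded_minimise(refine_cost, group)
            refined.append((cost, best))
        refined.sort(key=lambda t: t[0])
        site_best.append((refined[0][0], si, refined[0][1]))
        log.info("site %d: best initialisation cost %.5f", si, refined[0][0])

    finite = [t for t in site_best if np.isfinite(t[0])]
    if not finite:
        raise DegenerateInputError(
            "all-site initialisation non-finite; per-site best costs: "
            + ", ".join(f"{c:.4g}" for c, _, _ in site_best)
        )
    best_cost, best_si, best_params = min(finite, key=lambda t: (t[0], t[1]))
    chosen = sites[best_si]
    site_offset.offset = np.asarray(chosen.centroid, dtype=float)
    rot.angle = float(best_params[0])
    var_trans.offset = np.asarray(best_params[1:])

    trace = [("initialisation", best_cost)]
    fine_eval = ChainEvaluator(block_photo, slab_photo, min(config.pyramid),
                               block_mask, slab_mask)
    initial_cost = safe_cost(fine_eval, chain)
    linear_registration(block_photo, slab_photo, chain, config,
                        block_mask, slab_mask, trace, rotation_search=False)
    nonlinear_registration(block_photo, slab_photo, chain, config.alpha,
                           config.pyramid, config.max_gn_iterations,
                           block_mask, slab_mask)
    final_cost = safe_cost(fine_eval, chain)
    trace.append(("nonlinear", final_cost))
    log.info("stage2 cost trace: %s", trace)
    return Stage2Result(chain, chosen, trace, initial_cost, final_cost,
                        [(c, i) for c, i, _ in site_best])
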