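"""Stage 1: deformable registration of a histology image to a tissue
block photograph.

The histology image is downsampled to the block resolution, padded,
centre-aligned with the block and registered through three linear steps
(rotation search, similarity, affine) followed by diffusion-regularised
Gauss-Newton optimisation of a dense displacement field, all under the
MIND cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..core import (
    Affine2D,
    IsotropicScale,
    ParameterSelector,
    Rotation2D,
    TensorImage,
    TransformChain,
    Translation,
    gaussian_downsample,
    pad_image,
    resample,
)
from ..errors import DegenerateInputError
from ..optim import (
    OptimisationGroup,
    PyramidSchedule,
    bounded_minimise,
    gauss_newton_field,
    grid_search_rank,
)
from ..similarity import RegularisationSpec
from .config import Stage1Config
from .engine import ChainEvaluator, safe_cost

__all__ = ["Stage1Result", "stage1_register", "preprocess_histology",
           "linear_registration", "nonlinear_registration"]

log = logging.getLogger("histoslice.stages")


@dataclass
class Stage1Result:
    chain: TransformChain
    cost_trace: list = field(default_factory=list)
    initial_cost: float = np.nan
    final_cost: float = np.nan


def preprocess_histology(histology: TensorImage, block: TensorImage,
                         config: Stage1Config) -> TensorImage:
    """Downsample the histology image to the block resolution (Gaussian
    kernel, FWHM in histology pixels) and pad every edge."""
    target = float(max(block.resolution))
    img = histology
    if max(img.resolution) < target - 1e-12:
        img = gaussian_downsample(img, config.histology_fwhm, target)
    return pad_image(img, config.pad_fraction)


def _selector(chain, member, comps=None):
    return ParameterSelector([(chain.members.index(member), comps)])


def _optimise(chain, selector, evaluator, lower, upper, tolerance):
    selector.validate(chain)
    x0 = selector.get(chain)

    def objective(x):
        selector.set(chain, x)
        return safe_cost(evaluator, chain)

    group = OptimisationGroup(initial=x0, lower=lower, upper=upper,
                              tolerance=tolerance)
    best, cost = bounded_minimise(objective, group)
    selector.set(chain, best)
    return cost


def linear_registration(moving: TensorImage, fixed: TensorImage,
                        chain: TransformChain, config,
                        moving_mask=None, fixed_mask=None,
                        trace=None, rotation_search: bool = True):
    """Rotation search + similarity + affine refinement of the linear
    members (shared by stages 1 and 2 and site-detection registration).

    ``chain`` must contain Rotation2D, IsotropicScale, a variable
    Translation and Affine2D members (extra fixed members are allowed)."""
    rot = next(m for m in chain if isinstance(m, Rotation2D))
    scale = next(m for m in chain if isinstance(m, IsotropicScale))
    trans = [m for m in chain if isinstance(m, Translation)][-1]
    aff = next(m for m in chain if isinstance(m, Affine2D))
    evaluator = ChainEvaluator(moving, fixed, config.linear_resolution,
                               moving_mask, fixed_mask)

    if rotation_search:
        angles = np.arange(-180.0, 180.0, config.rotation_step) + rot.angle

        def angle_cost(a):
            rot.angle = float(a)
            return safe_cost(evaluator, chain)

        best = grid_search_rank(list(angles), angle_cost, keep=1)[0]
        rot.angle = float(best.parameters)
    sel = _selector(chain, rot)
    cost = _optimise(chain, sel, evaluator,
                     [rot.angle - config.rotation_refine],
                     [rot.angle + config.rotation_refine], config.tolerance)
    if trace is not None:
        trace.append(("rotation", cost))

    # similarity: rotation + isotropic scale + translation
    sel = ParameterSelector([
        (chain.members.index(rot), None),
        (chain.members.index(scale), None),
        (chain.members.index(trans), None),
    ])
    tb = config.translation_bound if hasattr(config, "translation_bound") else 10.0
    lo = [rot.angle - 15.0, config.scale_bounds[0],
          trans.offset[0] - tb, trans.offset[1] - tb]
    hi = [rot.angle + 15.0, config.scale_bounds[1],
          trans.offset[0] + tb, trans.offset[1] + tb]
    cost = _optimise(chain, sel, evaluator, lo, hi, config.tolerance)
    if trace is not None:
        trace.append(("similarity", cost))

    # full 2-D affine
    sel = _selector(chain, aff)
    p = aff.params
    mb, ob = config.affine_matrix_bound, config.affine_offset_bound
    lo = np.concatenate([p[:4] - mb, p[4:] - ob])
    hi = np.concatenate([p[:4] + mb, p[4:] + ob])
    cost = _optimise(chain, sel, evaluator, lo, hi, config.tolerance)
    if not np.isfinite(cost):
        raise DegenerateInputError("degenerate overlap after the affine step")
    if trace is not None:
        trace.append(("affine", cost))
    return cost


def nonlinear_registration(moving: TensorImage, fixed: TensorImage,
                           chain: TransformChain, alpha: float,
                           pyramid, max_iter: int = 20,
                           moving_mask=None, fixed_mask=None,
                           cost_log=None):
    """Append a Gauss-Newton-optimised dense displacement field to a
    linear chain.

    The field lives in the fixed image's physical frame: with linear part
    ``A`` the total mapping is ``x -> A(x) + u(A(x))``, which matches the
    chain order (field applied last).  The data term is evaluated on the
    fixed grid after pulling the moving image through ``A``-inverse —
    an exact change of variables for affine ``A``."""
    mov = moving if moving_mask is None else TensorImage(
        moving.data, moving.domain.copy(), np.asarray(moving_mask, float))
    fix = fixed if fixed_mask is None else TensorImage(
        fixed.data, fixed.domain.copy(), np.asarray(fixed_mask, float))
    fix = _crop_to_footprint(fix, mov, chain)
    # moving resampled into the fixed frame through the inverse linear chain
    mov_in_fixed_domain = mov.domain.copy(external=chain.copy())
    warped_moving = resample(
        TensorImage(mov.data, mov_in_fixed_domain, mov.mask),
        fix.domain, "linear",
    )
    field = gauss_newton_field(
        warped_moving, fix, RegularisationSpec(alpha),
        PyramidSchedule(tuple(pyramid)), max_iter=max_iter, cost_log=cost_log,
    )
    chain.append(field)
    return field


def _crop_to_footprint(fixed: TensorImage, moving: TensorImage,
                       chain: TransformChain, margin_frac: float = 0.1):
    """Restrict the fixed image to the chain-mapped moving footprint (plus
    a margin); keeps the displacement-field solve proportional to the
    moving image, not the full fixed scene."""
    corners_idx = np.array([
        (i, j)
        for i in (0, moving.shape[0] - 1)
        for j in (0, moving.shape[1] - 1)
    ], dtype=float)
    mapped = chain.apply(moving.domain.internal.apply(corners_idx))
    idx = fixed.domain.physical_to_index(mapped)
    span = idx.max(axis=0) - idx.min(axis=0)
    lo = np.floor(idx.min(axis=0) - margin_frac * span).astype(int)
    hi = np.ceil(idx.max(axis=0) + margin_frac * span).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, fixed.shape)
    if np.any(hi - lo < 8) or (np.all(lo == 0) and np.all(hi == fixed.shape)):
        return fixed
    data = fixed.data[lo[0]:hi[0], lo[1]:hi[1]]
    internal = TransformChain(
        [Translation(lo.astype(float))] + fixed.domain.internal.copy().members
    )
    from ..core import ImageDomain
    domain = ImageDomain(data.shape, internal,
                         resolution=fixed.resolution.copy())
    mask = None if fixed.mask is None else fixed.mask[lo[0]:hi[0], lo[1]:hi[1]]
    return TensorImage(data.copy(), domain, mask)


def stage1_register(histology: TensorImage, block_photo: TensorImage,
                    config: Stage1Config | None = None) -> Stage1Result:
    """Run the full stage-1 sequence and return the optimised chain
    (rotation, scale, translation, affine, dense displacement field)
    mapping histology physical coordinates to block-photo physical mm."""
    config = config or Stage1Config()
    hist = preprocess_histology(histology, block_photo, config)

    chain = TransformChain([
        Rotation2D(0.0, centre=(0.0, 0.0)),
        IsotropicScale(1.0),
        Translation((0.0, 0.0)),
        Affine2D(),
    ])
    trace = []
    fine_eval = ChainEvaluator(hist, block_photo, min(config.pyramid),
                               hist.mask, block_photo.mask)
    initial_cost = safe_cost(fine_eval, chain)
    linear_registration(hist, block_photo, chain, config,
                        hist.mask, block_photo.mask, trace)
    gn_log = []
    nonlinear_registration(hist, block_photo, chain, config.alpha,
                           config.pyramid, config.max_gn_iterations,
                           hist.mask, block_photo.mask, cost_log=gn_log)
    final_cost = safe_cost(fine_eval, chain)
    trace.append(("nonlinear", final_cost))
    log.info("stage1 cost trace: %s", trace)
    return Stage1Result(chain, trace, initial_cost, final_cost)
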