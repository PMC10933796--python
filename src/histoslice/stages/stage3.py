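"""Stage 3: deformable slice-to-volume registration of a brain-slab
photograph to an MRI volume.

The photo is embedded in 3-D and its pose searched within a configured
rectangular slab prior: (1) a rigid search crosses equidistant positions
along the slab axis with a small set of per-axis rotations, each candidate
refined by bounded minimisation through a resolution pyramid with interim
ranking; (2) a 3-D affine refinement; (3) in-plane control-point
displacements; (4) simultaneous in-plane and through-plane displacements.
The MIND cost is always evaluated between the photo and the volume
resampled onto the photo's embedded 2-D domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..core import (
    Affine3D,
    ControlPointField,
    Embed2Dto3D,
    IsotropicScale,
    ParameterSelector,
    Rotation2D,
    Rotation3D,
    TensorImage,
    TransformChain,
    Translation,
    euler_matrix,
    gaussian_downsample,
)
from ..errors import DegenerateInputError
from ..optim import OptimisationGroup, bounded_minimise, grid_search_rank
from .config import Stage3Config
from .engine import ChainEvaluator, safe_cost

__all__ = ["Stage3Result", "stage3_register", "slab_frame", "place_control_points"]

log = logging.getLogger("histoslice.stages")

#: permutation aligning slice axes (u, v) with volume axes 1, 2 and the
#: slice normal with volume axis 0 (matches the synthetic slab frame)
SLAB_BASE = np.array([
    [0.0, 0.0, 1.0],
    [1.0, 0.0, 0.0],
    [0.0, 1.0, 0.0],
])


def slab_frame(slab_angles) -> np.ndarray:
    """Column frame (e_u, e_v, normal) of a slab prior given its tilt."""
    return euler_matrix(slab_angles) @ SLAB_BASE


@dataclass
class Stage3Result:
    chain: TransformChain
    cost_trace: list = field(default_factory=list)
    step_chains: dict = field(default_factory=dict)  # step name -> chain copy
    initial_cost: float = np.nan
    final_cost: float = np.nan


def place_control_points(photo: TensorImage, count: int, seed: int = 0,
                         mask=None):
    """Evenly scattered control points (mm, slice frame) over the photo
    foreground bounding box, with a small seeded jitter to avoid exact
    collinearity."""
    fg = photo.foreground_mask() if mask is None else np.asarray(mask) > 0
    if not fg.any():
        raise DegenerateInputError("photo has no foreground for control points")
    idx = np.argwhere(fg)
    lo = photo.domain.index_to_physical(idx.min(axis=0)[None].astype(float),
                                        external=False)[0]
    hi = photo.domain.index_to_physical(idx.max(axis=0)[None].astype(float),
                                        external=False)[0]
    ny = max(2, int(round(np.sqrt(count * (hi[0] - lo[0])
                                  / max(hi[1] - lo[1], 1e-6)))))
    nx = max(2, int(round(count / ny)))
    gy = np.linspace(lo[0], hi[0], ny)
    gx = np.linspace(lo[1], hi[1], nx)
    pts = np.array([(a, b) for a in gy for b in gx])
    rng = np.random.default_rng(seed)
    jitter = 0.05 * min(gy[1] - gy[0], gx[1] - gx[0])
    pts = pts + rng.uniform(-jitter, jitter, pts.shape)
    return np.column_stack([pts, np.zeros(len(pts))])


def _build_chain(photo: TensorImage, config: Stage3Config):
    frame = slab_frame(config.slab_angles)
    points = place_control_points(photo, config.n_control_points, config.seed)
    sigma = config.control_sigma
    cpf = ControlPointField(points, sigma=sigma, active=(0, 1))
    chain = TransformChain([
        IsotropicScale(1.0),
        Rotation2D(0.0, centre=(0.0, 0.0)),
        Translation((0.0, 0.0)),
        Embed2Dto3D(),
        cpf,
        # prior orientation as a fixed base; the optimisable angles are
        # well-conditioned per-slice-axis deltas starting at zero
        Rotation3D((0.0, 0.0, 0.0), centre=(0.0, 0.0, 0.0), base=frame),
        Translation(np.asarray(config.slab_centre, dtype=float)),
        Affine3D(),
    ])
    return chain, frame


def stage3_register(slab_photo: TensorImage, mri: TensorImage,
                    config: Stage3Config | None = None,
                    mask=None, last_step: int = 4) -> Stage3Result:
    """Four-step slice-to-volume optimisation; returns the full chain.

    ``last_step`` truncates the sequence (1 = rigid search only, ... 4 =
    full non-linear refinement)."""
    config = config or Stage3Config()

    vol_res = float(max(mri.resolution))
    photo = slab_photo
    if max(photo.resolution) < vol_res - 1e-12:
        photo = gaussian_downsample(photo, config.photo_fwhm, vol_res)
        if mask is not None:
            raise DegenerateInputError(
                "supply the mask attached to the photo image when the photo "
                "needs downsampling"
            )
    if mask is None and photo.mask is None:
        photo = TensorImage(photo.data, photo.domain.copy(),
                            photo.foreground_mask(config.mask_threshold).astype(float))
    elif mask is not None:
        photo = TensorImage(photo.data, photo.domain.copy(),
                            np.asarray(mask, dtype=float))

    # the prior slab must intersect the volume
    centre_idx = mri.domain.physical_to_index(
        np.asarray(config.slab_centre, dtype=float)[None])[0]
    if np.any(centre_idx < -0.5) or np.any(centre_idx > np.asarray(mri.shape) - 0.5):
        raise DegenerateInputError("prior slab centre outside the MRI field of view")

    chain, frame = _build_chain(photo, config)
    rot3 = next(m for m in chain if isinstance(m, Rotation3D))
    trans3 = [m for m in chain if isinstance(m, Translation)][-1]
    aff3 = next(m for m in chain if isinstance(m, Affine3D))
    cpf = next(m for m in chain if isinstance(m, ControlPointField))
    i_rot3 = chain.members.index(rot3)
    i_trans3 = chain.members.index(trans3)
    rigid_sel = ParameterSelector([(i_rot3, None), (i_trans3, None)])

    levels = [float(r) for r in config.pyramid]
    evaluators = {
        res: ChainEvaluator(photo, mri, res, photo.mask) for res in levels
    }
    fine = evaluators[levels[-1]]
    trace = []
    step_chains = {}
    initial_cost = safe_cost(fine, chain)

    # ---- step 1: rigid search --------------------------------------------
    normal = frame[:, 2]
    half = config.slab_thickness / 2.0
    positions = np.linspace(-half, half, config.n_axis_positions)
    r3 = config.rotation_range / 2.0
    base_angles = rot3.angles.copy()
    base_centre = np.asarray(config.slab_centre, dtype=float)
    ip = config.inplane_search
    inplane = [(0.0, 0.0)]
    if ip > 0:
        inplane = [(a, b) for a in (-ip, 0.0, ip) for b in (-ip, 0.0, ip)]
    candidates = []
    for pos in positions:
        for du, dv in inplane:
            centre = (base_centre + pos * normal
                      + du * frame[:, 0] + dv * frame[:, 1])
            for da in (-r3, 0.0, r3):
                for db in (-r3, 0.0, r3):
                    for dc in (-r3, 0.0, r3):
                        candidates.append(np.concatenate([
                            base_angles + [da, db, dc], centre]))

    coarse = evaluators[levels[0]]

    def rigid_cost_at(evaluator, params):
        rigid_sel.set(chain, params)
        return safe_cost(evaluator, chain)

    ranked = grid_search_rank(
        candidates, lambda p: rigid_cost_at(coarse, p), keep=config.initial_keep
    )
    survivors = [(rc.cost, rc.ordinal, np.asarray(rc.parameters, dtype=float))
                 for rc in ranked]
    log.info("rigid search: %d candidates, best coarse cost %.5f",
             len(candidates), survivors[0][0])

    def refine(evaluator, params, tol, max_evals):
        lo = np.concatenate([
            params[:3] - config.refine_rotation_bound,
            params[3:] - config.refine_translation_bound,
        ])
        hi = np.concatenate([
            params[:3] + config.refine_rotation_bound,
            params[3:] + config.refine_translation_bound,
        ])
        group = OptimisationGroup(initial=params, lower=lo, upper=hi,
                                  tolerance=tol, max_evaluations=max_evals)
        return bounded_minimise(lambda p: rigid_cost_at(evaluator, p), group)

    for li, res in enumerate(levels):
        evaluator = evaluators[res]
        last = li == len(levels) - 1
        if last:  # interim ranking: only the short list reaches full price
            survivors = survivors[: config.prune_min]
        refined = []
        for _, ordinal, params in survivors:
            best, cost = refine(evaluator, params, config.tolerance,
                                1500 if last else 600)
            refined.append((cost, ordinal, best))
        refined.sort(key=lambda t: (t[0], t[1]))
        keep = 1 if last else max(
            config.prune_min, int(round(len(refined) * config.prune_fraction)))
        survivors = refined[:keep]
        log.info("rigid level %.3g mm: best cost %.5f (%d survivors)",
                 res, survivors[0][0], len(survivors))

    # final deep polish of the single winner at the finest level
    best, cost = refine(evaluators[levels[-1]], survivors[0][2],
                        config.final_tolerance, 3000)
    rigid_sel.set(chain, best)
    trace.append(("rigid", cost))
    step_chains["rigid"] = chain.copy()
    if last_step <= 1:
        log.info("stage3 cost trace: %s", trace)
        return Stage3Result(chain, trace, step_chains, initial_cost, cost)

    # ---- step 2: affine ---------------------------------------------------
    aff_sel = ParameterSelector([(chain.members.index(aff3), None)])
    p = aff3.params
    mb, ob = config.affine_matrix_bound, config.affine_offset_bound
    lo = np.concatenate([p[:9] - mb, p[9:] - ob])
    hi = np.concatenate([p[:9] + mb, p[9:] + ob])

    def set_and_cost(selector, evaluator, x):
        selector.set(chain, x)
        return safe_cost(evaluator, chain)

    group = OptimisationGroup(initial=p, lower=lo, upper=hi,
                              tolerance=config.final_tolerance,
                              max_evaluations=2500)
    best, cost = bounded_minimise(
        lambda x: set_and_cost(aff_sel, fine, x), group)
    aff_sel.set(chain, best)
    trace.append(("affine", cost))
    step_chains["affine"] = chain.copy()
    if last_step <= 2:
        log.info("stage3 cost trace: %s", trace)
        return Stage3Result(chain, trace, step_chains, initial_cost, cost)

    # ---- step 3: in-plane control-point displacements ---------------------
    i_cpf = chain.members.index(cpf)
    cpf.active = (0, 1)
    sel = ParameterSelector([(i_cpf, None)])
    x0 = sel.get(chain)
    group = OptimisationGroup(
        initial=x0, lower=x0 - config.inplane_bound,
        upper=x0 + config.inplane_bound, tolerance=config.tolerance,
        max_evaluations=3500,
    )
    best, cost = bounded_minimise(lambda x: set_and_cost(sel, fine, x), group)
    sel.set(chain, best)
    trace.append(("inplane", cost))
    step_chains["inplane"] = chain.copy()
    if last_step <= 3:
        log.info("stage3 cost trace: %s", trace)
        return Stage3Result(chain, trace, step_chains, initial_cost, cost)

    # ---- step 4: full 3-D control-point displacements ---------------------
    cpf.active = (0, 1, 2)
    sel = ParameterSelector([(i_cpf, None)])
    x0 = sel.get(chain)
    group = OptimisationGroup(
        initial=x0, lower=x0 - config.deform_bound,
        upper=x0 + config.deform_bound, tolerance=config.final_tolerance,
        max_evaluations=6000,
    )
    best, cost = bounded_minimise(lambda x: set_and_cost(sel, fine, x), group)
    sel.set(chain, best)
    trace.append(("deform", cost))
    step_chains["deform"] = chain.copy()

    final_cost = cost
    log.info("stage3 cost trace: %s", trace)
    return Stage3Result(chain, trace, step_chains, initial_cost, final_cost)
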