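"""Stage 4: direct histology-to-MRI refinement, hemisphere-chain merging
and reduced-DOF reparameterisation.

The composed Stage 1-3 mapping is re-expressed as a light chain (sparse
3-D control-point field, 3-D rotation, 3-D translation) fitted by least
squares on a sample grid, then fine-tuned with the rigid search confined
to +/-2 mm of perpendicular travel.  The non-linear steps are off by
default (the linear steps gave the best overall match on the study data)
but can be switched on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..core import (
    ControlPointField,
    DenseDisplacementField,
    Embed2Dto3D,
    ParameterSelector,
    Rotation3D,
    TensorImage,
    TransformChain,
    Translation,
    gaussian_downsample,
)
from ..errors import ConfigurationError, DegenerateInputError, HistosliceError
from ..optim import OptimisationGroup, bounded_minimise
from .config import Stage4Config
from .engine import ChainEvaluator, safe_cost
from .stage3 import place_control_points

__all__ = ["Stage4Result", "stage4_refine", "merge_hemisphere_chains",
           "fit_reduced_chain"]

log = logging.getLogger("histoslice.stages")


@dataclass
class Stage4Result:
    chain: TransformChain
    fit_residual: float
    cost_trace: list = field(default_factory=list)
    step_chains: dict = field(default_factory=dict)
    initial_cost: float = np.nan
    final_cost: float = np.nan


def merge_hemisphere_chains(left: TransformChain, right: TransformChain,
                            weight_map, photo_domain) -> TransformChain:
    """Pointwise convex combination of two slice-to-volume chains.

    ``weight_map`` gives the left-chain weight per photo pixel (1 in the
    left-hemisphere core, 0 in the right); the merged action is stored as
    a dense 3-vector displacement field over the 2-D photo domain, so the
    result is a single embedded chain, continuous wherever the weight map
    is."""
    w = np.asarray(weight_map, dtype=float)
    if w.shape != tuple(photo_domain.shape):
        raise ConfigurationError("weight map shape does not match the photo domain")
    if np.any(w < 0) or np.any(w > 1):
        raise ConfigurationError("weights must lie in [0, 1]")
    pts2 = photo_domain.physical_points(external=False)
    pl = left.apply(pts2)
    pr = right.apply(pts2)
    merged = w.ravel()[:, None] * pl + (1.0 - w.ravel()[:, None]) * pr
    base = np.column_stack([pts2, np.zeros(len(pts2))])
    vectors = (merged - base).reshape(photo_domain.shape + (3,))
    origin = photo_domain.index_to_physical(
        np.zeros((1, 2)), external=False)[0]
    fld = DenseDisplacementField(vectors, spacing=photo_domain.resolution,
                                 origin=origin)
    return TransformChain([fld])


def fit_reduced_chain(init_mapping: TransformChain, domain, config: Stage4Config,
                      foreground=None):
    """Least-squares reparameterisation of a histology-to-MRI mapping as
    control-point field + rotation + translation.

    Sampling happens on a ``fit_grid`` x ``fit_grid`` lattice over the
    histology domain; returns ``(chain, median_residual_mm)``."""
    shape = np.asarray(domain.shape, dtype=float)
    g = config.fit_grid
    ii = np.linspace(0, shape[0] - 1, g)
    jj = np.linspace(0, shape[1] - 1, g)
    idx = np.array([(a, b) for a in ii for b in jj])
    x2 = domain.internal.apply(idx)
    if foreground is not None:
        fg = np.asarray(foreground, dtype=bool)
        keep = fg[np.clip(np.round(idx[:, 0]).astype(int), 0, int(shape[0]) - 1),
                  np.clip(np.round(idx[:, 1]).astype(int), 0, int(shape[1]) - 1)]
        if keep.sum() >= 16:
            x2 = x2[keep]
    y = init_mapping.apply(x2)
    x3 = np.column_stack([x2, np.zeros(len(x2))])

    # rigid Procrustes fit (rotation + translation, no scaling)
    xc = x3.mean(axis=0)
    yc = y.mean(axis=0)
    h = (x3 - xc).T @ (y - yc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = yc - rot @ xc

    # residual displacement in the pre-rotation (slice) frame
    resid = (y - t) @ rot - x3  # rows: R^T (y - t) - x
    # control points over the full domain extent
    pts = place_control_points(
        TensorImage(np.ones(domain.shape), domain.copy()),
        config.n_control_points, 0)
    cpf = ControlPointField(pts, sigma=config.control_sigma, active=(0, 1, 2))
    k_pp = cpf._kernel(cpf.points, cpf.points)
    k_xp = cpf._kernel(x3, cpf.points)
    basis = k_xp @ np.linalg.inv(k_pp)
    disp, *_ = np.linalg.lstsq(basis, resid, rcond=None)
    cpf.set_displacements(disp)

    chain = TransformChain([
        Embed2Dto3D(),
        cpf,
        Rotation3D((0.0, 0.0, 0.0), centre=(0.0, 0.0, 0.0), base=rot),
        Translation(t),
    ])
    fitted = chain.apply(x2)
    residual = float(np.median(np.linalg.norm(fitted - y, axis=1)))
    return chain, residual


def stage4_refine(histology: TensorImage, mri: TensorImage,
                  init_mapping: TransformChain,
                  config: Stage4Config | None = None) -> Stage4Result:
    """Reparameterise and fine-tune a composed histology-to-MRI mapping."""
    config = config or Stage4Config()

    vol_res = float(max(mri.resolution))
    hist = histology
    if max(hist.resolution) < vol_res - 1e-12:
        hist = gaussian_downsample(hist, 6.25, vol_res)
    if hist.mask is None:
        hist = TensorImage(hist.data, hist.domain.copy(),
                           hist.foreground_mask(config.mask_threshold).astype(float))

    chain, residual = fit_reduced_chain(
        init_mapping, hist.domain, config,
        foreground=hist.mask > 0 if hist.mask is not None else None)
    if residual > config.fit_residual_threshold:
        raise HistosliceError(
            f"reparameterisation residual {residual:.3f} mm exceeds "
            f"{config.fit_residual_threshold} mm; increase the number of "
            "control points"
        )

    cpf = next(m for m in chain if isinstance(m, ControlPointField))
    rot3 = next(m for m in chain if isinstance(m, Rotation3D))
    trans3 = [m for m in chain if isinstance(m, Translation)][-1]
    frame = rot3.base.copy()
    t0 = trans3.offset.copy()

    levels = [float(r) for r in config.pyramid]
    evaluators = {r: ChainEvaluator(hist, mri, r, hist.mask) for r in levels}
    fine = evaluators[levels[-1]]
    trace = []
    step_chains = {}
    initial_cost = safe_cost(fine, chain)

    # rigid refinement with bounded perpendicular travel: translation is
    # parameterised in the slice frame as (in-plane u, in-plane v, perp)
    def rigid_cost(x):
        rot3.angles = x[:3]
        trans3.offset = t0 + frame @ x[3:]
        return safe_cost(fine, chain)

    rb, ib, pb = (config.rotation_bound, config.inplane_translation_bound,
                  config.perpendicular_bound)
    group = OptimisationGroup(
        initial=np.zeros(6),
        lower=[-rb] * 3 + [-ib, -ib, -pb],
        upper=[rb] * 3 + [ib, ib, pb],
        tolerance=config.tolerance, max_evaluations=4000,
    )
    best, cost = bounded_minimise(rigid_cost, group)
    rigid_cost(best)
    trace.append(("rigid", cost))
    step_chains["rigid"] = chain.copy()

    if config.run_nonlinear:
        i_cpf = chain.members.index(cpf)
        for name, active in (("inplane", (0, 1)), ("deform", (0, 1, 2))):
            cpf.active = active
            sel = ParameterSelector([(i_cpf, None)])
            x0 = sel.get(chain)
            group = OptimisationGroup(
                initial=x0, lower=x0 - config.deform_bound,
                upper=x0 + config.deform_bound,
                tolerance=config.tolerance, max_evaluations=5000,
            )

            def nl_cost(x, sel=sel):
                sel.set(chain, x)
                return safe_cost(fine, chain)

            best, cost = bounded_minimise(nl_cost, group)
            sel.set(chain, best)
            trace.append((name, cost))
            step_chains[name] = chain.copy()

    final_cost = trace[-1][1]
    log.info("stage4 cost trace: %s (fit residual %.3f mm)", trace, residual)
    return Stage4Result(chain, residual, trace, step_chains,
                        initial_cost, final_cost)
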