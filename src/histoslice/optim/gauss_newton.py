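"""Diffusion-regularised Gauss-Newton estimation of dense displacement
fields under the MIND data term.

The solver works on the fixed image's grid: the unknown field ``u`` holds
one mm displacement vector per fixed pixel, the moving image is sampled at
``x + u(x)``, descriptors are recomputed on the warped result
(resample-then-describe) and the normal equations

    (J' W J + lam * L + ridge) du = -(J' W r + lam * L u)

are assembled sparsely, with ``L`` the forward-difference graph Laplacian
of the diffusion penalty.  Objective decrease is enforced by step-halving;
the field is linearly upsampled (in mm) between pyramid levels.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import map_coordinates
from scipy.sparse.linalg import spsolve

from ..core import DenseDisplacementField, TensorImage
from ..core.image import snap_coords
from ..errors import DegenerateInputError
from ..similarity import RegularisationSpec, mind_descriptor
from .pyramid import PyramidSchedule, at_resolution

__all__ = ["gauss_newton_field"]

log = logging.getLogger("histoslice.optim")

RIDGE_FRACTION = 1e-6
MAX_HALVINGS = 5
REL_TOL = 1e-5


def _laplacian_1d(n):
    d = sp.diags([np.full(n - 1, -1.0), np.ones(n - 1)], [0, 1],
                 shape=(n - 1, n)) if n > 1 else sp.csr_matrix((0, n))
    return (d.T @ d).tocsr()


def _laplacian_2d(h, w):
    ih, iw = sp.identity(h), sp.identity(w)
    return (sp.kron(_laplacian_1d(h), iw) + sp.kron(ih, _laplacian_1d(w))).tocsr()


class _LevelProblem:
    def __init__(self, fixed: TensorImage, moving: TensorImage, alpha: float):
        self.fixed = fixed
        self.moving = moving
        self.alpha = alpha
        self.shape = fixed.shape
        self.grid_phys = fixed.domain.physical_points(external=False)
        self.mf = mind_descriptor(fixed)
        self.fweight = np.ones(self.shape)
        if fixed.mask is not None:
            self.fweight *= fixed.mask
        self.n = int(np.prod(self.shape))
        # diffusion penalty is grid-spacing-scaled (finite differences per
        # mm), making the regularisation resolution-independent
        h = fixed.resolution
        ih, iw = sp.identity(self.shape[0]), sp.identity(self.shape[1])
        self.lap = (sp.kron(_laplacian_1d(self.shape[0]), iw) / h[0] ** 2
                    + sp.kron(ih, _laplacian_1d(self.shape[1])) / h[1] ** 2
                    ).tocsr()
        self._hy, self._hx = float(h[0]), float(h[1])
        res = fixed.resolution
        fdesc = self.mf.descriptors
        self._fgrad_y = np.empty_like(fdesc)
        self._fgrad_x = np.empty_like(fdesc)
        for c in range(fdesc.shape[-1]):
            self._fgrad_y[..., c], self._fgrad_x[..., c] = np.gradient(
                fdesc[..., c], res[0], res[1]
            )

    def warp(self, u):
        q = self.grid_phys + u.reshape(-1, 2)
        idx = snap_coords(self.moving.domain.physical_to_index(q))
        shape = np.asarray(self.moving.shape, dtype=float)
        inb = np.all((idx >= 0) & (idx <= shape - 1), axis=1).reshape(self.shape)
        warped = map_coordinates(self.moving.data, idx.T, order=1,
                                 mode="constant", cval=0.0).reshape(self.shape)
        weight = self.fweight * inb
        if self.moving.mask is not None:
            mw = map_coordinates(self.moving.mask, idx.T, order=1,
                                 mode="constant", cval=0.0).reshape(self.shape)
            weight = weight * mw
        return warped, weight

    def evaluate(self, u):
        """Objective value plus everything needed for the GN update."""
        warped, weight = self.warp(u)
        mw = mind_descriptor(warped)
        w = weight * (self.mf.valid & mw.valid)
        wsum = w.sum()
        if wsum <= 0:
            raise DegenerateInputError("displacement field left no image overlap")
        r = mw.descriptors - self.mf.descriptors
        # data term averaged over channels so alpha weighs the diffusion
        # term against a per-pixel residual of order one
        data = float((w[..., None] * r**2).sum() / (wsum * r.shape[-1]))
        du0 = (np.diff(u[..., 0], axis=0) / self._hy) ** 2
        dv0 = (np.diff(u[..., 0], axis=1) / self._hx) ** 2
        du1 = (np.diff(u[..., 1], axis=0) / self._hy) ** 2
        dv1 = (np.diff(u[..., 1], axis=1) / self._hx) ** 2
        reg = float(du0.sum() + dv0.sum() + du1.sum() + dv1.sum()) / self.n
        return data + self.alpha * reg, r, w, wsum, mw.descriptors

    def objective(self, u):
        return self.evaluate(u)[0]

    def update(self, u):
        f0, r, w, wsum, mdesc = self.evaluate(u)
        res = self.fixed.resolution
        ncomp = r.shape[-1]
        # symmetric (ESM-style) gradients: average of fixed and warped
        # descriptor gradients -- markedly more stable than one-sided
        gy = np.empty_like(mdesc)
        gx = np.empty_like(mdesc)
        for c in range(ncomp):
            my, mx = np.gradient(mdesc[..., c], res[0], res[1])
            gy[..., c] = 0.5 * (my + self._fgrad_y[..., c])
            gx[..., c] = 0.5 * (mx + self._fgrad_x[..., c])
        wt = (w / (wsum * ncomp))[..., None]
        a00 = (wt * gy * gy).sum(-1).ravel()
        a01 = (wt * gy * gx).sum(-1).ravel()
        a11 = (wt * gx * gx).sum(-1).ravel()
        g0 = (wt * gy * r).sum(-1).ravel()
        g1 = (wt * gx * r).sum(-1).ravel()
        lam = self.alpha / self.n
        lap = self.lap
        u0 = u[..., 0].ravel()
        u1 = u[..., 1].ravel()
        rhs = -np.concatenate([g0 + lam * (lap @ u0), g1 + lam * (lap @ u1)])
        ridge = RIDGE_FRACTION * (a00.sum() + a11.sum())
        eye = sp.identity(self.n) * max(ridge, 1e-15)
        a = sp.bmat(
            [
                [sp.diags(a00) + lam * lap + eye, sp.diags(a01)],
                [sp.diags(a01), sp.diags(a11) + lam * lap + eye],
            ],
            format="csc",
        )
        delta = spsolve(a, rhs)
        step = np.stack(
            [delta[: self.n].reshape(self.shape), delta[self.n :].reshape(self.shape)],
            axis=-1,
        )
        return f0, step


def gauss_newton_field(fixed: TensorImage, moving: TensorImage,
                       spec: RegularisationSpec,
                       schedule: PyramidSchedule,
                       max_iter: int = 20,
                       initial_field: DenseDisplacementField | None = None,
                       cost_log: list | None = None) -> DenseDisplacementField:
    """Optimise a dense displacement field aligning ``moving`` (sampled at
    displaced fixed-grid positions) with ``fixed`` under the MIND data
    term plus diffusion regularisation.

    Both images must live in a common physical frame through their
    internal chains.  The returned field holds mm vectors over the fixed
    grid at the finest pyramid level."""
    field = initial_field
    for res in schedule:
        f_lvl = at_resolution(fixed, res)
        m_lvl = at_resolution(moving, res)
        prob = _LevelProblem(f_lvl, m_lvl, spec.alpha)
        u = np.zeros(prob.shape + (2,))
        if field is not None:
            u = field.displacement(prob.grid_phys).reshape(prob.shape + (2,))
        f_prev = prob.objective(u)
        for it in range(max_iter):
            try:
                f_here, step = prob.update(u)
            except DegenerateInputError:
                raise
            # line search along the GN direction: extend while improving
            # (the saturating MIND residual makes plain GN under-step),
            # halve on increase
            accepted = False
            f_new = f_here
            f_try = prob.objective(u + step)
            if f_try < f_here:
                best_scale, f_new, accepted = 1.0, f_try, True
                scale = 2.0
                for _ in range(3):
                    f_ext = prob.objective(u + scale * step)
                    if f_ext < f_new:
                        best_scale, f_new = scale, f_ext
                        scale *= 2.0
                    else:
                        break
                u = u + best_scale * step
            else:
                scale = 0.5
                for _ in range(MAX_HALVINGS):
                    f_try = prob.objective(u + scale * step)
                    if f_try < f_here:
                        u = u + scale * step
                        f_new, accepted = f_try, True
                        break
                    scale *= 0.5
            if not accepted:
                break
            if cost_log is not None:
                cost_log.append((res, it, f_new))
            if f_here - f_new < REL_TOL * max(f_here, 1e-12):
                f_prev = f_new
                break
            f_prev = f_new
        origin = f_lvl.domain.index_to_physical(
            np.zeros((1, 2)), external=False
        )[0]
        field = DenseDisplacementField(u, spacing=f_lvl.resolution, origin=origin)
        log.debug("GN level %.3g mm: objective %.6g", res, f_prev)
    return field
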