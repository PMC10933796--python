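"""Transformation chains: ordered composition, Jacobians, vector
reorientation and parameter-group addressing."""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError, NotInvertibleError
from .transforms import Transformation, _as_points

__all__ = [
    "TransformChain",
    "ParameterSelector",
    "apply_chain",
    "chain_jacobian",
    "reorient_vectors",
]


class TransformChain:
    """Ordered sequence of :class:`Transformation` members.

    Applying the chain applies the members in list order.  Chains
    concatenate with ``+`` and are indexable like lists.
    """

    def __init__(self, members=()):
        self.members: list[Transformation] = list(members)

    # -- container protocol -------------------------------------------------
    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return TransformChain(self.members[idx])
        return self.members[idx]

    def __add__(self, other):
        if isinstance(other, TransformChain):
            return TransformChain(self.members + other.members)
        if isinstance(other, Transformation):
            return TransformChain(self.members + [other])
        return NotImplemented

    def append(self, member: Transformation):
        self.members.append(member)

    def copy(self) -> "TransformChain":
        return _copy.deepcopy(self)

    # -- geometry -----------------------------------------------------------
    def _check_dims(self, dim):
        for i, m in enumerate(self.members):
            if m.dim_in is not None and m.dim_in != dim:
                raise ConfigurationError(
                    f"chain member {i} ({type(m).__name__}) expects "
                    f"{m.dim_in}-D input but receives {dim}-D points"
                )
            dim = m.dim_out if m.dim_out is not None else dim
        return dim

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        self._check_dims(pts.shape[1])
        for m in self.members:
            pts = m.map_points(pts)
        if not np.all(np.isfinite(pts)):
            raise ConfigurationError("chain produced non-finite coordinates")
        return pts

    def inverse_apply(self, points) -> np.ndarray:
        """Backward mapping (members inverted in reverse order).

        Members without an analytic inverse (displacement fields) are
        inverted by fixed-point iteration on ``p <- q - u(p)``."""
        pts = _as_points(points)
        for m in reversed(self.members):
            try:
                pts = m.inverse_map(pts)
            except NotInvertibleError:
                pts = _fixed_point_inverse(m, pts)
        return pts

    def jacobian(self, points) -> np.ndarray:
        """Per-point Jacobian of the full composition (chain rule)."""
        pts = _as_points(points)
        dim = pts.shape[1]
        total = np.broadcast_to(np.eye(dim), (len(pts), dim, dim)).copy()
        for m in self.members:
            jac = m.jacobian(pts)
            total = np.einsum("nij,njk->nik", jac, total)
            pts = m.map_points(pts)
        return total

    # -- parameters ---------------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        if not self.members:
            return np.zeros(0)
        return np.concatenate([m.params for m in self.members])

    @params.setter
    def params(self, values):
        v = np.asarray(values, dtype=float).ravel()
        pos = 0
        for m in self.members:
            n = m.nparams
            m.params = v[pos : pos + n]
            pos += n
        if pos != v.size:
            raise ConfigurationError("parameter vector length mismatch")

    def __repr__(self):  # pragma: no cover
        inner = ", ".join(type(m).__name__ for m in self.members)
        return f"TransformChain([{inner}])"


def _fixed_point_inverse(member, points, iters=20, tol=1e-9):
    if member.dim_in != member.dim_out:
        raise NotInvertibleError(
            f"{type(member).__name__} changes dimensionality; no inverse"
        )
    est = points.copy()
    for _ in range(iters):
        disp = member.map_points(est) - est
        new = points - disp
        if np.max(np.abs(new - est)) < tol:
            est = new
            break
        est = new
    return est


@dataclass
class ParameterSelector:
    """Addresses a subset of chain parameters: list of
    ``(member_index, component_indices)`` pairs.  ``None`` component
    indices select all of that member's parameters."""

    entries: list = field(default_factory=list)

    def validate(self, chain: TransformChain):
        for mi, comps in self.entries:
            if not (0 <= mi < len(chain)):
                raise ConfigurationError(f"selector member index {mi} out of range")
            n = chain[mi].nparams
            if comps is not None and (np.max(comps) >= n or np.min(comps) < 0):
                raise ConfigurationError(
                    f"selector addresses parameter {np.max(comps)} of member "
                    f"{mi} which has only {n} parameters"
                )

    def get(self, chain: TransformChain) -> np.ndarray:
        out = []
        for mi, comps in self.entries:
            p = chain[mi].params
            out.append(p if comps is None else p[np.asarray(comps)])
        return np.concatenate(out) if out else np.zeros(0)

    def set(self, chain: TransformChain, values):
        v = np.asarray(values, dtype=float).ravel()
        pos = 0
        for mi, comps in self.entries:
            p = chain[mi].params
            if comps is None:
                n = p.size
                p = v[pos : pos + n]
            else:
                comps = np.asarray(comps)
                n = comps.size
                p[comps] = v[pos : pos + n]
            chain[mi].params = p
            pos += n
        if pos != v.size:
            raise ConfigurationError("selector value length mismatch")


# -- functional front-ends --------------------------------------------------

def apply_chain(chain: TransformChain, points) -> np.ndarray:
    """Map physical points through the chain (identity for empty chains)."""
    return chain.apply(points)


def chain_jacobian(chain: TransformChain, points):
    """Per-point Jacobians and their determinants.

    Determinants are reported for square Jacobians only; dimension-
    changing chains yield ``nan`` determinants."""
    jac = chain.jacobian(points)
    if jac.shape[1] == jac.shape[2]:
        dets = np.linalg.det(jac)
    else:
        dets = np.full(len(jac), np.nan)
    return jac, dets


def reorient_vectors(chain: TransformChain, points, vectors) -> np.ndarray:
    """Rotate 3-vectors by the rotational part (polar decomposition) of
    the chain's local Jacobian at each point."""
    vecs = np.atleast_2d(np.asarray(vectors, dtype=float))
    jac = chain.jacobian(points)
    if jac.shape[1] != jac.shape[2]:
        raise ConfigurationError("reorientation requires a square local Jacobian")
    u, s, vt = np.linalg.svd(jac)
    if np.any(s < 1e-12):
        bad = np.where(s.min(axis=1) < 1e-12)[0]
        raise ConfigurationError(
            f"degenerate local Jacobian at point indices {bad.tolist()}"
        )
    rot = np.einsum("nij,njk->nik", u, vt)
    return np.einsum("nij,nj->ni", rot, vecs)
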