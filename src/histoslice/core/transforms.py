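"""Parameterised spatial transformations.

Every transformation maps arrays of points ``(N, dim_in) -> (N, dim_out)``
in physical millimetres and exposes a local Jacobian.  Angles are degrees.
``params`` is the flat vector of *optimisable* parameters; fixed attributes
(rotation centres, control-point locations, kernel widths, field domains)
are not part of it.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import map_coordinates

from ..errors import ConfigurationError, NotInvertibleError

__all__ = [
    "Transformation",
    "Rotation2D",
    "IsotropicScale",
    "Translation",
    "Affine2D",
    "Affine3D",
    "Embed2Dto3D",
    "Rotation3D",
    "DenseDisplacementField",
    "ControlPointField",
    "rbf_displace",
]


def _as_points(points, dim=None):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if dim is not None and pts.shape[1] != dim:
        raise ConfigurationError(
            f"expected {dim}-D points, got shape {pts.shape}"
        )
    return pts


class Transformation:
    """Abstract base of all chain members."""

    #: input/output dimensionality; None means "matches input"
    dim_in: int | None = None
    dim_out: int | None = None

    @property
    def params(self) -> np.ndarray:
        raise NotImplementedError

    @params.setter
    def params(self, values) -> None:
        raise NotImplementedError

    @property
    def nparams(self) -> int:
        return self.params.size

    def map_points(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        """Local Jacobian, shape ``(N, dim_out, dim_in)``."""
        raise NotImplementedError

    def inverse_map(self, points: np.ndarray) -> np.ndarray:
        raise NotInvertibleError(
            f"{type(self).__name__} does not provide an inverse mapping"
        )

    def copy(self) -> "Transformation":
        import copy as _copy

        return _copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}(params={np.asarray(self.params)})"


def _rot2(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s], [s, c]])


class Rotation2D(Transformation):
    """In-plane rotation (counter-clockwise, degrees) about ``centre``."""

    dim_in = dim_out = 2

    def __init__(self, angle: float = 0.0, centre=(0.0, 0.0)):
        self.angle = float(angle)
        self.centre = np.asarray(centre, dtype=float)

    @property
    def params(self):
        return np.array([self.angle])

    @params.setter
    def params(self, values):
        self.angle = float(np.asarray(values).ravel()[0])

    def map_points(self, points):
        pts = _as_points(points, 2)
        return (pts - self.centre) @ _rot2(self.angle).T + self.centre

    def jacobian(self, points):
        pts = _as_points(points, 2)
        return np.broadcast_to(_rot2(self.angle), (len(pts), 2, 2)).copy()

    def inverse_map(self, points):
        pts = _as_points(points, 2)
        return (pts - self.centre) @ _rot2(-self.angle).T + self.centre


class IsotropicScale(Transformation):
    """Uniform scaling about the origin; works in any dimension."""

    def __init__(self, factor: float = 1.0):
        self.factor = float(factor)

    @property
    def params(self):
        return np.array([self.factor])

    @params.setter
    def params(self, values):
        self.factor = float(np.asarray(values).ravel()[0])

    def map_points(self, points):
        return _as_points(points) * self.factor

    def jacobian(self, points):
        pts = _as_points(points)
        d = pts.shape[1]
        return np.broadcast_to(np.eye(d) * self.factor, (len(pts), d, d)).copy()

    def inverse_map(self, points):
        if self.factor == 0:
            raise NotInvertibleError("zero scale factor")
        return _as_points(points) / self.factor


class Translation(Transformation):
    """Rigid offset in millimetres (2-D or 3-D)."""

    def __init__(self, offset):
        self.offset = np.asarray(offset, dtype=float).ravel()
        self.dim_in = self.dim_out = self.offset.size

    @property
    def params(self):
        return self.offset.copy()

    @params.setter
    def params(self, values):
        self.offset = np.asarray(values, dtype=float).ravel()

    def map_points(self, points):
        return _as_points(points, self.dim_in) + self.offset

    def jacobian(self, points):
        pts = _as_points(points, self.dim_in)
        d = self.dim_in
        return np.broadcast_to(np.eye(d), (len(pts), d, d)).copy()

    def inverse_map(self, points):
        return _as_points(points, self.dim_in) - self.offset


class _Affine(Transformation):
    def __init__(self, matrix=None, offset=None, dim=2):
        self._d = dim
        self.matrix = np.eye(dim) if matrix is None else np.asarray(matrix, float).reshape(dim, dim).copy()
        self.offset = np.zeros(dim) if offset is None else np.asarray(offset, float).ravel().copy()
        self.dim_in = self.dim_out = dim

    @property
    def params(self):
        return np.concatenate([self.matrix.ravel(), self.offset])

    @params.setter
    def params(self, values):
        v = np.asarray(values, dtype=float).ravel()
        d = self._d
        self.matrix = v[: d * d].reshape(d, d).copy()
        self.offset = v[d * d :].copy()

    def map_points(self, points):
        return _as_points(points, self._d) @ self.matrix.T + self.offset

    def jacobian(self, points):
        pts = _as_points(points, self._d)
        return np.broadcast_to(self.matrix, (len(pts), self._d, self._d)).copy()

    def inverse_map(self, points):
        try:
            inv = np.linalg.inv(self.matrix)
        except np.linalg.LinAlgError as exc:
            raise NotInvertibleError("singular affine matrix") from exc
        return (_as_points(points, self._d) - self.offset) @ inv.T

    @property
    def homogeneous(self) -> np.ndarray:
        h = np.eye(self._d + 1)
        h[: self._d, : self._d] = self.matrix
        h[: self._d, self._d] = self.offset
        return h


class Affine2D(_Affine):
    def __init__(self, matrix=None, offset=None):
        super().__init__(matrix, offset, dim=2)


class Affine3D(_Affine):
    def __init__(self, matrix=None, offset=None):
        super().__init__(matrix, offset, dim=3)

    @classmethod
    def from_homogeneous(cls, mat4: np.ndarray) -> "Affine3D":
        mat4 = np.asarray(mat4, dtype=float)
        return cls(mat4[:3, :3], mat4[:3, 3])


class Embed2Dto3D(Transformation):
    """Plane embedding: ``(x, y) -> (x, y, 0)``.  No parameters."""

    dim_in, dim_out = 2, 3

    @property
    def params(self):
        return np.zeros(0)

    @params.setter
    def params(self, values):
        if np.asarray(values).size:
            raise ConfigurationError("Embed2Dto3D takes no parameters")

    def map_points(self, points):
        pts = _as_points(points, 2)
        return np.column_stack([pts, np.zeros(len(pts))])

    def jacobian(self, points):
        pts = _as_points(points, 2)
        j = np.zeros((len(pts), 3, 2))
        j[:, 0, 0] = 1.0
        j[:, 1, 1] = 1.0
        return j

    def inverse_map(self, points):
        return _as_points(points, 3)[:, :2]


def euler_angles_from_matrix(matrix) -> np.ndarray:
    """Inverse of :func:`euler_matrix` (intrinsic x-y-z, degrees)."""
    m = np.asarray(matrix, dtype=float)
    ay = math.asin(np.clip(m[0, 2], -1.0, 1.0))
    if abs(m[0, 2]) < 1.0 - 1e-12:
        ax = math.atan2(-m[1, 2], m[2, 2])
        az = math.atan2(-m[0, 1], m[0, 0])
    else:  # gimbal lock
        ax = math.atan2(m[2, 1], m[1, 1])
        az = 0.0
    return np.degrees([ax, ay, az])


def euler_matrix(angles_deg) -> np.ndarray:
    """Intrinsic x-y-z Euler rotation matrix: R = Rx @ Ry @ Rz."""
    ax, ay, az = np.radians(np.asarray(angles_deg, dtype=float).ravel())
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


class Rotation3D(Transformation):
    """3-D rotation given as intrinsic x-y-z Euler angles (degrees) about
    ``centre``.

    An optional fixed ``base`` rotation matrix is composed after the
    Euler angles (``matrix = base @ euler(angles)``).  This keeps the
    optimisable angles near zero for arbitrary prior orientations, away
    from the gimbal-lock singularity of the Euler parameterisation."""

    dim_in = dim_out = 3

    def __init__(self, angles=(0.0, 0.0, 0.0), centre=(0.0, 0.0, 0.0),
                 base=None):
        self.angles = np.asarray(angles, dtype=float).ravel().copy()
        self.centre = np.asarray(centre, dtype=float).ravel().copy()
        self.base = None if base is None else np.asarray(base, dtype=float).copy()

    @property
    def params(self):
        return self.angles.copy()

    @params.setter
    def params(self, values):
        self.angles = np.asarray(values, dtype=float).ravel().copy()

    @property
    def matrix(self):
        m = euler_matrix(self.angles)
        return m if self.base is None else self.base @ m

    def map_points(self, points):
        pts = _as_points(points, 3)
        return (pts - self.centre) @ self.matrix.T + self.centre

    def jacobian(self, points):
        pts = _as_points(points, 3)
        return np.broadcast_to(self.matrix, (len(pts), 3, 3)).copy()

    def inverse_map(self, points):
        pts = _as_points(points, 3)
        return (pts - self.centre) @ self.matrix + self.centre


class DenseDisplacementField(Transformation):
    """Per-pixel displacement vectors on a regular grid.

    The field domain is given by ``spacing`` (mm per grid step, one value
    per grid axis) and ``origin`` (physical mm position of grid node
    ``(0, ..., 0)``).  Vectors are interpolated linearly; queries outside
    the grid receive the nearest-edge vector.

    When ``vectors`` carry one more component than the grid has axes
    (3-vectors over a 2-D domain), the mapping embeds its 2-D input at
    ``z = 0`` before adding the displacement — this supports merged
    slice-to-volume fields defined over a photo domain.
    """

    def __init__(self, vectors: np.ndarray, spacing, origin=None):
        vectors = np.asarray(vectors, dtype=float)
        if not np.all(np.isfinite(vectors)):
            raise ConfigurationError("displacement field contains non-finite vectors")
        self.vectors = vectors.copy()
        self.grid_dim = vectors.ndim - 1
        self.vec_dim = vectors.shape[-1]
        if self.vec_dim not in (self.grid_dim, self.grid_dim + 1):
            raise ConfigurationError(
                f"cannot map {self.grid_dim}-D grid with {self.vec_dim}-vectors"
            )
        self.spacing = np.broadcast_to(
            np.asarray(spacing, dtype=float).ravel(), (self.grid_dim,)
        ).copy()
        self.origin = (
            np.zeros(self.grid_dim)
            if origin is None
            else np.asarray(origin, dtype=float).ravel().copy()
        )
        self.dim_in = self.grid_dim
        self.dim_out = self.vec_dim

    @property
    def shape(self):
        return self.vectors.shape[:-1]

    @property
    def params(self):
        return self.vectors.ravel().copy()

    @params.setter
    def params(self, values):
        self.vectors = np.asarray(values, dtype=float).reshape(self.vectors.shape).copy()

    def displacement(self, points) -> np.ndarray:
        pts = _as_points(points, self.grid_dim)
        coords = (pts - self.origin) / self.spacing
        # nearest-edge extension for out-of-domain queries
        coords = np.clip(coords, 0.0, np.asarray(self.shape) - 1.0)
        out = np.empty((len(pts), self.vec_dim))
        for c in range(self.vec_dim):
            out[:, c] = map_coordinates(
                self.vectors[..., c], coords.T, order=1, mode="nearest"
            )
        return out

    def map_points(self, points):
        pts = _as_points(points, self.grid_dim)
        disp = self.displacement(pts)
        if self.vec_dim == self.grid_dim:
            return pts + disp
        base = np.column_stack([pts, np.zeros(len(pts))])
        return base + disp

    def jacobian(self, points):
        """Finite-difference Jacobian (central, half-grid-step)."""
        pts = _as_points(points, self.grid_dim)
        jac = np.zeros((len(pts), self.dim_out, self.dim_in))
        eye = np.zeros((self.dim_out, self.dim_in))
        eye[: self.dim_in, : self.dim_in] = np.eye(self.dim_in)
        for a in range(self.grid_dim):
            h = 0.5 * self.spacing[a]
            step = np.zeros(self.grid_dim)
            step[a] = h
            dplus = self.displacement(pts + step)
            dminus = self.displacement(pts - step)
            jac[:, :, a] = (dplus - dminus) / (2 * h)
        return jac + eye


class ControlPointField(Transformation):
    """Sparse displacement field interpolated with Gaussian radial basis
    functions.

    ``points`` are fixed control-point locations (mm); ``displacements``
    are the optimisable vectors carried by them.  RBF weights are solved
    from the kernel system so the field interpolates the control values
    exactly.  ``active`` optionally restricts which vector components are
    exposed through ``params`` (e.g. in-plane only)."""

    def __init__(self, points, displacements=None, sigma=None, active=None):
        self.points = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        k, d = self.points.shape
        if k < 1:
            raise ConfigurationError("at least one control point required")
        self.displacements = (
            np.zeros((k, d))
            if displacements is None
            else np.asarray(displacements, dtype=float).reshape(k, d).copy()
        )
        if sigma is None:
            sigma = self._default_sigma()
        if sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        self.sigma = float(sigma)
        self.active = (
            tuple(range(d)) if active is None else tuple(int(a) for a in active)
        )
        self.dim_in = self.dim_out = d
        self._check_duplicates()
        self._kernel_lu = None  # lazy Cholesky-free LU of the kernel matrix
        self._weights = None

    def _default_sigma(self) -> float:
        if len(self.points) == 1:
            return 1.0
        diff = self.points[:, None, :] - self.points[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        return float(np.mean(dist.min(axis=1)))

    def _check_duplicates(self):
        if len(self.points) < 2:
            return
        diff = self.points[:, None, :] - self.points[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        dup = np.argwhere(dist < 1e-9)
        if dup.size:
            pairs = sorted({tuple(sorted(p)) for p in dup})
            raise ConfigurationError(f"duplicate control points at index pairs {pairs}")

    @property
    def params(self):
        return self.displacements[:, self.active].ravel().copy()

    @params.setter
    def params(self, values):
        v = np.asarray(values, dtype=float).reshape(len(self.points), len(self.active))
        self.displacements[:, self.active] = v
        self._weights = None

    def set_displacements(self, disp):
        self.displacements = np.asarray(disp, dtype=float).reshape(
            self.displacements.shape
        ).copy()
        self._weights = None

    def _kernel(self, a, b):
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
        return np.exp(-d2 / (2.0 * self.sigma**2))

    def _solve_weights(self):
        if self._weights is None:
            k = self._kernel(self.points, self.points)
            try:
                self._weights = np.linalg.solve(k, self.displacements)
            except np.linalg.LinAlgError as exc:
                raise ConfigurationError("singular RBF kernel system") from exc
        return self._weights

    def displacement(self, points) -> np.ndarray:
        pts = _as_points(points, self.dim_in)
        if not self.displacements.any():
            return np.zeros_like(pts)
        w = self._solve_weights()
        return self._kernel(pts, self.points) @ w

    def map_points(self, points):
        pts = _as_points(points, self.dim_in)
        return pts + self.displacement(pts)

    def jacobian(self, points):
        pts = _as_points(points, self.dim_in)
        w = self._solve_weights()  # (K, d)
        k = self._kernel(pts, self.points)  # (N, K)
        diff = pts[:, None, :] - self.points[None, :, :]  # (N, K, d)
        # d/dx of exp(-|x-p|^2 / 2s^2) = -(x-p)/s^2 * kernel
        grad = -(diff / self.sigma**2) * k[:, :, None]  # (N, K, d_in)
        jac = np.einsum("nkd,ke->ned", grad, w)  # jac[n, e, d] = du_e/dx_d
        d = self.dim_in
        return np.broadcast_to(np.eye(d), jac.shape).copy() + jac


def rbf_displace(field: ControlPointField, query_points) -> np.ndarray:
    """Displacement vectors (mm) of a control-point field at query points."""
    return field.displacement(query_points)
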