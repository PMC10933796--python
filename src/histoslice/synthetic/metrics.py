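"""Registration accuracy metrics: MRE and MCD."""

from __future__ import annotations

import numpy as np
import shapely

from ..core import ImageDomain, TensorImage, TransformChain
from ..errors import ConfigurationError, DegenerateInputError

__all__ = ["median_registration_error", "median_contour_distance"]


def median_registration_error(chain: TransformChain, truth_points: np.ndarray,
                              slice_domain: ImageDomain,
                              foreground=None) -> float:
    """Median distance between registered slice pixels and their
    corresponding ground-truth surface points (point-to-corresponding-
    point, in mm).

    ``chain`` is the external slice-to-volume chain; pixel indices are
    first pushed through the slice domain's internal chain."""
    truth = np.asarray(truth_points, dtype=float).reshape(-1, 3)
    idx = slice_domain.grid_indices()
    mapped = chain.apply(slice_domain.internal.apply(idx))
    if mapped.shape != truth.shape:
        raise ConfigurationError("truth points do not match the slice domain")
    err = np.linalg.norm(mapped - truth, axis=1)
    if foreground is not None:
        fg = np.asarray(foreground, dtype=bool).ravel()
        if not fg.any():
            raise DegenerateInputError("empty foreground for MRE")
        err = err[fg]
    return float(np.median(err))


def median_contour_distance(contour_a, contour_b,
                            sample_step: float = 0.05) -> float:
    """Median over densely resampled points of ``contour_a`` of the
    minimum (point-to-polyline) distance to ``contour_b`` — the directed
    MCD from the transformed moving contour to the fixed contour, in mm."""
    a = np.asarray(contour_a, dtype=float)
    b = np.asarray(contour_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateInputError("empty contour")
    pts = _densify(a, sample_step)
    if len(b) == 1:
        dist = np.linalg.norm(pts - b[0], axis=1)
    else:
        line = shapely.LineString(b)
        dist = shapely.distance(shapely.points(pts), line)
    return float(np.median(dist))


def _densify(polyline: np.ndarray, step: float) -> np.ndarray:
    if len(polyline) == 1:
        return polyline
    seg = np.diff(polyline, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    total = cum[-1]
    if total == 0:
        return polyline[:1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, polyline.shape[1]))
    for d in range(polyline.shape[1]):
        out[:, d] = np.interp(targets, cum, polyline[:, d])
    return out
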