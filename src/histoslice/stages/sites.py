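"""Sampling-site detection on serial brain-slab photographs.

Photographs of one slab face are ordered from most intact to most
excised (descending foreground area), consecutive pairs are aligned with
the stage-1 routine (coarser pyramid, higher regularisation, no masks),
the aligned pairs are binarized and XOR-ed, and the connected difference
components surviving the area/width filters are reported as candidate
block-sampling sites on the most intact photograph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import label, regionprops
from skimage.morphology import disk, opening

from ..core import (
    Affine2D,
    IsotropicScale,
    Rotation2D,
    TensorImage,
    TransformChain,
    Translation,
)
from ..errors import DegenerateInputError
from .config import SitesConfig
from .engine import ChainEvaluator
from .stage1 import linear_registration, nonlinear_registration

__all__ = ["SamplingSite", "detect_sampling_sites", "min_feret_diameter"]

log = logging.getLogger("histoslice.stages")


@dataclass
class SamplingSite:
    """Candidate block-extraction site on the most intact slab photo."""

    centroid: np.ndarray       # mm, physical coordinates of the intact photo
    area: float                # cm^2
    width: float               # mm, minimum caliper (feret) diameter
    pair_index: int            # consecutive photo pair that revealed it


def min_feret_diameter(points_mm: np.ndarray) -> float:
    """Minimum caliper width of a 2-D point cloud (rotating calipers on
    the convex hull)."""
    pts = np.asarray(points_mm, dtype=float)
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0
    verts = pts[hull.vertices]
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.linalg.norm(edges, axis=1)
    good = lengths > 1e-12
    normals = np.stack([-edges[good, 1], edges[good, 0]], axis=1)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    proj = verts @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.min())


def _register_pair(fixed: TensorImage, moving: TensorImage,
                   config: SitesConfig) -> TransformChain:
    """Align ``moving`` onto ``fixed`` (rigid, affine, non-linear)."""
    chain = TransformChain([
        Rotation2D(0.0), IsotropicScale(1.0), Translation((0.0, 0.0)), Affine2D(),
    ])

    class _LinCfg:
        linear_resolution = config.linear_resolution
        rotation_step = 30.0
        rotation_refine = 10.0
        scale_bounds = (0.9, 1.1)
        translation_bound = 5.0
        affine_matrix_bound = 0.1
        affine_offset_bound = 3.0
        tolerance = config.tolerance

    linear_registration(moving, fixed, chain, _LinCfg())
    nonlinear_registration(moving, fixed, chain, config.alpha, config.pyramid)
    return chain


def detect_sampling_sites(slab_photos, config: SitesConfig | None = None):
    """Find candidate sampling sites from >= 2 photos of one slab face.

    Returns a list of :class:`SamplingSite` with centroids in the
    physical coordinates of the most intact photo.  An empty list is a
    valid outcome (no confident sites)."""
    config = config or SitesConfig()
    photos = list(slab_photos)
    if len(photos) < 2:
        raise DegenerateInputError("at least two slab photos are required")

    order = sorted(
        range(len(photos)),
        key=lambda i: -int((photos[i].data > config.binarize_threshold
                            * photos[i].data.max()).sum()),
    )
    photos = [photos[i] for i in order]

    sites: list[SamplingSite] = []
    pair_chains: list[TransformChain] = []
    for k in range(len(photos) - 1):
        fixed, moving = photos[k], photos[k + 1]
        chain = _register_pair(fixed, moving, config)
        pair_chains.append(chain)

        # compare in the moving photo's frame: pull the fixed photo onto
        # the (level) moving grid through the recovered chain, binarize
        # both, XOR
        evaluator = ChainEvaluator(moving, fixed, config.pyramid[-1])
        warped_fixed, _ = evaluator.warp_fixed(chain)
        thr_m = config.binarize_threshold * evaluator.moving.data.max()
        thr_f = config.binarize_threshold * max(warped_fixed.max(), 1e-12)
        fg_moving = evaluator.moving.data > thr_m
        fg_fixed = warped_fixed > thr_f
        diff = fg_fixed ^ fg_moving

        res = float(evaluator.moving.resolution[0])
        # thin residual-misalignment rings along the slab outline would
        # bridge genuine sites; an opening well below the width filter
        # removes them without touching qualifying components
        radius = max(1, int(round(config.min_width_mm / 4.0 / res)))
        diff = opening(diff, disk(radius))
        labels = label(diff, connectivity=2)
        for region in regionprops(labels):
            area_cm2 = region.area * res**2 / 100.0
            if area_cm2 < config.min_area_cm2:
                continue
            coords_idx = np.asarray(region.coords, dtype=float)
            coords_mm = evaluator.moving.domain.index_to_physical(
                coords_idx, external=False
            )
            width = min_feret_diameter(coords_mm)
            if width < config.min_width_mm:
                continue
            centroid_local = coords_mm.mean(axis=0)
            # the site was found on the moving grid of pair k: its
            # position on photo k is chain(centroid); walk the earlier
            # pairwise chains back to the most intact photo
            pos = chain.apply(centroid_local[None])[0]
            for earlier in reversed(pair_chains[:-1]):
                pos = earlier.apply(pos[None])[0]
            sites.append(SamplingSite(pos, area_cm2, width, k))
    log.info("detected %d sampling site(s)", len(sites))
    return sites
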