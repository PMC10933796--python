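"""Standard phantom benchmark cases.

These builders assemble the deterministic desk-scale problems used by the
acceptance suite: simulated slice series with seeded pose perturbations
for the slice-to-volume stage, and slab/block/histology cases for the 2-D
stages.  Everything is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import find_contours

from ..core import TensorImage, TransformChain, Translation
from .phantom import (
    PhantomSpec,
    PhantomTruth,
    excise_blocks,
    invert_contrast,
    make_block_and_histology,
    make_phantom_volume,
    make_slab_photo,
)
from .surfaces import SliceSurface, sample_surface_slices

__all__ = [
    "default_phantom",
    "SliceCase",
    "slice_suite",
    "Stage2Case",
    "stage2_case",
    "Stage1Case",
    "stage1_case",
    "PERTURB_ROTATION_DEG",
    "PERTURB_INPLANE_MM",
    "PERTURB_NORMAL_MM",
]

# pose perturbation ranges for the simulated slice suites (chosen to
# reproduce initial misalignments of several millimetres)
PERTURB_ROTATION_DEG = 10.0
PERTURB_INPLANE_MM = 4.0
PERTURB_NORMAL_MM = 8.0

#: poses of the four-slice series: (tilt angles, normal offset mm)
SLICE_POSES = (
    ((0.0, 0.0, 0.0), -6.0),
    ((0.0, 0.0, 0.0), 4.0),
    ((0.0, 10.0, 0.0), 2.0),   # oblique: normal tilted about volume axis 1
    ((0.0, 0.0, 10.0), -3.0),  # oblique: normal tilted about volume axis 2
)


def default_phantom(seed: int = 0, shape: int = 96,
                    resolution: float = 0.5) -> TensorImage:
    return make_phantom_volume(
        PhantomSpec(shape=(shape,) * 3, resolution=resolution, seed=seed))


@dataclass
class SliceCase:
    image: TensorImage
    truth: PhantomTruth
    tilt: tuple
    prior_centre: tuple     # perturbed slab prior for stage 3
    prior_angles: tuple
    foreground: np.ndarray


def slice_suite(volume: TensorImage, order: int, seed: int = 0,
                n_slices: int = 4, slice_shape=(64, 64),
                max_deflection: float = 2.5):
    """Simulated slice series (planar or quadratic) with seeded pose
    perturbations expressed as perturbed stage-3 slab priors."""
    cases = []
    half = (slice_shape[0] - 1) / 2.0 * float(max(volume.resolution))
    shapes = [(0.8, 0.0, 0.5), (0.5, 0.2, 0.7), (0.9, 0.0, 0.3),
              (0.4, -0.2, 0.8)]
    # normalise each triple so the corner deflection equals max_deflection
    coefficients = [
        tuple(c * max_deflection / ((abs(a) + abs(b) + abs(cc)) * half**2)
              for c in (a, b, cc))
        for a, b, cc in shapes
    ]
    for i in range(n_slices):
        tilt, offset = SLICE_POSES[i % len(SLICE_POSES)]
        surf = SliceSurface(
            order=order,
            coefficients=coefficients[i % len(coefficients)] if order == 2
            else (0.0, 0.0, 0.0),
            tilt=tilt, offset=offset,
        )
        (image, truth), = sample_surface_slices(
            volume, [surf], slice_shape=slice_shape,
            resolution=float(max(volume.resolution)),
        )
        frame = truth.meta["frame"]
        rng = np.random.default_rng(seed * 1000 + i)
        d_rot = rng.uniform(-PERTURB_ROTATION_DEG, PERTURB_ROTATION_DEG, 3)
        d_in = rng.uniform(-PERTURB_INPLANE_MM, PERTURB_INPLANE_MM, 2)
        d_n = rng.uniform(-PERTURB_NORMAL_MM, PERTURB_NORMAL_MM)
        prior_angles = np.asarray(tilt, dtype=float) + d_rot
        prior_centre = (truth.meta["base"]
                        + d_in[0] * frame[:, 0] + d_in[1] * frame[:, 1]
                        + d_n * frame[:, 2])
        fg = image.data > 0.1 * image.data.max()
        cases.append(SliceCase(image, truth, tilt, tuple(prior_centre),
                               tuple(prior_angles), fg))
    return cases


@dataclass
class Stage2Case:
    slab: TensorImage
    slab_cut: TensorImage
    block_photo: TensorImage
    truth_chain: TransformChain      # block-photo physical mm -> slab mm
    contour: np.ndarray              # polyline in block-photo physical mm
    site_centre: np.ndarray
    other_rects: list


def stage2_case(seed: int = 0, deformation_mm: float = 0.3,
                n_extra_sites: int = 1) -> Stage2Case:
    """Slab photo with excised blocks plus the photographed block.

    The block photo is the slab crop pushed through a seeded smooth warp
    (the truth chain records it), so stage 2 must recover both the site
    and the deformation."""
    slab, clean = make_slab_photo(seed=seed)
    site_rect = ((6.0, -15.0), 22.0, 26.0)
    extra = [((-10.0, 15.0), 18.0, 22.0), ((18.0, 18.0), 16.0, 18.0)]
    rects = [site_rect] + extra[:n_extra_sites]
    cut = excise_blocks(slab, rects)
    _, block_photo, truth = make_block_and_histology(
        slab, site_rect, deformation_amplitude_mm=deformation_mm,
        contrast=None, histology_resolution=float(slab.resolution[0]),
        texture_amplitude=0.0, seed=seed + 11,
    )
    # same geometry sampled from the clean pattern for contour extraction
    _, block_clean, _ = make_block_and_histology(
        clean, site_rect, deformation_amplitude_mm=deformation_mm,
        contrast=None, histology_resolution=float(slab.resolution[0]),
        texture_amplitude=0.0, seed=seed + 11,
    )
    truth_chain = truth.chain.copy()
    truth_chain.append(Translation(np.asarray(site_rect[0], dtype=float)))
    level = 0.5 * (block_clean.data.min() + block_clean.data.max())
    contour_idx = max(find_contours(block_clean.data, level), key=len)
    contour_mm = block_photo.domain.index_to_physical(contour_idx,
                                                      external=False)
    return Stage2Case(slab, cut, block_photo, truth_chain, contour_mm,
                      np.asarray(site_rect[0], dtype=float),
                      extra[:n_extra_sites])


@dataclass
class Stage1Case:
    histology: TensorImage
    block: TensorImage
    truth_chain: TransformChain      # histology physical mm -> block mm
    contour: np.ndarray              # polyline in histology physical mm


def stage1_case(seed: int = 0, warp_px: float = 2.0) -> Stage1Case:
    """Histology/block pair: inverted contrast, seeded smooth warp of the
    stated pixel amplitude (at block resolution), fine texture."""
    slab, clean = make_slab_photo(seed=seed)
    rect = ((4.0, -8.0), 25.0, 35.0)
    res = float(slab.resolution[0])
    block, histology, truth = make_block_and_histology(
        slab, rect, deformation_amplitude_mm=warp_px * res,
        contrast=invert_contrast, histology_resolution=0.05,
        texture_amplitude=0.03, seed=seed + 21,
    )
    _, hist_clean, _ = make_block_and_histology(
        clean, rect, deformation_amplitude_mm=warp_px * res,
        contrast=invert_contrast, histology_resolution=0.05,
        texture_amplitude=0.0, seed=seed + 21,
    )
    contour_idx = max(
        find_contours(hist_clean.data,
                      0.5 * (hist_clean.data.min() + hist_clean.data.max())),
        key=len)
    contour_mm = histology.domain.index_to_physical(contour_idx,
                                                    external=False)
    return Stage1Case(histology, block, truth.chain.copy(), contour_mm)
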