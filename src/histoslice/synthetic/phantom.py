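"""Deterministic phantom generators.

The phantom volume mimics the contrast structure the pipeline relies on —
a folded high-intensity ribbon around a medium-intensity interior, dark
ventricle-like cavities, smooth texture and left-right asymmetry — at desk
scale, so every registration stage can be exercised with known ground
truth and no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from ..core import (
    ControlPointField,
    DenseDisplacementField,
    ImageDomain,
    TensorImage,
    TransformChain,
    Translation,
)
from ..errors import ConfigurationError

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom_volume",
    "make_slab_photo",
    "excise_blocks",
    "make_block_and_histology",
]

# intensity levels of the structural model
BACKGROUND = 0.0
WHITE_MATTER = 0.55
RIBBON = 0.95
VENTRICLE = 0.12


@dataclass
class PhantomSpec:
    """Parameters of the synthetic volume; output is a pure function of
    the spec (including its seed)."""

    shape: tuple = (96, 96, 96)
    resolution: float = 0.5           # mm / voxel
    ribbon_thickness: float = 3.0     # mm
    ventricle_size: float = 7.0       # mm
    texture_amplitude: float = 0.18
    texture_scale: float = 1.5        # voxels (Gaussian sigma)
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated image."""

    chain: TransformChain | None = None
    points: np.ndarray | None = None          # per-pixel target positions (mm)
    field: DenseDisplacementField | None = None
    contour: np.ndarray | None = None         # polyline in source pixel indices
    depth_offset: float = 0.0
    site_centre: np.ndarray | None = None     # mm, slab frame
    meta: dict = dc_field(default_factory=dict)


def _fold_modulation(direction, waves, amplitude):
    """Radial modulation from angular sinusoids; ``direction`` is (N, 3)
    unit vectors, ``waves`` a list of (freq_theta, freq_phi, phase)."""
    theta = np.arctan2(direction[:, 1], direction[:, 0])
    phi = np.arccos(np.clip(direction[:, 2], -1, 1))
    mod = np.zeros(len(direction))
    for ft, fp, ph in waves:
        mod += np.sin(ft * theta + fp * phi + ph)
    return 1.0 + amplitude * mod / max(len(waves), 1)


def make_phantom_volume(spec: PhantomSpec) -> TensorImage:
    """Brain-like 3-D test volume with reproducible structure.

    Two unequal hemisphere blobs with folded bright ribbons, dark interior
    cavities, smooth multiplicative texture and optional additive noise.
    """
    if min(spec.shape) < 48:
        raise ConfigurationError("phantom volume must be at least 48 voxels per axis")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    res = float(spec.resolution)
    domain = ImageDomain.centred(shape, res)
    pts = domain.grid_indices() * res - (np.asarray(shape) - 1) / 2.0 * res
    extent = np.asarray(shape) * res

    data = np.full(int(np.prod(shape)), BACKGROUND)
    # hemispheres: offset along axis 2 (left-right), left slightly larger
    hemi = [
        # (centre frac, radii frac, fold waves, fold amplitude)
        ((0.0, 0.0, -0.26), (0.42, 0.40, 0.24), [(4, 3, 0.5), (7, 2, 1.7)], 0.09),
        ((0.0, 0.02, 0.26), (0.38, 0.36, 0.21), [(5, 2, 2.9), (6, 4, 0.3)], 0.08),
    ]
    ribbon_frac = spec.ribbon_thickness / (0.4 * extent.min())
    for centre_f, radii_f, waves, amp in hemi:
        centre = np.asarray(centre_f) * extent
        radii = np.asarray(radii_f) * extent
        rel = (pts - centre) / radii
        dist = np.sqrt((rel**2).sum(1))
        with np.errstate(invalid="ignore", divide="ignore"):
            direction = rel / np.maximum(dist[:, None], 1e-12)
        boundary = _fold_modulation(direction, waves, amp)
        inside = dist < boundary
        interior = dist < boundary * (1.0 - ribbon_frac)
        data[inside] = RIBBON
        data[interior] = WHITE_MATTER
        # ventricle-like cavity
        vrad = spec.ventricle_size / 2.0
        vrel = (pts - centre - np.array([0.0, 0.0, 0.0])) / np.array(
            [vrad * 1.6, vrad, vrad]
        )
        data[(vrel**2).sum(1) < 1.0] = VENTRICLE

    vol = data.reshape(shape)
    tissue = vol > BACKGROUND
    texture = gaussian_filter(
        rng.standard_normal(shape), spec.texture_scale, mode="reflect"
    )
    texture /= max(texture.std(), 1e-12)
    vol = vol * (1.0 + spec.texture_amplitude * texture * tissue)
    if spec.noise_sd > 0:
        vol = vol + spec.noise_sd * rng.standard_normal(shape)
    vol = np.clip(vol, 0.0, None)
    return TensorImage(vol, domain)


# ---------------------------------------------------------------------------
# 2-D slab photograph model (for stage 1/2 phantoms)
# ---------------------------------------------------------------------------

def _slab_pattern(points_mm, half_extent, rng, texture_sigma_mm=1.0,
                  texture_amplitude=0.2):
    """Clean 2-D slab-face pattern evaluated at mm coordinates.

    Returns the structural value per point; texture is added separately by
    the caller on the pixel grid."""
    y, x = points_mm[:, 0], points_mm[:, 1]
    hy, hx = half_extent
    rel = np.sqrt((y / (0.88 * hy)) ** 2 + (x / (0.9 * hx)) ** 2)
    theta = np.arctan2(y / hy, x / hx)
    boundary = 1.0 + 0.10 * np.sin(5 * theta + 0.8) + 0.06 * np.sin(9 * theta + 2.2)
    val = np.full(len(points_mm), BACKGROUND)
    inside = rel < boundary
    ribbon = rel > boundary * 0.82
    val[inside] = WHITE_MATTER
    val[inside & ribbon] = RIBBON
    # interior dark cavities, asymmetric
    for cy, cx, ry, rx in ((0.15 * hy, -0.3 * hx, 6.0, 3.0),
                           (-0.1 * hy, 0.25 * hx, 4.0, 2.5)):
        d = ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2
        val[d < 1.0] = VENTRICLE
    # a few bright cord-like streaks for in-plane saliency
    streak = (np.sin(0.9 * y + 0.31 * x) * np.cos(0.53 * x - 0.2 * y))
    val[inside] *= 1.0 + 0.08 * streak[inside]
    return val


def make_slab_photo(size_mm=(80.0, 110.0), resolution: float = 0.2,
                    seed: int = 0, texture_amplitude: float = 0.2,
                    texture_sigma_mm: float = 0.8):
    """Synthetic photograph of a brain-slab face.

    Returns ``(photo, clean)`` where ``clean`` is the texture-free
    structural pattern (useful for extracting ground-truth contours)."""
    rng = np.random.default_rng(seed)
    shape = tuple(int(round(s / resolution)) for s in size_mm)
    domain = ImageDomain.centred(shape, resolution)
    pts = domain.physical_points(external=False)
    half = (size_mm[0] / 2.0, size_mm[1] / 2.0)
    clean = _slab_pattern(pts, half, rng).reshape(shape)
    texture = gaussian_filter(rng.standard_normal(shape),
                              texture_sigma_mm / resolution, mode="reflect")
    texture /= max(texture.std(), 1e-12)
    photo = clean * (1.0 + texture_amplitude * texture * (clean > BACKGROUND))
    photo = np.clip(photo, 0.0, None)
    return TensorImage(photo, domain), TensorImage(clean, domain.copy())


def excise_blocks(photo: TensorImage, rectangles) -> TensorImage:
    """Copy of a slab photo with rectangular regions (centre mm, height mm,
    width mm) replaced by background — the state after block sampling."""
    out = photo.copy()
    pts = photo.domain.physical_points(external=False)
    for centre, h, w in rectangles:
        cy, cx = centre
        inside = (np.abs(pts[:, 0] - cy) <= h / 2.0) & (
            np.abs(pts[:, 1] - cx) <= w / 2.0
        )
        out.data.ravel()[inside] = BACKGROUND
    return out


def _smooth_warp_field(extent_mm, amplitude_mm, seed, n_ctrl=4):
    """Seeded smooth RBF displacement field over a rectangle centred on
    the origin; peak magnitude scaled to ``amplitude_mm``."""
    rng = np.random.default_rng(seed)
    hy, hx = extent_mm[0] / 2.0, extent_mm[1] / 2.0
    gy = np.linspace(-hy, hy, n_ctrl)
    gx = np.linspace(-hx, hx, n_ctrl)
    pts = np.array([(a, b) for a in gy for b in gx])
    disp = rng.uniform(-1, 1, size=pts.shape)
    fld = ControlPointField(pts, disp, sigma=max(hy, hx) / (n_ctrl - 1) * 1.5)
    # scale to the requested peak magnitude
    probe = np.array([(a, b) for a in np.linspace(-hy, hy, 17)
                      for b in np.linspace(-hx, hx, 17)])
    peak = np.linalg.norm(fld.displacement(probe), axis=1).max()
    if peak > 0:
        fld.set_displacements(disp * (amplitude_mm / peak))
    return fld


def invert_contrast(values: np.ndarray) -> np.ndarray:
    """Monotone-decreasing intensity remap used for histology emulation."""
    peak = values.max()
    if peak <= 0:
        return values.copy()
    return (1.0 - values / peak) ** 1.2


def make_block_and_histology(slab_photo: TensorImage, site,
                             deformation_amplitude_mm: float = 0.4,
                             contrast=invert_contrast,
                             depth_offset: float = 0.0,
                             histology_resolution: float = 0.05,
                             texture_amplitude: float = 0.03,
                             seed: int = 0,
                             clean: TensorImage | None = None):
    """Cut a block from a slab photo and emulate its histology section.

    ``site`` is ``(centre_mm, height_mm, width_mm)`` in slab physical
    coordinates.  The histology image samples the block through a known
    smooth warp, applies a monotone contrast remap and adds seeded
    fine-scale texture.  Returns ``(block, histology, truth)`` where the
    truth chain maps histology pixel indices to block physical mm.
    """
    centre, h, w = site
    centre = np.asarray(centre, dtype=float)
    res = float(slab_photo.resolution[0])
    pts = slab_photo.domain.physical_points(external=False)
    hy = np.abs(pts[:, 0]).max()
    hx = np.abs(pts[:, 1]).max()
    if np.abs(centre[0]) + h / 2 > hy or np.abs(centre[1]) + w / 2 > hx:
        raise ConfigurationError("block rectangle exceeds the slab extent")

    bshape = (int(round(h / res)), int(round(w / res)))
    bdomain = ImageDomain.centred(bshape, res)
    bpts = bdomain.physical_points(external=False)
    slab_idx = slab_photo.domain.physical_to_index(bpts + centre, external=False)
    bdata = map_coordinates(slab_photo.data, slab_idx.T, order=1,
                            mode="constant", cval=BACKGROUND).reshape(bshape)
    block = TensorImage(bdata, bdomain)

    rng = np.random.default_rng(seed)
    hshape = tuple(int(round(s * res / histology_resolution)) for s in bshape)
    hdomain = ImageDomain.centred(hshape, histology_resolution)
    hpts = hdomain.physical_points(external=False)
    warp = None
    if deformation_amplitude_mm > 0:
        warp = _smooth_warp_field((h, w), deformation_amplitude_mm, seed)
        target = hpts + warp.displacement(hpts)
    else:
        target = hpts
    src_idx = slab_photo.domain.physical_to_index(target + centre, external=False)
    sampled = map_coordinates(slab_photo.data, src_idx.T, order=1,
                              mode="constant", cval=BACKGROUND).reshape(hshape)
    hist = contrast(sampled) if contrast is not None else sampled
    if texture_amplitude > 0:
        fine = gaussian_filter(rng.standard_normal(hshape), 1.0, mode="reflect")
        fine /= max(fine.std(), 1e-12)
        hist = np.clip(hist + texture_amplitude * fine, 0.0, None)
    histology = TensorImage(hist, hdomain)

    truth_members = []
    if warp is not None:
        truth_members.append(warp)
    truth_chain = TransformChain(truth_members)
    truth = PhantomTruth(
        chain=truth_chain,
        field=None,
        site_centre=centre,
        depth_offset=depth_offset,
        meta={"warp": warp, "block_size_mm": (h, w)},
    )
    return block, histology, truth
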