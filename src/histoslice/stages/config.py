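"""Per-stage parameter bundles and YAML plumbing.

Shipped defaults equal the published "typical" values: stage-1 pyramid
0.8/0.4/0.2 mm/px with histology FWHM 6.25 px; site detection at 1.5 and
1.0 mm/px with alpha 0.6; stage-2 grid search in 30 degree increments and
+/-10 mm around each site with the best 3 refined; stage-3 pyramid
2/1/0.5/0.25 mm/px, 5-11 axis positions, 3 rotation values in a 30 degree
range per axis, 32 control points; stage-4 16 control points and a +/-2 mm
perpendicular bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields as dc_fields

import numpy as np
import yaml

from ..errors import ConfigurationError

__all__ = [
    "Stage1Config",
    "SitesConfig",
    "Stage2Config",
    "Stage3Config",
    "Stage4Config",
    "load_config",
    "save_config",
]


@dataclass
class Stage1Config:
    pyramid: tuple = (0.8, 0.4, 0.2)      # mm/px for the non-linear step
    linear_resolution: float = 0.4        # mm/px for the linear steps
    alpha: float = 0.35
    histology_fwhm: float = 6.25          # px, histology downsampling kernel
    pad_fraction: float = 1.0 / 6.0
    rotation_step: float = 30.0           # deg, coarse rotation search
    rotation_refine: float = 20.0         # deg, bound around grid optimum
    scale_bounds: tuple = (0.8, 1.25)
    translation_bound: float = 10.0       # mm
    affine_matrix_bound: float = 0.25
    affine_offset_bound: float = 5.0      # mm
    max_gn_iterations: int = 20
    tolerance: float = 1e-4
    seed: int = 0


@dataclass
class SitesConfig:
    pyramid: tuple = (1.5, 1.0)
    alpha: float = 0.6
    linear_resolution: float = 1.5
    binarize_threshold: float = 0.1       # fraction of per-image max
    min_area_cm2: float = 1.0
    min_width_mm: float = 4.0
    tolerance: float = 1e-3
    seed: int = 0


@dataclass
class Stage2Config:
    pyramid: tuple = (0.8, 0.4, 0.2)
    linear_resolution: float = 0.4
    grid_resolution: float = 1.6          # mm/px for site initialisation
    alpha: float = 0.35
    mask_threshold: float = 0.1           # 10% relative intensity
    rotation_step: float = 30.0           # deg
    rotation_refine: float = 15.0         # deg, rigid-step bound
    translation_range: float = 10.0       # mm around each site
    translation_step: float = 5.0         # mm grid step within the range
    refine_keep: int = 3                  # candidates refined per site
    scale_bounds: tuple = (0.8, 1.25)
    affine_matrix_bound: float = 0.25
    affine_offset_bound: float = 5.0
    max_gn_iterations: int = 20
    tolerance: float = 1e-4
    seed: int = 0


@dataclass
class Stage3Config:
    pyramid: tuple = (2.0, 1.0, 0.5)      # mm/px, coarse to fine
    photo_fwhm: float = 5.0               # px
    slab_thickness: float = 20.0          # mm, rigid search extent
    slab_centre: tuple = (0.0, 0.0, 0.0)  # mm, prior
    slab_angles: tuple = (0.0, 0.0, 0.0)  # deg, prior orientation
    n_axis_positions: int = 7             # 5-11 equidistant points
    inplane_search: float = 4.0           # mm, +/- in-plane sweep offsets
    rotation_range: float = 30.0          # deg, 3 values in this range/axis
    initial_keep: int = 12                # survivors of the coarse sweep
    prune_fraction: float = 0.5           # kept between pyramid levels
    prune_min: int = 3
    refine_rotation_bound: float = 20.0   # deg around current estimate
    refine_translation_bound: float = 6.0 # mm around current estimate
    affine_matrix_bound: float = 0.15
    affine_offset_bound: float = 2.0      # mm
    n_control_points: int = 32
    control_sigma: float | None = None    # mm; None = mean NN spacing
    inplane_bound: float = 2.0            # mm, step-3 displacement bound
    deform_bound: float = 4.0             # mm, step-4 displacement bound
    mask_threshold: float = 0.1
    tolerance: float = 1e-4
    final_tolerance: float = 1e-7
    seed: int = 0


@dataclass
class Stage4Config:
    pyramid: tuple = (1.0, 0.5)
    n_control_points: int = 16
    control_sigma: float | None = None
    perpendicular_bound: float = 2.0      # mm
    inplane_translation_bound: float = 3.0
    rotation_bound: float = 10.0          # deg
    fit_grid: int = 32                    # reparameterisation sample grid
    fit_residual_threshold: float = 0.5   # mm, median
    run_nonlinear: bool = False           # default stops after linear steps
    deform_bound: float = 2.0             # mm, if non-linear steps enabled
    mask_threshold: float = 0.1
    tolerance: float = 1e-5
    seed: int = 0


_STAGES = {
    "stage1": Stage1Config,
    "sites": SitesConfig,
    "stage2": Stage2Config,
    "stage3": Stage3Config,
    "stage4": Stage4Config,
}


def _coerce(cls, data: dict):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})
    for f in dc_fields(cls):
        v = getattr(cfg, f.name)
        if isinstance(v, (int, float)) and not np.isfinite(v):
            raise ConfigurationError(f"non-finite config value for {f.name}")
    return cfg


def load_config(path_or_dict, stage: str):
    """Build a stage config from a YAML file (or parsed dict).

    The YAML may either hold the stage parameters at top level or nest
    them under the stage name."""
    if stage not in _STAGES:
        raise ConfigurationError(f"unknown stage '{stage}'")
    cls = _STAGES[stage]
    if path_or_dict is None:
        return cls()
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    if stage in data and isinstance(data[stage], dict):
        data = data[stage]
    return _coerce(cls, data)


def save_config(config, path):
    stage = next(name for name, cls in _STAGES.items()
                 if isinstance(config, cls))
    with open(path, "w") as fh:
        yaml.safe_dump({stage: _plain(asdict(config))}, fh)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    return obj
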