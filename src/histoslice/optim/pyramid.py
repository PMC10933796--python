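"""Multi-resolution scheduling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import TensorImage, gaussian_downsample
from ..errors import ConfigurationError

__all__ = ["PyramidSchedule", "at_resolution"]


@dataclass
class PyramidSchedule:
    """Ordered list of working resolutions in mm/pixel, coarse to fine."""

    resolutions: tuple

    def __post_init__(self):
        res = tuple(float(r) for r in self.resolutions)
        if not res:
            raise ConfigurationError("empty pyramid schedule")
        if any(b >= a for a, b in zip(res, res[1:]) if True) and not all(
            a > b for a, b in zip(res, res[1:])
        ):
            raise ConfigurationError("pyramid resolutions must strictly decrease")
        self.resolutions = res

    def __iter__(self):
        return iter(self.resolutions)

    def __len__(self):
        return len(self.resolutions)


def at_resolution(image: TensorImage, target_mm: float,
                  smooth_factor: float = 2.0) -> TensorImage:
    """Anti-aliased representation of ``image`` at ``target_mm`` per pixel.

    Smoothing FWHM scales with the downsampling factor; images already at
    (or coarser than) the target are returned unchanged."""
    src = float(np.max(image.resolution))
    if target_mm <= src * (1 + 1e-9):
        return image
    factor = target_mm / src
    return gaussian_downsample(image, fwhm=smooth_factor * factor, target_resolution=target_mm)
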