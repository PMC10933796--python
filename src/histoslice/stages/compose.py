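"""Full-chain composition: histology pixels to (any) MRI voxel space."""

from __future__ import annotations

import numpy as np

from ..core import Affine3D, TransformChain
from ..errors import ConfigurationError

__all__ = ["compose_full_chain"]


def _static_dim_check(members):
    dim = None
    for i, m in enumerate(members):
        if m.dim_in is not None:
            if dim is not None and m.dim_in != dim:
                raise ConfigurationError(
                    f"incompatible dimensionality at junction {i - 1} -> {i}: "
                    f"{dim}-D output meets {m.dim_in}-D input "
                    f"({type(members[i - 1]).__name__} -> {type(m).__name__})"
                )
            dim = m.dim_in
        if m.dim_out is not None:
            dim = m.dim_out


def compose_full_chain(stage_chains, flirt_matrices=None) -> TransformChain:
    """Concatenate per-stage chains into a single mapping and optionally
    append 4x4 physical-mm affines (e.g. imported FLIRT matrices) to reach
    other MRI modality spaces."""
    members = []
    for chain in stage_chains:
        if isinstance(chain, TransformChain):
            members.extend(chain.members)
        else:
            members.append(chain)
    if flirt_matrices is not None:
        mats = np.asarray(flirt_matrices, dtype=float)
        if mats.ndim == 2:
            mats = mats[None]
        for mat in mats:
            if mat.shape != (4, 4):
                raise ConfigurationError("appended matrices must be 4x4")
            members.append(Affine3D.from_homogeneous(mat))
    _static_dim_check(members)
    return TransformChain([m.copy() for m in members])
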