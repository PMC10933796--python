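"""Exhaustive candidate evaluation with stable ranking."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, HistosliceError

__all__ = ["RankedCandidate", "grid_search_rank"]


@dataclass
class RankedCandidate:
    ordinal: int          # position in the input candidate list
    parameters: object
    cost: float


def grid_search_rank(candidates, objective, keep: int):
    """Evaluate every candidate and return the best ``keep`` of them.

    Sorting is by cost ascending with ties broken by input ordinal, so the
    ranking is fully deterministic.  Non-finite candidates are dropped; if
    every candidate is non-finite an error is raised."""
    candidates = list(candidates)
    if not candidates:
        raise ConfigurationError("empty candidate list")
    ranked = []
    for i, cand in enumerate(candidates):
        cost = float(objective(cand))
        if np.isfinite(cost):
            ranked.append(RankedCandidate(i, cand, cost))
    if not ranked:
        raise HistosliceError("all grid-search candidates evaluated non-finite")
    ranked.sort(key=lambda rc: (rc.cost, rc.ordinal))
    return ranked[: max(1, int(keep))]
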