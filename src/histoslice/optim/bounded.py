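"""Bounded derivative-free local minimisation.

The contract is BOBYQA-like: bounded, gradient-free, local, deterministic.
The implementation delegates to scipy's bounded Powell method, which
satisfies the same post-conditions (feasible result, objective never above
the initial value)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ..errors import ConfigurationError, HistosliceError

__all__ = ["OptimisationGroup", "bounded_minimise", "optimise_chain_group"]


@dataclass
class OptimisationGroup:
    """A bounded parameter group for local optimisation.

    ``selector`` (optional) addresses chain parameters; ``initial`` is the
    start vector, ``lower``/``upper`` the per-parameter bounds."""

    initial: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    selector: object = None
    trust_radius: float | None = None  # default: 10% of bound width
    tolerance: float = 1e-4
    max_evaluations: int = 10000

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float).ravel()
        self.lower = np.asarray(self.lower, dtype=float).ravel()
        self.upper = np.asarray(self.upper, dtype=float).ravel()
        if not (self.lower.shape == self.upper.shape == self.initial.shape):
            raise ConfigurationError("bounds/initial shape mismatch")
        if np.any(self.lower > self.upper):
            raise ConfigurationError("lower bound exceeds upper bound")
        if np.any(self.initial < self.lower - 1e-12) or np.any(
            self.initial > self.upper + 1e-12
        ):
            raise ConfigurationError("initial value outside bounds")


def bounded_minimise(objective, group: OptimisationGroup):
    """Minimise ``objective`` within the group's box bounds.

    Returns ``(parameters, cost)`` with ``cost <= objective(initial)`` and
    parameters strictly inside the bounds.  Raises on a non-finite start;
    aborts with a diagnostic if the objective keeps returning non-finite
    values during the search."""
    x0 = np.clip(group.initial, group.lower, group.upper)
    f0 = float(objective(x0))
    if not np.isfinite(f0):
        raise HistosliceError("objective non-finite at the initial point")

    bad = {"count": 0}

    def wrapped(x):
        v = float(objective(np.clip(x, group.lower, group.upper)))
        if not np.isfinite(v):
            bad["count"] += 1
            if bad["count"] > 50:
                raise HistosliceError(
                    "objective returned non-finite values repeatedly during "
                    "bounded minimisation"
                )
            return 1e30
        return v

    span = group.upper - group.lower
    scale = np.where(span > 0, span, 1.0)
    if group.initial.size == 0:
        return group.initial.copy(), f0
    res = minimize(
        wrapped,
        x0,
        method="Powell",
        bounds=list(zip(group.lower, group.upper)),
        options={
            "xtol": group.tolerance,
            "ftol": group.tolerance * 1e-2,
            "maxfev": group.max_evaluations,
            "direc": np.diag(
                scale * (0.1 if group.trust_radius is None else group.trust_radius)
            ),
        },
    )
    x = np.clip(np.atleast_1d(res.x), group.lower, group.upper)
    fx = float(objective(x))
    if fx > f0:  # guarantee the non-worsening post-condition
        return x0, f0
    return x, fx


def optimise_chain_group(chain, selector, cost_fn, lower, upper,
                         tolerance=1e-4, max_evaluations=10000):
    """Optimise the chain parameters addressed by ``selector`` in place.

    ``cost_fn`` is a zero-argument callable evaluating the current chain
    state.  Returns the final cost."""
    selector.validate(chain)
    x0 = selector.get(chain)

    def objective(x):
        selector.set(chain, x)
        return cost_fn()

    group = OptimisationGroup(
        initial=x0, lower=np.asarray(lower, float), upper=np.asarray(upper, float),
        selector=selector, tolerance=tolerance, max_evaluations=max_evaluations,
    )
    best, cost = bounded_minimise(objective, group)
    selector.set(chain, best)
    return cost
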