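"""Bipolar-II mood oscillator: vector field, regressor, parameters, equilibrium.

The model is a van der Pol / Liénard oscillator for a scalar "emotional mood"
x(t).  In state-space form with x1 = mood and x2 = mood change rate,

    dx1/dt = x2
    dx2/dt = -c*x1 + b*a*x2 - b*x1**2*x2 + u

where u is the treatment (control) input.  With u = 0 any nonzero initial
mood settles onto a stable limit cycle — the untreated mood swing.  The drift
of the x2 equation is linear in the parameter triple theta = (c, b*a, b) with
regressor W = (-x1, x2, -x1**2*x2), which is what makes adaptive control of
the model tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MoodModel",
    "MoodState",
    "vector_field",
    "regressor",
    "pack_parameters",
    "equilibrium",
]


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class MoodModel:
    """Patient parameters of the mood oscillator.

    Parameters
    ----------
    a : float
        Damping-threshold parameter (> 0).  Mood excursions with ``|x1| <
        sqrt(a)`` are anti-damped (the swing grows); beyond it damping is
        positive.
    b : float
        Nonlinear damping gain (> 0); scales how strongly the state-dependent
        damping acts.
    c : float
        Restoring stiffness (> 0); ``sqrt(c)`` is the small-``b`` angular
        frequency of the swing.

    All three are dimensionless; the model carries no physical units.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"model parameter {name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class MoodState:
    """State of the oscillator: mood ``x1`` and its change rate ``x2``."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        _require_finite("state component", self.x1, self.x2)

    def as_tuple(self) -> tuple[float, float]:
        return (self.x1, self.x2)


def vector_field(model: MoodModel, state: MoodState, u: float) -> MoodState:
    """Evaluate the mood-oscillator vector field (dx1/dt, dx2/dt).

    Returns the state derivative under treatment input ``u``:
    ``dx1/dt = x2`` and ``dx2/dt = -c*x1 + b*a*x2 - b*x1**2*x2 + u``.
    The returned object reuses :class:`MoodState` as a plain (dx1, dx2) pair.
    """
    _require_finite("control input u", u)
    x1, x2 = state.x1, state.x2
    dx2 = -model.c * x1 + model.b * model.a * x2 - model.b * x1 * x1 * x2 + u
    return MoodState(x2, dx2)


def regressor(state: MoodState) -> tuple[float, float, float]:
    """Regression vector W = (-x1, x2, -x1**2 * x2).

    Satisfies ``dot(W, theta) == drift of dx2/dt`` for
    ``theta = pack_parameters(model)``, i.e. the x2 dynamics are linear in
    the unknown parameters.
    """
    x1, x2 = state.x1, state.x2
    return (-x1, x2, -x1 * x1 * x2)


def pack_parameters(model: MoodModel) -> tuple[float, float, float]:
    """Parameter vector theta = (c, b*a, b) of the linear-in-parameters form."""
    return (model.c, model.b * model.a, model.b)


def unpack_parameters(theta: tuple[float, float, float]) -> MoodModel:
    """Inverse of :func:`pack_parameters`: (c, ba, b) -> MoodModel(a, b, c)."""
    c, ba, b = theta
    return MoodModel(a=ba / b, b=b, c=c)


def equilibrium(model: MoodModel) -> MoodState:
    """The unique equilibrium of the unforced model: the origin.

    Setting dx1/dt = 0 forces x2 = 0, and then dx2/dt = -c*x1 = 0 forces
    x1 = 0 since c > 0.
    """
    # model validity is enforced at construction; the origin is exact
    assert model.c > 0
    return MoodState(0.0, 0.0)
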