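"""Backstepping treatment controllers for the mood oscillator.

Two control laws drive the mood x1 and its rate x2 to the origin:

* exact-model-knowledge (EMK): uses the true parameter triple
  theta = (c, b*a, b) to cancel the plant drift, leaving a linear,
  exponentially stable closed loop;
* adaptive: replaces theta with a running estimate theta_hat driven by the
  gradient update rule d(theta_hat)/dt = Gamma @ W * h, guaranteeing
  boundedness and state convergence without knowing the parameters.

Both are built on the backstepping variable h = x2 - x2d with virtual
control x2d = -k1*x1: stabilising x1 through x2 and then shaping the h
dynamics with the actual input u.

Sign convention: differentiating x2d = -k1*x1 along dx1/dt = -k1*x1 + h
gives dh/dt = W.theta + u - k1**2*x1 + k1*h, so the stabilising law is

    u = -W.theta + k1**2*x1 - k1*h - x1 - k2*h

which produces exactly dx1/dt = -k1*x1 + h and dh/dt = -k2*h - x1 (and, in
the adaptive case, dh/dt = -k2*h - x1 + W.theta_tilde).  A variant with the
k1**2 and k1 terms flipped (``as_printed=True``) is kept for comparison; it
is still stabilising for the default gains but does not achieve the exact
cancellation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import MoodModel, MoodState, pack_parameters, regressor

__all__ = [
    "ControlGains",
    "AdaptationGain",
    "backstepping_error",
    "emk_control",
    "adaptive_control",
    "update_law",
]


@dataclass(frozen=True)
class ControlGains:
    """Backstepping gains: k1 shapes the x1 loop, k2 the h loop; both > 0."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"control gain {name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class AdaptationGain:
    """3x3 symmetric positive-definite update-gain matrix Gamma."""

    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"adaptation gain must be 3x3, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("adaptation gain must be finite")
        if not np.allclose(m, m.T, rtol=0.0, atol=1e-12):
            raise ValueError("adaptation gain must be symmetric")
        if np.min(np.linalg.eigvalsh(m)) <= 0:
            raise ValueError("adaptation gain must be positive-definite")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def scaled_identity(cls, gain: float) -> "AdaptationGain":
        return cls(gain * np.eye(3))

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def backstepping_error(state: MoodState, k1: float) -> float:
    """Backstepping variable h = x2 - x2d = x2 + k1*x1 (x2d = -k1*x1)."""
    if not (math.isfinite(k1) and k1 > 0):
        raise ValueError(f"gain k1 must be finite and > 0, got {k1!r}")
    return state.x2 + k1 * state.x1


def _stabilizing_input(w_dot_theta: float, state: MoodState, gains: ControlGains,
                       as_printed: bool) -> float:
    h = backstepping_error(state, gains.k1)
    x1 = state.x1
    if as_printed:
        # law with the k1^2 / k1 signs as originally stated; stabilising for
        # the default gains but without the exact drift cancellation
        return -w_dot_theta - gains.k1 ** 2 * x1 + gains.k1 * h - x1 - gains.k2 * h
    return -w_dot_theta + gains.k1 ** 2 * x1 - gains.k1 * h - x1 - gains.k2 * h


def emk_control(model: MoodModel, state: MoodState, gains: ControlGains,
                as_printed: bool = False) -> float:
    """Exact-model-knowledge control input.

    u = -W.theta + k1**2*x1 - k1*h - x1 - k2*h, cancelling the plant drift so
    the closed loop is linear: dx1/dt = -k1*x1 + h, dh/dt = -k2*h - x1.
    """
    theta = pack_parameters(model)
    w = regressor(state)
    w_dot_theta = w[0] * theta[0] + w[1] * theta[1] + w[2] * theta[2]
    return _stabilizing_input(w_dot_theta, state, gains, as_printed)


def adaptive_control(theta_hat, state: MoodState, gains: ControlGains,
                     as_printed: bool = False) -> float:
    """Adaptive control input: the EMK law with theta replaced by theta_hat.

    Substituted into the plant, the closed h dynamics carry a residual
    W.theta_tilde (theta_tilde = theta - theta_hat) that the update law
    cancels in the Lyapunov derivative.
    """
    w = regressor(state)
    w_dot_theta = w[0] * theta_hat[0] + w[1] * theta_hat[1] + w[2] * theta_hat[2]
    return _stabilizing_input(w_dot_theta, state, gains, as_printed)


def update_law(state: MoodState, k1: float, gamma: AdaptationGain) -> np.ndarray:
    """Gradient parameter update: d(theta_hat)/dt = Gamma @ W * h.

    Chosen so the cross term h * W.theta_tilde cancels exactly in the
    derivative of the adaptive Lyapunov function, leaving
    dV/dt = -k1*x1**2 - k2*h**2.
    """
    h = backstepping_error(state, k1)
    w = np.asarray(regressor(state), dtype=float)
    return gamma.matrix @ w * h


def closed_loop_matrix(gains: ControlGains, as_printed: bool = False) -> np.ndarray:
    """Linear (x1, h) closed-loop matrix under the EMK law.

    For the corrected law this is [[-k1, 1], [-1, -k2]]; for the as-printed
    variant the uncancelled k1-terms re-enter the h row.  Useful both as the
    matrix-exponential simulation oracle and for eigenvalue stability checks.
    """
    k1, k2 = gains.k1, gains.k2
    if as_printed:
        # dh/dt = u-terms + k1*h - k1^2*x1 with the printed u
        return np.array([[-k1, 1.0], [-2.0 * k1 ** 2 - 1.0, 2.0 * k1 - k2]])
    return np.array([[-k1, 1.0], [-1.0, -k2]])
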