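"""Closed- and open-loop time integration of the mood oscillator.

Three scenarios are supported: untreated (u = 0, the sustained mood swing),
exact-model-knowledge backstepping treatment, and adaptive backstepping
treatment with online parameter estimation.  The default integrator is
fixed-step classical RK4 with the control law evaluated inside every
derivative stage (continuous-time feedback, no zero-order hold); a SciPy
adaptive stepper (RK45) is available as an alternative.  Everything is
deterministic: identical configurations produce bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .controllers import AdaptationGain, ControlGains, adaptive_control, emk_control
from .model import MoodModel, MoodState, pack_parameters, vector_field

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "IntegrationError",
    "simulate_untreated",
    "simulate_emk",
    "simulate_adaptive",
]

#: states with any component beyond this magnitude abort the run
OVERFLOW_GUARD = 1e6

_METHODS = ("rk4-fixed", "adaptive-stepper")


class IntegrationError(RuntimeError):
    """Raised when a trajectory blows up; carries the time of failure."""

    def __init__(self, time: float, message: str | None = None):
        self.time = time
        super().__init__(message or f"state exceeded overflow guard at t={time:.6g}")


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings for one scenario run.

    duration and step are in the model's dimensionless time unit.  The step
    must resolve the run (step <= duration / 100).  ``record_every`` thins
    the output grid (1 = keep every step).
    """

    duration: float = 10.0
    step: float = 1e-3
    method: str = "rk4-fixed"
    initial_state: MoodState = MoodState(0.5, 0.0)
    initial_estimate: Optional[tuple[float, float, float]] = None
    record_every: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"duration must be finite and > 0, got {self.duration!r}")
        if not (math.isfinite(self.step) and self.step > 0):
            raise ValueError(f"step must be finite and > 0, got {self.step!r}")
        if self.step > self.duration / 100:
            raise ValueError(
                f"step {self.step} too coarse for duration {self.duration} "
                "(need step <= duration / 100)"
            )
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {_METHODS}")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed record of a simulation run.

    ``states`` is an (n, 2) array of (x1, x2); ``control`` the applied input
    u per time point; ``estimates`` the (n, 3) running parameter estimate for
    adaptive runs; ``lyapunov`` the Lyapunov value per time point for
    controlled runs.
    """

    times: np.ndarray
    states: np.ndarray
    control: np.ndarray
    estimates: Optional[np.ndarray] = None
    lyapunov: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if n == 0:
            return
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        for name in ("states", "control", "estimates", "lyapunov"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != times length {n}")

    @property
    def x1(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x2(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def duration(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"t": self.times, "x1": self.x1, "x2": self.x2, "u": self.control}
        if self.estimates is not None:
            for i in range(3):
                cols[f"theta{i + 1}_hat"] = self.estimates[:, i]
        if self.lyapunov is not None:
            cols["V"] = self.lyapunov
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Trajectory":
        est_cols = [c for c in ("theta1_hat", "theta2_hat", "theta3_hat") if c in df]
        return cls(
            times=df["t"].to_numpy(),
            states=df[["x1", "x2"]].to_numpy(),
            control=df["u"].to_numpy(),
            estimates=df[est_cols].to_numpy() if len(est_cols) == 3 else None,
            lyapunov=df["V"].to_numpy() if "V" in df else None,
        )


def _integrate(f: Callable[[float, Sequence[float]], tuple], y0: Sequence[float],
               config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Integrate dy/dt = f(t, y) on the fixed output grid; returns (times, ys)."""
    n_steps = max(int(round(config.duration / config.step)), 1)
    h = config.duration / n_steps
    dim = len(y0)

    if config.method == "adaptive-stepper":
        from scipy.integrate import solve_ivp

        times = np.arange(0, n_steps + 1, config.record_every) * h
        sol = solve_ivp(
            lambda t, y: np.asarray(f(t, y)),
            (0.0, config.duration),
            np.asarray(y0, dtype=float),
            method="RK45",
            t_eval=times,
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise IntegrationError(float(sol.t[-1]) if len(sol.t) else 0.0, sol.message)
        ys = sol.y.T
        if np.any(np.abs(ys) > OVERFLOW_GUARD):
            i = int(np.argmax(np.any(np.abs(ys) > OVERFLOW_GUARD, axis=1)))
            raise IntegrationError(float(times[i]))
        return times, ys

    n_rec = n_steps // config.record_every + 1
    times = np.empty(n_rec)
    ys = np.empty((n_rec, dim))
    y = tuple(float(v) for v in y0)
    times[0] = 0.0
    ys[0] = y
    rec = 1
    half = h / 2.0
    sixth = h / 6.0
    for i in range(n_steps):
        t = i * h
        k1 = f(t, y)
        k2 = f(t + half, tuple(y[j] + half * k1[j] for j in range(dim)))
        k3 = f(t + half, tuple(y[j] + half * k2[j] for j in range(dim)))
        k4 = f(t + h, tuple(y[j] + h * k3[j] for j in range(dim)))
        y = tuple(
            y[j] + sixth * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]) for j in range(dim)
        )
        if any(abs(v) > OVERFLOW_GUARD for v in y):
            raise IntegrationError((i + 1) * h)
        if (i + 1) % config.record_every == 0:
            times[rec] = (i + 1) * h
            ys[rec] = y
            rec += 1
    return times[:rec], ys[:rec]


def simulate_untreated(model: MoodModel, config: SimulationConfig) -> Trajectory:
    """Integrate the unforced oscillator (u = 0): the untreated mood swing."""

    def f(t: float, y: Sequence[float]) -> tuple:
        d = vector_field(model, MoodState(y[0], y[1]), 0.0)
        return (d.x1, d.x2)

    times, ys = _integrate(f, config.initial_state.as_tuple(), config)
    return Trajectory(times=times, states=ys, control=np.zeros(len(times)))


def simulate_emk(model: MoodModel, gains: ControlGains, config: SimulationConfig,
                 as_printed: bool = False) -> Trajectory:
    """Closed-loop run under the exact-model-knowledge backstepping law.

    Records the applied input u and the Lyapunov value
    V = x1**2/2 + h**2/2 at every output time.
    """

    def f(t: float, y: Sequence[float]) -> tuple:
        s = MoodState(y[0], y[1])
        u = emk_control(model, s, gains, as_printed=as_printed)
        d = vector_field(model, s, u)
        return (d.x1, d.x2)

    times, ys = _integrate(f, config.initial_state.as_tuple(), config)
    u = np.array([
        emk_control(model, MoodState(x1, x2), gains, as_printed=as_printed)
        for x1, x2 in ys
    ])
    h = ys[:, 1] + gains.k1 * ys[:, 0]
    v = 0.5 * ys[:, 0] ** 2 + 0.5 * h ** 2
    return Trajectory(times=times, states=ys, control=u, lyapunov=v)


def simulate_adaptive(model: MoodModel, gains: ControlGains, gamma: AdaptationGain,
                      config: SimulationConfig, as_printed: bool = False) -> Trajectory:
    """Closed-loop run under the adaptive backstepping law.

    Integrates the augmented 5-state system (x1, x2, theta_hat): the plant
    evolves with the true parameters, the controller sees only theta_hat,
    and theta_hat follows the gradient update rule.  Records u, theta_hat,
    and the adaptive Lyapunov value
    V = x1**2/2 + h**2/2 + theta_tilde' Gamma^-1 theta_tilde / 2 per time
    point (theta_tilde uses the true parameters, known to the simulator).
    """
    if config.initial_estimate is None:
        raise ValueError("adaptive simulation requires config.initial_estimate")
    theta_hat0 = tuple(float(v) for v in config.initial_estimate)
    if len(theta_hat0) != 3:
        raise ValueError("initial_estimate must have 3 components (c, b*a, b)")

    g = gamma.matrix
    k1 = gains.k1

    def f(t: float, y: Sequence[float]) -> tuple:
        s = MoodState(y[0], y[1])
        theta_hat = (y[2], y[3], y[4])
        u = adaptive_control(theta_hat, s, gains, as_printed=as_printed)
        d = vector_field(model, s, u)
        hh = s.x2 + k1 * s.x1
        w = (-s.x1, s.x2, -s.x1 * s.x1 * s.x2)
        dth = (
            hh * (g[0, 0] * w[0] + g[0, 1] * w[1] + g[0, 2] * w[2]),
            hh * (g[1, 0] * w[0] + g[1, 1] * w[1] + g[1, 2] * w[2]),
            hh * (g[2, 0] * w[0] + g[2, 1] * w[1] + g[2, 2] * w[2]),
        )
        return (d.x1, d.x2, dth[0], dth[1], dth[2])

    y0 = config.initial_state.as_tuple() + theta_hat0
    times, ys = _integrate(f, y0, config)
    states = ys[:, :2]
    estimates = ys[:, 2:]
    u = np.array([
        adaptive_control(th, MoodState(x1, x2), gains, as_printed=as_printed)
        for (x1, x2), th in zip(states, estimates)
    ])
    h = states[:, 1] + k1 * states[:, 0]
    theta = np.asarray(pack_parameters(model))
    tilde = theta[None, :] - estimates
    g_inv = gamma.inverse
    v = 0.5 * states[:, 0] ** 2 + 0.5 * h ** 2 + 0.5 * np.einsum(
        "ni,ij,nj->n", tilde, g_inv, tilde
    )
    return Trajectory(times=times, states=states, control=u, estimates=estimates, lyapunov=v)
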