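"""Lyapunov-based verification and trajectory summary metrics.

The stability proofs behind both controllers are energy arguments: the EMK
closed loop drains V = x1**2/2 + h**2/2 at rate dV/dt = -k1*x1**2 - k2*h**2,
hence V(t) <= V(0)*exp(-beta*t) with beta = 2*min(k1, k2); the adaptive loop
drains the augmented V that adds theta_tilde' Gamma^-1 theta_tilde / 2, at
the same rate — the estimation error contributes no drain, which is why
theta_hat is only guaranteed to settle, not to identify the true parameters.
This module turns those arguments, and the figure-level claims (sustained
oscillation when untreated, zero mood reversals under treatment, estimates
settling to constants), into computable checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .controllers import AdaptationGain, ControlGains, backstepping_error
from .model import MoodState
from .simulate import Trajectory

__all__ = [
    "ConvergenceReport",
    "lyapunov_emk",
    "lyapunov_adaptive",
    "exponential_envelope_check",
    "oscillation_metrics",
    "estimate_convergence",
    "summarize",
]


@dataclass(frozen=True)
class ConvergenceReport:
    """Summary metrics of a simulated run; fields are None when not computed.

    settling_time is the first time after which |x1| stays within the
    settle tolerance for the rest of the run.  estimate_drift is the largest
    per-component total variation of theta_hat over the final window.
    Zero crossings count strict sign changes of x1 (touching zero without
    crossing does not count as a mood reversal).
    """

    settled: Optional[bool] = None
    settling_time: Optional[float] = None
    final_estimate: Optional[tuple[float, float, float]] = None
    final_error: Optional[tuple[float, float, float]] = None
    estimate_drift: Optional[float] = None
    zero_crossings: Optional[int] = None
    peak_amplitude: Optional[float] = None


def lyapunov_emk(state: MoodState, k1: float) -> float:
    """EMK Lyapunov value V = x1**2/2 + h**2/2; zero only at the origin."""
    h = backstepping_error(state, k1)
    return 0.5 * state.x1 ** 2 + 0.5 * h ** 2


def lyapunov_adaptive(state: MoodState, theta_tilde: Sequence[float],
                      gamma: AdaptationGain, k1: float) -> float:
    """Adaptive Lyapunov value: EMK value plus theta_tilde' Gamma^-1 theta_tilde / 2."""
    tilde = np.asarray(theta_tilde, dtype=float)
    if tilde.shape != (3,):
        raise ValueError("theta_tilde must have 3 components")
    return lyapunov_emk(state, k1) + 0.5 * float(tilde @ gamma.inverse @ tilde)


def exponential_envelope_check(trajectory: Trajectory, gains: ControlGains,
                               slack: float = 1e-6) -> tuple[bool, float]:
    """Check V(t) <= V(0) * exp(-beta*t) * (1 + slack) with beta = 2*min(k1, k2).

    beta is the sharp rate implied by dV/dt = -k1*x1**2 - k2*h**2
    <= -2*min(k1, k2)*V.  Returns (passed, worst_ratio) where worst_ratio is
    the largest observed V(t) / (V(0)*exp(-beta*t)); 0 for an identically
    zero run.
    """
    if trajectory.lyapunov is None:
        raise ValueError("trajectory carries no Lyapunov series")
    v = np.asarray(trajectory.lyapunov, dtype=float)
    if len(v) == 0:
        raise ValueError("empty trajectory")
    beta = 2.0 * min(gains.k1, gains.k2)
    v0 = v[0]
    if v0 == 0.0:
        worst = 0.0 if np.all(v == 0.0) else math.inf
        return worst <= 1.0 + slack, worst
    envelope = v0 * np.exp(-beta * trajectory.times)
    worst = float(np.max(v / envelope))
    return worst <= 1.0 + slack, worst


def _final_window_slice(trajectory: Trajectory, window: float) -> slice:
    if len(trajectory.times) == 0:
        raise ValueError("empty trajectory")
    if window >= trajectory.duration:
        raise ValueError(
            f"window {window} must be shorter than the run duration {trajectory.duration}"
        )
    start = int(np.searchsorted(trajectory.times, trajectory.duration - window))
    return slice(start, None)


def count_zero_crossings(x: np.ndarray) -> int:
    """Strict sign changes between consecutive samples; zeros never cross."""
    s = np.sign(x)
    return int(np.sum(s[:-1] * s[1:] < 0))


def oscillation_metrics(trajectory: Trajectory, window: float) -> ConvergenceReport:
    """Peak |x1| over the final window and mood reversals over the whole run.

    For an untreated run the peak amplitude estimates the limit-cycle
    amplitude; for a treated run zero crossings quantify whether any mood
    reversal occurred during treatment.
    """
    sl = _final_window_slice(trajectory, window)
    return ConvergenceReport(
        peak_amplitude=float(np.max(np.abs(trajectory.x1[sl]))),
        zero_crossings=count_zero_crossings(trajectory.x1),
    )


def estimate_convergence(trajectory: Trajectory, true_theta: Sequence[float],
                         window: float, drift_tol: float = 1e-4) -> ConvergenceReport:
    """Has theta_hat settled to a constant over the final window?

    Settling is defined by total variation: each component of theta_hat must
    vary by less than drift_tol over the window.  The final estimate and its
    error against the true parameters are reported, never asserted — the
    gradient update guarantees settling, not identification, absent
    persistent excitation.
    """
    if trajectory.estimates is None:
        raise ValueError("trajectory carries no estimate series")
    sl = _final_window_slice(trajectory, window)
    est = trajectory.estimates[sl]
    tv = np.sum(np.abs(np.diff(est, axis=0)), axis=0)
    final = tuple(float(v) for v in trajectory.estimates[-1])
    theta = np.asarray(true_theta, dtype=float)
    return ConvergenceReport(
        settled=bool(np.all(tv < drift_tol)),
        final_estimate=final,
        final_error=tuple(float(v) for v in theta - trajectory.estimates[-1]),
        estimate_drift=float(np.max(tv)),
    )


def settling_time(trajectory: Trajectory, tol: float = 1e-3) -> tuple[bool, Optional[float]]:
    """First time after which |x1| never again exceeds tol."""
    inside = np.abs(trajectory.x1) <= tol
    if not inside[-1]:
        return False, None
    # last index where |x1| > tol; settled one sample later
    outside = np.nonzero(~inside)[0]
    idx = 0 if len(outside) == 0 else int(outside[-1]) + 1
    return True, float(trajectory.times[idx])


def summarize(trajectory: Trajectory, window: Optional[float] = None,
              settle_tol: float = 1e-3,
              true_theta: Optional[Sequence[float]] = None,
              drift_tol: float = 1e-4) -> ConvergenceReport:
    """Combined report: settling, oscillation metrics, estimate convergence.

    The final window defaults to 25% of the run duration.
    """
    if window is None:
        window = 0.25 * trajectory.duration
    osc = oscillation_metrics(trajectory, window)
    settled, t_settle = settling_time(trajectory, settle_tol)
    est: ConvergenceReport | None = None
    if trajectory.estimates is not None and true_theta is not None:
        est = estimate_convergence(trajectory, true_theta, window, drift_tol)
    return ConvergenceReport(
        settled=settled,
        settling_time=t_settle,
        final_estimate=est.final_estimate if est else (
            tuple(float(v) for v in trajectory.estimates[-1])
            if trajectory.estimates is not None else None
        ),
        final_error=est.final_error if est else None,
        estimate_drift=est.estimate_drift if est else None,
        zero_crossings=osc.zero_crossings,
        peak_amplitude=osc.peak_amplitude,
    )
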