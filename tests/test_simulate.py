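"""Integration tests: fixed-step RK4 behaviour, oracles, and scenario runs."""

import math

import numpy as np
import pytest

from moodquench import (
    AdaptationGain,
    ControlGains,
    IntegrationError,
    MoodModel,
    MoodState,
    SimulationConfig,
    Trajectory,
    pack_parameters,
    simulate_adaptive,
    simulate_emk,
    simulate_untreated,
)
from .conftest import ADAPTIVE_GAINS, PUBLISHED_MODEL, PUBLISHED_X0, emk_closed_form


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(duration=-1)
    with pytest.raises(ValueError):
        SimulationConfig(duration=10, step=0.2)  # coarser than duration/100
    with pytest.raises(ValueError):
        SimulationConfig(method="euler")
    with pytest.raises(ValueError):
        SimulationConfig(record_every=0)


def test_trajectory_validation():
    with pytest.raises(ValueError):
        Trajectory(times=np.array([0.0, 0.5, 0.5]), states=np.zeros((3, 2)),
                   control=np.zeros(3))
    with pytest.raises(ValueError):
        Trajectory(times=np.array([0.0, 1.0]), states=np.zeros((3, 2)),
                   control=np.zeros(2))


@pytest.mark.parametrize("scenario", ["untreated", "emk", "adaptive"])
def test_zero_initial_state_stays_at_equilibrium(scenario):
    cfg = SimulationConfig(duration=2.0, step=1e-2, initial_state=MoodState(0, 0),
                           initial_estimate=(6, 2.5, 5))
    if scenario == "untreated":
        traj = simulate_untreated(PUBLISHED_MODEL, cfg)
    elif scenario == "emk":
        traj = simulate_emk(PUBLISHED_MODEL, ControlGains(1.1, 10), cfg)
    else:
        traj = simulate_adaptive(PUBLISHED_MODEL, ADAPTIVE_GAINS,
                                 AdaptationGain.scaled_identity(0.1), cfg)
        assert np.all(traj.estimates == traj.estimates[0])
    assert np.all(traj.states == 0.0)
    assert np.all(traj.control == 0.0)


def test_simulation_is_deterministic(untreated_traj, published_model):
    again = simulate_untreated(
        published_model, SimulationConfig(duration=40.0, initial_state=PUBLISHED_X0)
    )
    assert np.array_equal(untreated_traj.states, again.states)
    assert np.array_equal(untreated_traj.times, again.times)


def test_untreated_published_run_sustains_oscillation(untreated_traj):
    """Nonzero initial mood leads to a sustained fixed-amplitude swing."""
    final = untreated_traj.x1[untreated_traj.times >= 30.0]
    assert np.max(np.abs(final)) > 1.0  # far from settling
    signs = np.sign(final)
    assert np.sum(signs[:-1] * signs[1:] < 0) > 5  # still crossing zero


def test_untreated_never_trips_overflow_guard_from_moderate_states():
    for x0 in [MoodState(2.0, 0.0), MoodState(-2.0, 1.0)]:
        traj = simulate_untreated(
            PUBLISHED_MODEL, SimulationConfig(duration=40.0, step=2e-3, initial_state=x0)
        )
        assert np.all(np.isfinite(traj.states))


def test_overflow_guard_reports_blowup_time():
    """A stiff start far outside the limit cycle destabilizes fixed-step RK4;
    the guard aborts and names the time."""
    with pytest.raises(IntegrationError) as exc:
        simulate_untreated(
            PUBLISHED_MODEL,
            SimulationConfig(duration=10.0, step=1e-2, initial_state=MoodState(100.0, 0.0)),
        )
    assert exc.value.time > 0
    assert "t=" in str(exc.value)


def test_harmonic_limit_matches_cosine():
    """With b ~ 0 the untreated solution is 0.5*cos(3t) (omega = sqrt(9))."""
    model = MoodModel(a=1.0, b=1e-6, c=9.0)
    period = 2 * math.pi / 3.0
    traj = simulate_untreated(
        model, SimulationConfig(duration=period, step=1e-3,
                                initial_state=MoodState(0.5, 0.0))
    )
    exact = 0.5 * np.cos(3.0 * traj.times)
    assert np.max(np.abs(traj.x1 - exact)) < 1e-4


def test_rk4_convergence_order():
    """Halving the step shrinks the end-state error ~16x (observed order >= 3.5)."""
    x0 = MoodState(0.5, 0.0)
    ref = simulate_untreated(
        PUBLISHED_MODEL, SimulationConfig(duration=5.0, step=1e-4, initial_state=x0)
    ).states[-1]
    errs = []
    for step in (0.04, 0.02, 0.01):
        end = simulate_untreated(
            PUBLISHED_MODEL, SimulationConfig(duration=5.0, step=step, initial_state=x0)
        ).states[-1]
        errs.append(np.max(np.abs(end - ref)))
    orders = [math.log2(errs[i] / errs[i + 1]) for i in range(2)]
    assert min(orders) >= 3.5


def test_emk_matches_matrix_exponential_oracle(emk_traj, emk_gains):
    """Exact drift cancellation makes the closed loop linear; RK4 at the
    default step reproduces the matrix-exponential solution to <= 1e-6."""
    idx = np.arange(0, len(emk_traj.times), 50)
    exact = emk_closed_form(emk_gains, PUBLISHED_X0, emk_traj.times[idx])
    assert np.max(np.abs(emk_traj.states[idx] - exact)) <= 1e-6


def test_emk_mood_never_reverses_sign(emk_traj):
    signs = np.sign(emk_traj.x1)
    assert np.sum(signs[:-1] * signs[1:] < 0) == 0


def test_adaptive_requires_initial_estimate():
    with pytest.raises(ValueError):
        simulate_adaptive(PUBLISHED_MODEL, ADAPTIVE_GAINS,
                          AdaptationGain.scaled_identity(0.1),
                          SimulationConfig(duration=2.0, step=1e-2))


def test_adaptive_with_negligible_gain_reduces_to_emk(published_model, emk_gains):
    """Seeded at the true parameters with a negligible adaptation gain, the
    adaptive loop is the EMK loop (max trajectory difference < 1e-10)."""
    cfg = SimulationConfig(duration=10.0, initial_state=PUBLISHED_X0)
    emk = simulate_emk(published_model, emk_gains, cfg)
    adp = simulate_adaptive(
        published_model, emk_gains, AdaptationGain.scaled_identity(1e-12),
        SimulationConfig(duration=10.0, initial_state=PUBLISHED_X0,
                         initial_estimate=pack_parameters(published_model)),
    )
    assert np.max(np.abs(emk.states - adp.states)) < 1e-10


def test_adaptive_published_run_quenches_and_settles(adaptive_traj):
    assert abs(adaptive_traj.x1[-1]) < 1e-3
    # each estimate component settles: negligible motion over the final quarter
    tail = adaptive_traj.estimates[adaptive_traj.times >= 7.5]
    assert np.max(np.sum(np.abs(np.diff(tail, axis=0)), axis=0)) < 1e-4


def test_record_every_thins_output(published_model):
    cfg = SimulationConfig(duration=2.0, step=1e-2, record_every=10,
                           initial_state=PUBLISHED_X0)
    traj = simulate_untreated(published_model, cfg)
    assert len(traj.times) == 21
    assert traj.times[1] == pytest.approx(0.1)


def test_adaptive_stepper_agrees_with_rk4(published_model, emk_gains):
    cfg_rk = SimulationConfig(duration=5.0, step=1e-3, initial_state=PUBLISHED_X0)
    cfg_ad = SimulationConfig(duration=5.0, step=1e-3, method="adaptive-stepper",
                              initial_state=PUBLISHED_X0)
    rk = simulate_emk(published_model, emk_gains, cfg_rk)
    ad = simulate_emk(published_model, emk_gains, cfg_ad)
    assert np.max(np.abs(rk.states - ad.states)) < 1e-7
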