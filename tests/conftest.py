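"""Shared fixtures: the published scenario settings and their simulated runs.

The expensive closed-loop runs are session-scoped so the whole suite pays
for each integration once.
"""

import numpy as np
import pytest

from moodquench import (
    AdaptationGain,
    ControlGains,
    MoodModel,
    MoodState,
    SimulationConfig,
    simulate_adaptive,
    simulate_emk,
    simulate_untreated,
)

#: published patient parameters and initial condition
PUBLISHED_MODEL = MoodModel(a=1.0, b=2.0, c=9.0)
PUBLISHED_X0 = MoodState(0.5, 0.0)
EMK_GAINS = ControlGains(1.1, 10.0)
ADAPTIVE_GAINS = ControlGains(1.22, 10.0)
THETA_HAT0 = (6.0, 2.5, 5.0)


@pytest.fixture(scope="session")
def published_model():
    return PUBLISHED_MODEL


@pytest.fixture(scope="session")
def emk_gains():
    return EMK_GAINS


@pytest.fixture(scope="session")
def adaptive_gains():
    return ADAPTIVE_GAINS


@pytest.fixture(scope="session")
def gamma01():
    return AdaptationGain.scaled_identity(0.1)


@pytest.fixture(scope="session")
def untreated_traj(published_model):
    """Untreated limit-cycle run: horizon 40, step 1e-3."""
    return simulate_untreated(
        published_model, SimulationConfig(duration=40.0, initial_state=PUBLISHED_X0)
    )


@pytest.fixture(scope="session")
def untreated_traj_fine(published_model):
    """Step/10 reference for the untreated run (amplitude oracle)."""
    return simulate_untreated(
        published_model, SimulationConfig(duration=40.0, step=1e-4, initial_state=PUBLISHED_X0)
    )


@pytest.fixture(scope="session")
def emk_traj(published_model, emk_gains):
    """Exact-model-knowledge run with the published gains, horizon 10."""
    return simulate_emk(
        published_model, emk_gains, SimulationConfig(duration=10.0, initial_state=PUBLISHED_X0)
    )


@pytest.fixture(scope="session")
def adaptive_traj(published_model, adaptive_gains, gamma01):
    """Adaptive run with the published gains and estimate initialization."""
    return simulate_adaptive(
        published_model, adaptive_gains, gamma01,
        SimulationConfig(duration=10.0, initial_state=PUBLISHED_X0,
                         initial_estimate=THETA_HAT0),
    )


def emk_closed_form(gains, x0, times):
    """Eigendecomposition (matrix-exponential) oracle for the EMK closed loop.

    With the drift cancelled, (x1, h) obey the linear system
    d/dt (x1, h) = [[-k1, 1], [-1, -k2]] (x1, h); mapping back through
    x2 = h - k1*x1 gives the exact state trajectory.
    """
    k1, k2 = gains.k1, gains.k2
    a_mat = np.array([[-k1, 1.0], [-1.0, -k2]])
    lam, p = np.linalg.eig(a_mat.astype(complex))
    z0 = np.array([x0.x1, x0.x2 + k1 * x0.x1], dtype=complex)
    coef = np.linalg.solve(p, z0)
    z = (p @ (np.exp(np.outer(lam, np.asarray(times))) * coef[:, None])).T.real
    x1 = z[:, 0]
    x2 = z[:, 1] - k1 * z[:, 0]
    return np.column_stack([x1, x2])
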