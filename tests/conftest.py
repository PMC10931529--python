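import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from grayode import pk, simulate_forward, subsample, ultradian


@pytest.fixture(scope="session")
def pk_model():
    return pk()


@pytest.fixture(scope="session")
def endocrine_model():
    return ultradian()


@pytest.fixture(scope="session")
def pk_dense(pk_model):
    """Tight-tolerance reference trajectory of the PK model on [0, 50] h."""
    return simulate_forward(pk_model, t_grid=np.linspace(0, 50, 2001))


@pytest.fixture(scope="session")
def endocrine_dense(endocrine_model):
    """Reference trajectory of the glucose-insulin model on [0, 1800] min."""
    return simulate_forward(endocrine_model, t_grid=np.linspace(0, 1800, 3601))


@pytest.fixture(scope="session")
def pk_obs_100(pk_model):
    traj = simulate_forward(pk_model, t_grid=np.linspace(0, 50, 100))
    return subsample(traj, 100)


def pk_closed_form(t):
    """Exact PK solution: G decays, B rises and falls, U accumulates."""
    t = np.asarray(t, dtype=float)
    kg, kb, dose = 0.72, 0.15, 0.1
    G = dose * np.exp(-kg * t)
    B = kg * dose / (kg - kb) * (np.exp(-kb * t) - np.exp(-kg * t))
    U = dose - G - B
    return B, G, U
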