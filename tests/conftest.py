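import numpy as np
import pytest

from reflectedflow import load_preset, steady_state_1d, steady_state_2d


@pytest.fixture(scope="session")
def basic_pset():
    return load_preset("basic")


@pytest.fixture(scope="session")
def robust_pset():
    return load_preset("robust")


@pytest.fixture(scope="session")
def basic_auxin(basic_pset):
    return basic_pset.auxin


@pytest.fixture(scope="session")
def basic_steady50(basic_auxin):
    """Stationary basic-set profile at alpha=1, N=50 (Cauchy problem)."""
    res = steady_state_1d(basic_auxin, N=50)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def steady2d_basic(basic_auxin):
    """Stationary basic-set 2D layout at M=8, N=50."""
    return steady_state_2d(basic_auxin, M=8, N=50)


@pytest.fixture(scope="session")
def grown_root(basic_pset):
    """One long basic-set growing-root simulation shared across tests."""
    from reflectedflow.params import FluxSchedule
    from reflectedflow.extended1d import run_extended

    return run_extended(
        basic_pset,
        5000.0,
        seed=11,
        schedule=FluxSchedule(0.06, 1.5e-4),
        dt_max=0.05,
        record_every=100.0,
        snapshot_every=250.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
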