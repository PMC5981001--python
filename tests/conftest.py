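import numpy as np
import pytest

from optiongen import GeneratorConfig, TaskGeometry, simulate_cohort
from optiongen.model import RawTrajectory


@pytest.fixture(scope="session")
def geometry() -> TaskGeometry:
    return TaskGeometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


def make_trajectory(path_id="p1", n=50, seed=0, start=(0.0, 0.0), end=(0.0, 204.0)):
    """Random smooth-ish polyline from start to end with valid timestamps."""
    rng = np.random.default_rng(seed)
    frac = np.linspace(0.0, 1.0, n)
    base = np.outer(1 - frac, start) + np.outer(frac, end)
    wiggle = np.cumsum(rng.normal(0, 1.5, size=(n, 2)), axis=0)
    wiggle -= np.outer(frac, wiggle[-1])  # pin endpoints
    xy = base + wiggle
    t = np.cumsum(rng.uniform(0.01, 0.05, n))
    t -= t[0]
    return RawTrajectory(path_id=path_id, samples=np.column_stack([t, xy]), onset=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-agent single-session cohort reused by read-only tests."""
    return simulate_cohort(GeneratorConfig(n_agents=6, master_seed=1), "single_session")
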