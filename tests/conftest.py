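import numpy as np
import pytest

from slitmosaic import simulate
from slitmosaic.segment import BoostingConfig


@pytest.fixture(scope="session")
def default_spec():
    return simulate.SceneSpec()


@pytest.fixture(scope="session")
def clean_spec():
    """Artifact-free scene (no glare, no noise) for exactness checks."""
    return simulate.SceneSpec(noise_sigma=0.0, glare_count=0)


@pytest.fixture(scope="session")
def short_loop(default_spec):
    """Eight-frame loop with default artifacts; shared across tests."""
    traj = simulate.preset_trajectory("loop", 8, default_spec)
    return simulate.render_sequence(default_spec, traj)


@pytest.fixture(scope="session")
def short_sweep(default_spec):
    traj = simulate.preset_trajectory("sweep", 6, default_spec, step=8.0)
    return simulate.render_sequence(default_spec, traj)


@pytest.fixture(scope="session")
def fast_boost():
    """Reduced boosting budget for unit tests; the full 200-round default
    is exercised by the acceptance suite."""
    return BoostingConfig(rounds=60, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
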