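import numpy as np
import pytest
from hypothesis import settings

from secothal import SessionConfig, generate_session

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")
from secothal.synthetic_data import _spikes_from_grid


@pytest.fixture(scope="session")
def mid_session():
    """One 2000-s, 12-cell tactile-conditioning session with ground truth.

    Seed chosen once for the fixture; the cell draw includes pure-coupling,
    pure-kernel, and kernel+coupling archetypes used across test modules.
    """
    return generate_session(SessionConfig(duration=2000.0, n_cells=12), seed=7)


@pytest.fixture(scope="session")
def small_session():
    """A short session for I/O and pipeline smoke tests."""
    return generate_session(SessionConfig(duration=400.0, n_cells=4), seed=42)


def spikes_from_rate(rate_grid, dt, seed):
    """Poisson spikes from a piecewise-constant rate (test helper)."""
    return _spikes_from_grid(np.asarray(rate_grid, dtype=float), dt, np.random.default_rng(seed))
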