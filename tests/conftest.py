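import numpy as np
import pytest

from ivmotion.synthetic import default_presets, simulate_cohort
from ivmotion.tracks import Track


@pytest.fixture(scope="session")
def cohort200():
    """The standard study-scale cohort: 5 archetypes x 40 tracks, seed 1."""
    return simulate_cohort(default_presets(), 40, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for pipeline-level tests: 5 archetypes x 10 tracks."""
    return simulate_cohort(default_presets(n_steps=16), 10, seed=7)


def random_track(rng, n_points=10, dt=60.0, scale=10.0, track_id="t",
                 condition=""):
    """A seeded random-walk track for oracle comparisons."""
    pos = np.cumsum(rng.normal(0, scale, size=(n_points, 3)), axis=0)
    return Track(track_id, pos, np.arange(n_points) * dt, condition)
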