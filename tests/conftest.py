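import numpy as np
import pytest

import geomob
from geomob import pipeline
from geomob.ingest import filter_single_day_users, split_trajectories


@pytest.fixture(scope="session")
def world10():
    """A 10-anchor UK-like world shared across tests."""
    return geomob.make_world(10, seed=11)


@pytest.fixture(scope="session")
def population50(world10):
    """50 simulated users over the shared world (events, ground truth)."""
    return geomob.simulate_population(world10, 50, seed=11)


@pytest.fixture(scope="session")
def fitted50(population50):
    """Fitted per-user models for the 50-user population."""
    events, _ = population50
    trajectories = split_trajectories(filter_single_day_users(events))
    results, models = pipeline.fit_population(trajectories)
    return results, models


@pytest.fixture(scope="session")
def grid50(fitted50):
    _, models = fitted50
    return geomob.aggregate_location_grid(models)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
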