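import itertools

import pytest

from fillet import fixtures
from fillet.model import CurationState


def fixed_clock():
    """Deterministic injectable clock: monotone fake timestamps."""
    counter = itertools.count(1)
    return lambda: f"2000-01-01T00:00:{next(counter) % 60:02d}"


@pytest.fixture
def clock():
    return fixed_clock()


@pytest.fixture
def empty_state(clock):
    return CurationState(clock=clock)


@pytest.fixture(scope="session")
def scenario():
    """The canned diploid curation scenario (seed 1), shared read-only."""
    return fixtures.make_curation_scenario(seed=1)


@pytest.fixture
def fresh_scenario():
    """A private copy of the scenario for tests that mutate state."""
    return fixtures.make_curation_scenario(seed=1, clock=fixed_clock())
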