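import numpy as np
import pytest

from dfcstates import (
    ComponentTimecourseSet, default_assignment, default_state_process,
)


@pytest.fixture(scope="session")
def assignment47():
    return default_assignment(47)


@pytest.fixture(scope="session")
def state_process(assignment47):
    return default_state_process(assignment47)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def noise_ts(rng):
    """Small white-noise time-course set (8 components, 120 TR)."""
    ids = tuple(f"IC{i+1:02d}" for i in range(8))
    return ComponentTimecourseSet(
        values=rng.standard_normal((8, 120)), tr=2.25,
        component_ids=ids, participant_id="P0001",
    )

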