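import numpy as np
import pytest

from operant.design import NEGATIVE, POSITIVE, BlockSpec
from operant.simulate import BlockData, simulate_cohort


def make_block(
    responded,
    outcomes=None,
    phase="training",
    cue="standard",
    rating=0,
    memory=True,
    session=1,
    position=0,
):
    """Hand-build a BlockData from explicit bin vectors."""
    responded = np.asarray(responded, dtype=bool)
    if outcomes is None:
        outcomes = np.zeros_like(responded)
    spec = BlockSpec(
        session=session,
        position=position,
        cue=cue,
        phase=phase,
        contingency=POSITIVE if phase == "training" else NEGATIVE,
        duration_bins=responded.size,
    )
    return BlockData(
        spec=spec,
        responded=responded,
        outcomes=np.asarray(outcomes, dtype=bool),
        causality_rating=rating,
        memory_correct=memory,
    )


def make_count_block(n_responses, duration=120, **kwargs):
    """BlockData with a given response count (responses first, no outcomes)."""
    resp = np.zeros(duration, dtype=bool)
    resp[:n_responses] = True
    return make_block(resp, **kwargs)


@pytest.fixture(scope="session")
def block_factory():
    return make_block


@pytest.fixture(scope="session")
def count_block_factory():
    return make_count_block


@pytest.fixture(scope="session")
def goal_cohort():
    """Small goal-directed exp1 cohort shared across tests."""
    return simulate_cohort("exp1", 20, "goal_directed", seed=11)
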