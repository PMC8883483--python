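"""Shared fixtures: the trained-network pool used by the attainment and
analysis criteria.

Training ten 128-unit networks dominates the suite's runtime, so it happens
once per session here; the analysis tests reuse the first converged networks
as their ensemble.
"""

import numpy as np
import pytest

from wmrnn import trainer
from wmrnn.trainer import TrainConfig

POOL_SEEDS = list(range(10))


@pytest.fixture(scope="session")
def trained_pool():
    """Train one 128-unit ODR network (fixed 1.5 s delay, batch 64,
    eta 0.001, <= 3000 Adam updates) per seed, stopping at 95% correct."""
    results = {}
    for seed in POOL_SEEDS:
        results[seed] = trainer.train(TrainConfig(n_rec=128, seed=seed))
    return results


@pytest.fixture(scope="session")
def trained_ensemble(trained_pool):
    """The first three fully trained networks of the pool."""
    done = [r for r in trained_pool.values() if r.converged]
    if len(done) < 3:
        pytest.fail("fewer than three networks reached the fully trained stage")
    return done[:3]
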