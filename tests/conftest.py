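import numpy as np
import pytest

from motionmlp.psychometric import TrialRecord, build_hypothesis_grid


@pytest.fixture(scope="session")
def grid150():
    """The default 150-hypothesis grid spanning presentable levels 0-100%."""
    return build_hypothesis_grid()


def random_history(rng: np.random.Generator, n_trials: int):
    """A random (level, correctness) history for likelihood oracles."""
    return [
        TrialRecord(level=float(rng.uniform(0, 100)), correct=bool(rng.random() < 0.6))
        for _ in range(n_trials)
    ]
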