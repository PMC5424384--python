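import numpy as np
import pytest

from codasub.composition import DEFAULT_PARTS, SequentialBinaryPartition
from codasub.simulate import default_config, generate_records

PARTS = DEFAULT_PARTS


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def records(cfg):
    """One synthetic cohort (n=169) under the study-condition defaults."""
    return generate_records(cfg)


@pytest.fixture(scope="session")
def bases():
    """Two distinct ilr bases over the same parts, for invariance checks."""
    custom = SequentialBinaryPartition(
        # balance 1: {sleep, st} vs {lpa, mvpa}; then within each pair
        np.array([[1, 1, 0],
                  [1, -1, 0],
                  [-1, 0, 1],
                  [-1, 0, -1]]), PARTS)
    return (SequentialBinaryPartition.pivot(PARTS),
            SequentialBinaryPartition.pivot_reversed(PARTS),
            custom)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
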