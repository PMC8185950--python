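import numpy as np
import pytest

from rhythmhic.genome import GenomeDef, RestrictionMap
from rhythmhic.simulate import SimConfig, simulate_truth


@pytest.fixture(scope="session")
def genome():
    return GenomeDef.from_pairs([("chr1", 20_000_000), ("chr2", 20_000_000)])


@pytest.fixture(scope="session")
def fragmap(genome):
    return RestrictionMap.tile(genome, 4000)


@pytest.fixture(scope="session")
def default_truth():
    """One shared planted-truth draw for the read-only tests."""
    return simulate_truth(SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
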