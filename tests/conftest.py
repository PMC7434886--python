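import numpy as np
import pytest

from nucpioneer.io_tracks import Genome
from nucpioneer.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_genome(rng):
    """A 20 kb iid-uniform single-chromosome genome."""
    g = Genome()
    g.add("c1", "".join(rng.choice(list("ACGT"), size=20_000)))
    return g


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted dataset shared across tests (read-only)."""
    config = SimConfig(
        seed=11,
        genome_length=60_000,
        n_peaks={"G1": 20, "G2": 20, "G3": 20},
        fragments_per_locus=100,
    )
    return simulate_dataset(config)
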