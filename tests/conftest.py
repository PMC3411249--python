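import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from satdisperse import make_consensus_pair
from satdisperse.synthetic import GeneratorConfig, plant_genome


@pytest.fixture(scope="session")
def consensus_pair():
    return make_consensus_pair(20240401)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One small planted genome shared by the slower integration tests."""
    cfg = GeneratorConfig(n_chromosomes=1, chromosome_length=250_000,
                          n_satellite=4, n_transposon=4,
                          genes_per_chromosome=8)
    return plant_genome(cfg, 7, tmp_path_factory.mktemp("sim"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
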