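import numpy as np
import pytest

from compoundg4 import Genome, SyntheticConfig, simulate


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


@pytest.fixture(scope="session")
def default_dataset():
    """The seed-42 synthetic cohort: 50 compound, 100 single, 100 background."""
    return simulate(SyntheticConfig())


@pytest.fixture()
def tiny_genome():
    return Genome({"chr1": "ACGTACGTACGTACGT", "chr2": "GGGGCCCCAAAATTTT"})
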