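import numpy as np
import pytest

from numtforge.numt_detect import detect_numts
from numtforge.synthetic_data import SimulationConfig, simulate_dataset


def make_small_config(seed: int = 11, **kw) -> SimulationConfig:
    """Desk-scale study conditions reused across tests: two 250 kb
    scaffolds, 12 planted NUMTs, 4 chimeric transcripts."""
    defaults = dict(
        seed=seed,
        n_scaffolds=2,
        scaffold_length=250_000,
        n_numts=12,
        n_background_transcripts=6,
        n_chimeric_transcripts=4,
        n_decoy_transcripts=6,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(make_small_config())


@pytest.fixture(scope="session")
def small_detection(small_dataset):
    return detect_numts(small_dataset.mito, small_dataset.genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n: int, at: float = 0.5) -> str:
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])
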