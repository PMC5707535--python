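import numpy as np
import pytest

from cocktailscope import seq_synth as ss


@pytest.fixture(scope="session")
def small_db():
    """Four phage genomes, 15-25 kb, with distinct order-3 models."""
    db, _ = ss.generate_phage_db(4, (15_000, 25_000), n_hosts=4, seed=7)
    return db


@pytest.fixture(scope="session")
def six_genome_db():
    db, _ = ss.generate_phage_db(6, (20_000, 40_000), seed=11)
    return db


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))
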