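import numpy as np
import pytest

import rpodprofiler as rp


@pytest.fixture(scope="session")
def rpod_pair():
    """The rpoD primer pair used throughout: PsEG30F / PsEG790R."""
    return rp.known_primer("PsEG30F"), rp.known_primer("PsEG790R")


@pytest.fixture(scope="session")
def small_db():
    """Well-separated 8-species reference database (736 nt, >=3%
    divergence)."""
    cfg = rp.SimulationConfig(seed=11, n_species=8)
    db, _ = rp.simulate_reference_db(cfg)
    return db


@pytest.fixture(scope="session")
def small_index(small_db):
    return rp.DatabaseIndex(small_db)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
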