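import numpy as np
import pytest

from hsqtl.lmm import EigenK, kinship_from_dosages
from hsqtl.simulate import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_pop():
    """245 animals, 2 chromosomes, moderately dense map (fast to impute)."""
    cfg = SimConfig(
        n_animals=245,
        chromosomes=[("1", 60.0, 80), ("2", 60.0, 80)],
        n_generations=25,
        genotyping_error=0.002,
        seed=5,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def small_pop_kinship(small_pop):
    return kinship_from_dosages(small_pop.dose, ids=small_pop.animals)


@pytest.fixture(scope="session")
def small_pop_eigen(small_pop_kinship):
    return EigenK.from_kinship(small_pop_kinship)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
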