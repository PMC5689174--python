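import numpy as np
import pytest

from retroburst.classify import load_default_library
from retroburst.detect import DetectorParams, detect_elements
from retroburst.simulate import (
    SimulationConfig,
    insert_elements,
    make_family_template,
    simulate_background,
)


@pytest.fixture(scope="session")
def domain_library():
    return load_default_library()


@pytest.fixture(scope="session")
def gypsy_template(domain_library):
    return make_family_template(
        "GYPSY_T", "Gypsy", seed=11, ltr_len=350, chromoviridae=True,
        library=domain_library,
    )


@pytest.fixture(scope="session")
def copia_template(domain_library):
    return make_family_template(
        "COPIA_T", "Copia", seed=22, ltr_len=300, peptide_divergence=0.2,
        library=domain_library,
    )


@pytest.fixture(scope="session")
def small_simulation(gypsy_template, copia_template):
    """200 kb genome with 3 aged copies of each of two families."""
    genome = simulate_background(200_000, 0.5, seed=1)
    config = SimulationConfig(n_insertions=3, ages=[0.0, 5e6, 10e6], seed=3)
    genome, truths = insert_elements(genome, [gypsy_template, copia_template], config)
    return genome, truths


@pytest.fixture(scope="session")
def detected_candidates(small_simulation):
    genome, _ = small_simulation
    return detect_elements(genome.records, DetectorParams())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
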