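import numpy as np
import pytest

from mabckit.backcross_sim import DONOR, RECIPIENT, GeneticMap, PlantGenome, cross
from mabckit.datasets import background_panel, default_panel, table1_panel, toy_matrix


@pytest.fixture(scope="session")
def saltol_panel():
    return table1_panel()


@pytest.fixture(scope="session")
def bg_panel():
    return background_panel()


@pytest.fixture(scope="session")
def full_panel():
    return default_panel()


@pytest.fixture(scope="session")
def toy():
    return toy_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20121227)


@pytest.fixture(scope="session")
def genetic_map(full_panel):
    return GeneticMap(full_panel.chromosome_lengths_bp, 4.0)


@pytest.fixture(scope="session")
def founders(full_panel):
    lengths = full_panel.chromosome_lengths_bp
    return (
        PlantGenome.founder("recipient", RECIPIENT, lengths),
        PlantGenome.founder("donor", DONOR, lengths),
    )


@pytest.fixture
def f1(founders, genetic_map, rng):
    recipient, donor = founders
    return cross(donor, recipient, 1, genetic_map, rng, id_prefix="F1_")[0]
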