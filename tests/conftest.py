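import numpy as np
import pytest

from retroclock.simulate import EvolutionParams, make_provirus_template

TRNA = "GGCTCGTTGGTCTAGGGGTATGATTCTCGCTTAGGGTGCGAGAGGTCCCGGGTTCAAATCCCGGACGAGCCCACCA"

GENE_LENGTHS = {"gag": 900, "pro": 450, "pol": 1200, "env": 600}


@pytest.fixture(scope="session")
def trna() -> str:
    return TRNA


@pytest.fixture(scope="session")
def template():
    """A small (2.2 kb internal) template shared by cheap unit tests."""
    return make_provirus_template("famX", 120, GENE_LENGTHS, TRNA, seed=101)


@pytest.fixture()
def params() -> EvolutionParams:
    return EvolutionParams(seed=2024)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(77)
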