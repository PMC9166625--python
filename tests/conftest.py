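"""Shared fixtures: one mini-genome + locus design reused across tests."""

import numpy as np
import pytest

from spacernick.design import build_expected_amplicons
from spacernick.seqs import SYNTHETIC_ITR
from spacernick.simulate import build_mini_genome


@pytest.fixture(scope="session")
def genome_design():
    return build_mini_genome(seed=11)


@pytest.fixture(scope="session")
def genome(genome_design):
    return genome_design[0]


@pytest.fixture(scope="session")
def design(genome_design):
    return genome_design[1]


@pytest.fixture(scope="session")
def amplicons(genome_design):
    g, d = genome_design
    return build_expected_amplicons(d, g)


@pytest.fixture(scope="session")
def amplicons_itr(genome_design):
    g, d = genome_design
    return build_expected_amplicons(d, g, itr=SYNTHETIC_ITR)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
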