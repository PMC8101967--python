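import numpy as np
import pytest

from merlintools import simgenome
from merlintools.orf_domain import BlockProfile
from merlintools.simgenome import FamilySpec


@pytest.fixture(scope="session")
def profile() -> BlockProfile:
    return BlockProfile.default()


@pytest.fixture(scope="session")
def two_family_genome():
    """A genome with two clearly distinct planted families plus remnants."""
    specs = [
        FamilySpec("famA", tir_length=30, tsd_length=8, n_copies=3,
                   orf_length=300, per_copy_divergence=0.01),
        FamilySpec("famB", tir_length=40, tsd_length=9, n_copies=3,
                   orf_length=260, per_copy_divergence=0.01, n_remnants=1),
    ]
    genome, truth = simgenome.simulate_genome(specs, 70000, seed=11)
    queries = dict(truth.family_proteins)
    return genome, truth, queries


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
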