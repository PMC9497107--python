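import numpy as np
import pytest

from svlandscape.simulate import DerivativeGenome, make_reference


@pytest.fixture(scope="session")
def small_ref():
    """Two random 200 kb contigs, shared across tests."""
    return make_reference(2, [200_000, 200_000], seed=101)


@pytest.fixture()
def plain_genome(small_ref):
    """An unedited derivative genome (all four haplotypes = reference)."""
    return DerivativeGenome(small_ref)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
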