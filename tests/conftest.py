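import pytest

from splimlib.design import decompose
from splimlib.examples import example_scheme, three_codon_scheme


@pytest.fixture(scope="session")
def scheme4():
    """Synthetic 4-site, fully saturated Affibody-like scheme."""
    return example_scheme()


@pytest.fixture(scope="session")
def design4(scheme4):
    return decompose(scheme4)


@pytest.fixture(scope="session")
def scheme3():
    """Three proximal codons: one 4-nt and one 3-nt overhang junction."""
    return three_codon_scheme()


@pytest.fixture(scope="session")
def design3(scheme3):
    return decompose(scheme3)
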