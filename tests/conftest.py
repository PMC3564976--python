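import pytest

from tetramate import fixtures
from tetramate.types import MatingGenotype, Ploidy


def mono(strain, a, b):
    return MatingGenotype.make(strain, Ploidy.monokaryon, {a}, {b})


def dika(strain, a_alleles, b_alleles):
    return MatingGenotype.make(
        strain, Ploidy.dikaryon, set(a_alleles), set(b_alleles)
    )


@pytest.fixture(scope="session")
def european_table():
    return fixtures.european_strains()


@pytest.fixture(scope="session")
def functional_pairs():
    return fixtures.functional_proxy_pairs()


@pytest.fixture(scope="session")
def sib_monokaryons():
    return fixtures.spore_family_monokaryons()


@pytest.fixture(scope="session")
def observed_crossings():
    return fixtures.spore_family_crossings()
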