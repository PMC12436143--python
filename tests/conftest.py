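import pytest

import snpsat


@pytest.fixture(scope="session")
def matrix():
    return snpsat.load_matrix()


@pytest.fixture(scope="session")
def b2m_cds():
    return snpsat.fixtures.b2m_cds()


@pytest.fixture(scope="session")
def b2m_protein():
    return snpsat.fixtures.b2m_protein()


@pytest.fixture(scope="session")
def b2m_records(b2m_cds, matrix):
    return snpsat.enumerate_snps(b2m_cds, matrix)
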