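import pytest

from nat2loh import (
    default_barcodes,
    load_allele_frequencies,
    load_definitions,
    packaged_amplicon_path,
)
from nat2loh.io import read_fasta


@pytest.fixture(scope="session")
def catalog_and_table():
    return load_definitions()


@pytest.fixture(scope="session")
def catalog(catalog_and_table):
    return catalog_and_table[0]


@pytest.fixture(scope="session")
def table(catalog_and_table):
    return catalog_and_table[1]


@pytest.fixture(scope="session")
def frequencies():
    return load_allele_frequencies()


@pytest.fixture(scope="session")
def reference():
    return read_fasta(packaged_amplicon_path())


@pytest.fixture(scope="session")
def barcodes():
    return default_barcodes(4)
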