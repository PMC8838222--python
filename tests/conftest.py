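import pytest

from karyoploid import datasets


@pytest.fixture(scope="session")
def genome_table():
    """The packaged per-individual genome-size table, measured rows only."""
    return datasets.load_genome_size_table()


@pytest.fixture(scope="session")
def karyotype_table():
    """The packaged per-species karyotype descriptor table."""
    return datasets.load_karyotype_table()
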