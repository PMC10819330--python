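import pytest
from hypothesis import settings

from amypep import datasets

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def peptides():
    return datasets.load_peptides()


@pytest.fixture(scope="session")
def enzyme_in():
    return datasets.load_enzyme_in()


@pytest.fixture(scope="session")
def enzyme_hbv():
    return datasets.load_enzyme_hbv()


@pytest.fixture(scope="session")
def peptide_hbv_entries():
    return datasets.load_peptide_hbv_entries()


@pytest.fixture(scope="session")
def positional_table():
    return datasets.load_positional()


@pytest.fixture(scope="session")
def descriptors():
    props, classes = datasets.load_aa_properties()
    from amypep.qsar import reduce_descriptors

    return reduce_descriptors(props, classes)
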