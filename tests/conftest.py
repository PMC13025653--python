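import pytest

from peptriact import datasets, rsm


@pytest.fixture(scope="session")
def corn_design():
    return datasets.load_corn_design()


@pytest.fixture(scope="session")
def corn_fits(corn_design):
    return {name: rsm.fit_quadratic(corn_design, name) for name in datasets.CORN_RESPONSES}


@pytest.fixture(scope="session")
def corn_peptides():
    return datasets.load_corn_peptides()
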