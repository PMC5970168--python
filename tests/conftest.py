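import pytest

from cotton_mapk import datasets


@pytest.fixture(scope="session")
def y2h_edges():
    return datasets.load_interactions()


@pytest.fixture(scope="session")
def kkk_kk_edges(y2h_edges):
    return [e for e in y2h_edges if e.tier == "KKK-KK"]


@pytest.fixture(scope="session")
def exclusions():
    return datasets.load_exclusions()
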