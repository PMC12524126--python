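import pytest

from ptsdcea import load_fixture


@pytest.fixture(scope="session")
def nf_psych():
    return load_fixture("nf_vs_psychotherapy")


@pytest.fixture(scope="session")
def nf_pharma():
    return load_fixture("nf_vs_pharmacotherapy")


@pytest.fixture(scope="session")
def prism():
    return load_fixture("prism_vs_each")


@pytest.fixture(scope="session")
def all_fixtures(nf_psych, nf_pharma, prism):
    return [nf_psych, nf_pharma, prism]
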