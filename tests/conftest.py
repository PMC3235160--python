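import pytest

from crmcooc.synthetic_data import placeholder_motifs, table2_fixture


@pytest.fixture(scope="session")
def motifs():
    """The five placeholder factor models used throughout the tests."""
    return placeholder_motifs()


@pytest.fixture(scope="session")
def default_counts(motifs):
    """Selected-subset instance requirements: 2 per factor, 1 for dTcf."""
    return {m: (1 if m == "dTcf" else 2) for m in motifs}


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()
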