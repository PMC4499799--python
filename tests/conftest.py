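import pytest

from equicheck import build_profile, table1_fixture


@pytest.fixture(scope="session")
def table1():
    """The published two-marker diagnostic alignment and its ground truth."""
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_profile(table1):
    alignments, truth = table1
    return build_profile(alignments, truth.pair)
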