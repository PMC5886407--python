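import pytest

from knotfold.energy import load_params


@pytest.fixture(scope="session")
def dp09():
    return load_params("DP09")


@pytest.fixture(scope="session")
def t99():
    return load_params("T99")
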