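import pytest

from fissureflux import ModelConstants, table2_fixture


@pytest.fixture
def constants():
    return ModelConstants()


@pytest.fixture
def survey():
    return table2_fixture()
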