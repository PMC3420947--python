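import pytest

from polyqmod.coiledcoil import load_default_matrix
from polyqmod.synthetic import load_modifier_table


@pytest.fixture(scope="session")
def matrix():
    return load_default_matrix()


@pytest.fixture(scope="session")
def modifier_table():
    return load_modifier_table()
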