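import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from gtreach.fixtures import (
    chain_model,
    complex_motif,
    diamond_model,
    toy_canonical_tgfb,
)


@pytest.fixture(scope="session")
def toy():
    return toy_canonical_tgfb()


@pytest.fixture()
def chain3():
    return chain_model(3)


@pytest.fixture()
def diamond():
    return diamond_model()


@pytest.fixture()
def complex_m():
    return complex_motif()
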