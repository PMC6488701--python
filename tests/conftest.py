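import numpy as np
import pytest

from degenstore.alphabet import STANDARD_ALPHABETS, standard_alphabet
from degenstore.codec import build_codon_table


@pytest.fixture(scope="session")
def alphabets():
    return {name: standard_alphabet(name) for name in STANDARD_ALPHABETS}


@pytest.fixture(scope="session")
def tables(alphabets):
    return {name: build_codon_table(a) for name, a in alphabets.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
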