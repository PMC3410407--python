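import numpy as np
import pytest

from ktfam.motifs import load_motif_library
from ktfam.trees import load_species_tree


@pytest.fixture(scope="session")
def motif_library():
    return load_motif_library()


@pytest.fixture()
def species_tree():
    return load_species_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein_seq(rng, length: int, alphabet: str = AA20) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))
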