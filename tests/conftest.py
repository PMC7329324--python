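import numpy as np
import pytest

import symbionet as sn

# unambiguous reverse codon table (one codon per amino acid, no stops)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def back_translate(protein: str) -> str:
    return "".join(CODON[a] for a in protein)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def parent_genome():
    return sn.random_genome("parent", 50_000, seed=7)


@pytest.fixture(scope="session")
def prototype_bgc():
    return sn.make_prototype_bgc("proto", n_genes=8, seed=11)


@pytest.fixture
def random_marker(rng):
    return "".join(rng.choice(list("ACGT"), size=600))
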