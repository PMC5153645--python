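import numpy as np
import pytest

from inotoscan.homology_search import ScoringScheme
from inotoscan.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


# Standard genetic code, written out independently of any library table,
# used as the oracle for translation tests.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def oracle_translate(nt: str, frame: int) -> str:
    """Frame in {+1..+3, -1..-3}; trailing partial codons dropped."""
    if frame < 0:
        nt = nt.translate(_COMPLEMENT)[::-1]
    offset = abs(frame) - 1
    sub = nt[offset:]
    return "".join(
        CODON_TABLE[sub[i : i + 3]] for i in range(0, len(sub) - 2, 3)
    )


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]
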