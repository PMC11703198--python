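import numpy as np
import pytest

from spice.motif_io import MotifDatabase, MotifModel
from spice.peaks_io import SequenceWindow

ALPHABET = "ACGT"


def random_seq(rng: np.random.Generator, length: int, p=None) -> str:
    return "".join(ALPHABET[i] for i in rng.choice(4, size=length, p=p))


def random_motif(rng: np.random.Generator, name: str, width: int, sharpness: float = 5.0) -> MotifModel:
    """A random Dirichlet-column motif; higher sharpness = more informative."""
    pfm = rng.dirichlet([1.0 / sharpness] * 4, size=width)
    return MotifModel(name=name, pfm=pfm)


def plant(seq: str, site: str, pos: int) -> str:
    return seq[:pos] + site + seq[pos + len(site):]


def windows_from_seqs(seqs) -> list[SequenceWindow]:
    return [SequenceWindow(id=f"w{i}", seq=s) for i, s in enumerate(seqs)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)


MEME_SMALL = """\
MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.30 C 0.20 G 0.20 T 0.30

MOTIF AP1_TEST
letter-probability matrix: alength= 4 w= 7 nsites= 50 E= 1e-10
0.02 0.02 0.02 0.94
0.02 0.02 0.94 0.02
0.94 0.02 0.02 0.02
0.02 0.47 0.47 0.04
0.02 0.02 0.02 0.94
0.02 0.94 0.02 0.02
0.94 0.02 0.02 0.02

MOTIF UNIFORM_TEST
letter-probability matrix: alength= 4 w= 4 nsites= 10 E= 1
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
"""


@pytest.fixture
def meme_small(tmp_path):
    path = tmp_path / "small.meme"
    path.write_text(MEME_SMALL)
    return path


@pytest.fixture
def tiny_db(rng) -> MotifDatabase:
    motifs = [random_motif(rng, f"M{i}", 8) for i in range(6)]
    return MotifDatabase(motifs=motifs)
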