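import numpy as np
import pytest

from glycopu.seqio import AMINO_ACIDS, PeptideWindow


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_windows(rng):
    """Factory: n random 15-mer windows, optionally with 'X' symbols."""

    def make(n=100, with_x=False, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        alphabet = list(AMINO_ACIDS) + (["X"] * 3 if with_x else [])
        return [PeptideWindow("".join(local.choice(alphabet, size=15)))
                for _ in range(n)]

    return make


@pytest.fixture
def write_fasta(tmp_path):
    def _write(text, name="test.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
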