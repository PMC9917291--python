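import numpy as np
import pytest

from thermoseq.io import ProteinRecord
from thermoseq.synthetic_data import GeneratorSpec, generate_corpus

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """60-record strong-signal corpus reused across model tests."""
    return generate_corpus(GeneratorSpec(n_pos=30, n_neg=30, seed=11))


@pytest.fixture
def fasta_file(tmp_path):
    def write(entries, name="test.fasta"):
        path = tmp_path / name
        path.write_text(
            "".join(f">{h}\n{s}\n" for h, s in entries)
        )
        return path

    return write


@pytest.fixture
def make_record():
    def _make(id="r", length=40, residue="A", ogt=None, label=None, desc=""):
        return ProteinRecord(id, residue * length, label=label, ogt=ogt,
                             description=desc)

    return _make
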