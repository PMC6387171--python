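import numpy as np
import pytest

from motifskim import SequenceRead

BASES = np.array(list("ACGT"))


def random_read(rng: np.random.Generator, length: int, read_id: str = "r") -> SequenceRead:
    return SequenceRead(id=read_id, sequence="".join(rng.choice(BASES, size=length)))


def read_with_array(
    rng: np.random.Generator,
    length: int,
    unit: str,
    copies: int,
    read_id: str = "r",
) -> SequenceRead:
    """Random-background read with one planted exact tandem array."""
    seq = "".join(rng.choice(BASES, size=length))
    array = unit * copies
    if len(array) > length:
        raise ValueError("array longer than read")
    offset = int(rng.integers(0, length - len(array) + 1))
    seq = seq[:offset] + array + seq[offset + len(array):]
    return SequenceRead(id=read_id, sequence=seq)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def fastq_file(tmp_path):
    """Two-record FASTQ with mixed-case bases and mate suffixes."""
    path = tmp_path / "reads.fastq"
    path.write_text(
        "@read1/1\nacgtACGTacgt\n+\nIIIIIIIIIIII\n"
        "@read2/2\nTTTAGGGTTTAGGG\n+\nIIIIIIIIIIIIII\n"
    )
    return path
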