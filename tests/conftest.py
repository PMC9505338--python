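import numpy as np
import pytest

from thermostab.sequence_io import ProteinRecord
from thermostab.tables import STANDARD_AA


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=length))


@pytest.fixture(scope="session")
def random_sequences() -> list[str]:
    """30 random sequences, lengths 35-120, fixed seed."""
    rng = np.random.default_rng(42)
    return [
        random_sequence(rng, int(rng.integers(35, 121))) for _ in range(30)
    ]


@pytest.fixture(scope="session")
def random_records(random_sequences) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=f"r{i}", sequence=s) for i, s in enumerate(random_sequences)
    ]
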