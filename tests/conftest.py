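import numpy as np
import pytest

from famtrace.sequence_io import ProteinRecord
from famtrace.synthetic_data import AMINO_ACIDS, default_seed_protein


@pytest.fixture(scope="session")
def seed_protein():
    return default_seed_protein(300)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length, start_m=True):
    seq = "".join(rng.choice(list(AMINO_ACIDS), length))
    if start_m:
        seq = "M" + seq[1:]
    return ProteinRecord(f"p{rng.integers(10**6)}", seq)
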