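import numpy as np
import pytest

from kcolor.encoding import EncodedRead, codes_to_str
from kcolor.scoring import ScoringScheme


def random_valid_scheme(rng: np.random.Generator) -> ScoringScheme:
    """A random scheme satisfying the sign constraints."""
    gap_extend = -int(rng.integers(10, 120))
    return ScoringScheme(
        color_match=int(rng.integers(0, 60)),
        color_mismatch=-int(rng.integers(1, 300)),
        base_match=int(rng.integers(0, 80)),
        base_mismatch=-int(rng.integers(1, 300)),
        gap_extend=gap_extend,
        gap_open=gap_extend - int(rng.integers(1, 300)),
    )


def random_instance(rng: np.random.Generator, max_n=6, max_m=6, max_k=3):
    """A random tiny (read, reference) pair for oracle comparisons."""
    k = int(rng.integers(1, max_k + 1))
    n = int(rng.integers(1, max_n + 1))
    m = int(rng.integers(1, max_m + 1))
    adaptor = codes_to_str(rng.integers(0, 4, k - 1))
    read = EncodedRead(adaptor=adaptor, colors=tuple(int(c) for c in rng.integers(0, 4, n)))
    reference = codes_to_str(rng.integers(0, 4, m))
    return read, reference


def random_dna(rng: np.random.Generator, length: int) -> str:
    return codes_to_str(rng.integers(0, 4, length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
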