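import numpy as np
import pytest

from ktheta.alignment import AlignedSequenceSet, distance_matrix


def mutate(seq: str, positions, alphabet="ACGT") -> str:
    """Deterministically substitute the given positions (cyclic next base)."""
    out = list(seq)
    for p in positions:
        out[p] = alphabet[(alphabet.index(out[p]) + 1) % 4]
    return "".join(out)


def random_sequence(rng: np.random.Generator, L: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_block_alignment():
    """Two blocks of near-identical sequences, ~20% divergence between."""
    rng = np.random.default_rng(7)
    base_a = random_sequence(rng, 300)
    base_b = mutate(base_a, rng.choice(300, size=60, replace=False))
    recs = [
        ("a1", base_a),
        ("a2", mutate(base_a, [0, 10])),
        ("a3", mutate(base_a, [5])),
        ("b1", base_b),
        ("b2", mutate(base_b, [20, 30])),
        ("b3", mutate(base_b, [40])),
    ]
    return AlignedSequenceSet.from_pairs(recs)


@pytest.fixture
def two_block_matrix(two_block_alignment):
    return distance_matrix(two_block_alignment, model="JC")
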