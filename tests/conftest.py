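import numpy as np
import pytest

from afdist import DNA, Pattern, PatternSet, Sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20140514)


@pytest.fixture
def worked_example():
    """The ten-residue sequence and weight-3 pattern of the worked example."""
    return Sequence("S", "ATTATGCTAG"), Pattern("11001")


@pytest.fixture
def pattern_set():
    return PatternSet([Pattern("11001"), Pattern("101"), Pattern("111")])


def random_dna(rng, length: int, name: str = "x") -> Sequence:
    return Sequence(name, "".join(rng.choice(list("ACGT"), size=length)))


def brute_force_kmismatch(xs: str, ys: str, k: int, alphabet=DNA) -> np.ndarray:
    """Independent triple-loop oracle for k-mismatch matching statistics.

    Two residues match only if they are equal AND inside the alphabet
    (ambiguity codes never match anything).
    """
    out = np.zeros(len(xs), dtype=np.int64)
    for i in range(len(xs)):
        best = 0
        for j in range(len(ys)):
            mism = 0
            length = 0
            while i + length < len(xs) and j + length < len(ys):
                a, b = xs[i + length], ys[j + length]
                if a != b or a not in alphabet.symbols:
                    mism += 1
                    if mism > k:
                        break
                length += 1
            best = max(best, length)
        out[i] = best
    return out
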