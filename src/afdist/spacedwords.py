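"""Spaced-word frequency profiles and profile distances.

A spaced word is read off a sequence through a binary pattern: the residues
at the pattern's match positions form the word, the don't-care positions
accept any residue. For the sequence ``ATTATGCTAG`` and the pattern
``11001`` the six windows yield the words ``AT**T, TT**G, TA**C, AT**T,
TG**A, GC**G`` (``*`` marks a don't-care), so the relative frequency of
``AT**T`` is 2/6 and of the four other observed words 1/6 each.

Distances between two sequences are computed per pattern on the relative
frequency vectors — Euclidean or Jensen-Shannon — and then averaged over
the whole pattern set.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._types import Alphabet, DistanceMatrix, Sequence
from .errors import ContractError
from .patterns import Pattern, PatternSet
from .seqio import detect_alphabet

METRICS = ("euclidean", "js")


@dataclass
class SpacedWordProfile:
    """Sparse relative-frequency profile of spaced words under one pattern.

    Only observed words are stored; keys are the match-position characters
    (length = pattern weight). Mathematically identical to a dense vector
    over all |Σ|^weight possible words.
    """

    pattern: Pattern
    counts: dict
    total: int

    def frequency(self, word: str) -> float:
        return self.counts.get(word, 0) / self.total

    def frequencies(self) -> dict:
        return {w: c / self.total for w, c in self.counts.items()}


def extract_spaced_words(seq: Sequence, p: Pattern, alphabet: Alphabet = None) -> list:
    """List the spaced words of ``seq`` under pattern ``p``, left to right.

    One word per window position; a window whose *match* positions include a
    character outside the alphabet (e.g. N or X) is skipped — don't-care
    positions may hold anything. A sequence shorter than the pattern yields
    an empty list.
    """
    if alphabet is None:
        alphabet = detect_alphabet([seq])
    res = seq.residues
    pos = p.positions
    ell = p.length
    symbols = alphabet.symbols
    words = []
    for i in range(len(res) - ell + 1):
        chars = [res[i + j] for j in pos]
        if all(c in symbols for c in chars):
            words.append("".join(chars))
    return words


def format_spaced_word(word: str, p: Pattern) -> str:
    """Render a word key with '*' at the pattern's don't-care positions."""
    it = iter(word)
    return "".join(next(it) if c == "1" else "*" for c in p.mask)


def build_profile(seq: Sequence, p: Pattern, alphabet: Alphabet = None) -> SpacedWordProfile:
    """Aggregate spaced-word counts of ``seq`` under ``p`` into a profile."""
    words = extract_spaced_words(seq, p, alphabet)
    if not words:
        raise ContractError(
            f"sequence too short for pattern: no valid window of {p.mask!r} "
            f"in sequence {seq.name!r}"
        )
    counts = Counter(words)
    return SpacedWordProfile(pattern=p, counts=dict(counts), total=len(words))


def _check_same_pattern(a: SpacedWordProfile, b: SpacedWordProfile) -> None:
    if a.pattern.mask != b.pattern.mask:
        raise ContractError(
            f"profiles built under different patterns: {a.pattern.mask} vs {b.pattern.mask}"
        )


def _aligned_frequencies(a: SpacedWordProfile, b: SpacedWordProfile):
    keys = sorted(set(a.counts) | set(b.counts))
    fa = np.array([a.counts.get(k, 0) for k in keys], dtype=float) / a.total
    fb = np.array([b.counts.get(k, 0) for k in keys], dtype=float) / b.total
    return fa, fb


def euclidean_distance(a: SpacedWordProfile, b: SpacedWordProfile) -> float:
    """Euclidean distance between two relative-frequency profiles."""
    _check_same_pattern(a, b)
    fa, fb = _aligned_frequencies(a, b)
    return float(np.sqrt(np.sum((fa - fb) ** 2)))


def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def jensen_shannon_distance(
    a: SpacedWordProfile, b: SpacedWordProfile, sqrt: bool = False
) -> float:
    """Jensen-Shannon divergence between two profiles, in bits (range [0, 1]).

    JS(A,B) = H((A+B)/2) − (H(A)+H(B))/2 with Shannon entropy H in base 2.
    ``sqrt=True`` returns the square root, which is a true metric.
    """
    _check_same_pattern(a, b)
    fa, fb = _aligned_frequencies(a, b)
    js = _entropy2((fa + fb) / 2.0) - (_entropy2(fa) + _entropy2(fb)) / 2.0
    js = min(max(js, 0.0), 1.0)  # clip float roundoff to the theoretical range
    return math.sqrt(js) if sqrt else js


def pairwise_distance(
    x: Sequence,
    y: Sequence,
    ps: PatternSet,
    metric: str = "euclidean",
    alphabet: Alphabet = None,
    js_sqrt: bool = False,
) -> float:
    """Mean over all patterns of the per-pattern profile distance."""
    if metric not in METRICS:
        raise ContractError(f"unknown metric {metric!r}; choose from {METRICS}")
    if alphabet is None:
        alphabet = detect_alphabet([x, y])
    for p in ps:
        for s in (x, y):
            if p.length > len(s):
                raise ContractError(
                    f"pattern {p.mask!r} is longer than sequence {s.name!r}"
                )
    total = 0.0
    for p in ps:
        pa = build_profile(x, p, alphabet)
        pb = build_profile(y, p, alphabet)
        if metric == "euclidean":
            total += euclidean_distance(pa, pb)
        else:
            total += jensen_shannon_distance(pa, pb, sqrt=js_sqrt)
    return total / len(ps)


def distance_matrix(
    seqs,
    ps: PatternSet,
    metric: str = "euclidean",
    alphabet: Alphabet = None,
    js_sqrt: bool = False,
) -> DistanceMatrix:
    """Pairwise spaced-word distance matrix over a sequence set."""
    if len(seqs) < 2:
        raise ContractError("need at least two sequences for a distance matrix")
    if metric not in METRICS:
        raise ContractError(f"unknown metric {metric!r}; choose from {METRICS}")
    if alphabet is None:
        alphabet = detect_alphabet(seqs)
    for p in ps:
        for s in seqs:
            if p.length > len(s):
                raise ContractError(
                    f"pattern {p.mask!r} is longer than sequence {s.name!r}"
                )
    # Build each profile once: the matrix needs n*|ps| profiles, not n^2.
    profiles = [[build_profile(s, p, alphabet) for p in ps] for s in seqs]
    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            total = 0.0
            for a, b in zip(profiles[i], profiles[j]):
                if metric == "euclidean":
                    total += euclidean_distance(a, b)
                else:
                    total += jensen_shannon_distance(a, b, sqrt=js_sqrt)
            values[i, j] = values[j, i] = total / len(ps)
    return DistanceMatrix([s.name for s in seqs], values)
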