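"""Match/don't-care patterns for spaced words.

A pattern is a binary mask such as ``11001``: '1' marks a *match* position
(the residue there is part of the spaced word) and '0' a *don't-care*
position (any residue is allowed). The number of '1's is the pattern's
*weight*, its total length counts both kinds of position. Distances are
usually averaged over a whole set of patterns, which stabilizes the
estimate compared with a single pattern.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass

import numpy as np

from ._types import Alphabet, Sequence
from .errors import ContractError, InputFormatError

logger = logging.getLogger(__name__)

_MASK_RE = re.compile(r"^[01]+$")

#: Number of random patterns generated by default.
DEFAULT_NUM_PATTERNS = 10


@dataclass(frozen=True)
class Pattern:
    """A binary match/don't-care mask. The first position is always a match."""

    mask: str

    def __post_init__(self) -> None:
        if not _MASK_RE.match(self.mask):
            raise InputFormatError(f"invalid pattern mask: {self.mask!r}")
        if self.mask[0] != "1":
            raise ContractError(
                f"pattern mask must start with a match position: {self.mask!r}"
            )

    @property
    def weight(self) -> int:
        """Number of match positions."""
        return self.mask.count("1")

    @property
    def length(self) -> int:
        return len(self.mask)

    @property
    def positions(self) -> tuple:
        """Indices of the match positions, left to right."""
        return tuple(i for i, c in enumerate(self.mask) if c == "1")

    def __str__(self) -> str:
        return self.mask


class PatternSet:
    """An ordered set of distinct patterns."""

    def __init__(self, patterns) -> None:
        pats = list(patterns)
        if not pats:
            raise ContractError("pattern set must be non-empty")
        masks = [p.mask for p in pats]
        if len(set(masks)) != len(masks):
            raise ContractError("duplicate masks in pattern set")
        self.patterns = pats

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def __getitem__(self, i) -> Pattern:
        return self.patterns[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PatternSet) and self.masks() == other.masks()

    def masks(self) -> list:
        return [p.mask for p in self.patterns]

    @property
    def max_length(self) -> int:
        return max(p.length for p in self.patterns)


def parse_pattern(mask: str) -> Pattern:
    """Parse a binary mask string into a :class:`Pattern`.

    Leading don't-care positions only shift the window without changing the
    induced spaced words, so they are canonicalized away with a warning.
    """
    if not mask or not _MASK_RE.match(mask):
        raise InputFormatError(f"invalid pattern mask: {mask!r}")
    if "1" not in mask:
        raise InputFormatError(f"pattern has zero weight: {mask!r}")
    stripped = mask.lstrip("0")
    if stripped != mask:
        logger.warning(
            "pattern %r starts with don't-care positions; canonicalized to %r",
            mask,
            stripped,
        )
    return Pattern(stripped)


def generate_random_patterns(
    weight: int, dont_care: int, count: int, seed: int
) -> PatternSet:
    """Generate ``count`` distinct random patterns of the given shape.

    Every pattern has length ``weight + dont_care`` with exactly ``weight``
    match positions; the first and last positions are always matches and the
    interior is shuffled uniformly. Deterministic given ``seed``.
    """
    if weight < 2:
        raise ContractError("pattern weight must be >= 2")
    if dont_care < 0:
        raise ContractError("number of don't-care positions must be >= 0")
    if count < 1:
        raise ContractError("pattern count must be >= 1")
    length = weight + dont_care
    interior = length - 2
    ones_interior = weight - 2
    n_possible = math.comb(interior, ones_interior)
    if count > n_possible:
        raise ContractError(
            f"cannot generate {count} distinct patterns of weight {weight} and "
            f"length {length}: only {n_possible} exist"
        )
    rng = np.random.default_rng(seed)

    def _mask(inner_positions) -> str:
        inner = ["0"] * interior
        for p in inner_positions:
            inner[p] = "1"
        return "1" + "".join(inner) + "1"

    if n_possible <= 200_000:
        combos = list(itertools.combinations(range(interior), ones_interior))
        chosen = rng.permutation(n_possible)[:count]
        masks = [_mask(combos[i]) for i in chosen]
    else:
        seen, masks = set(), []
        while len(masks) < count:
            pos = tuple(
                sorted(rng.choice(interior, size=ones_interior, replace=False))
            )
            if pos not in seen:
                seen.add(pos)
                masks.append(_mask(pos))
    return PatternSet(Pattern(m) for m in masks)


def default_parameters(seqs, alphabet: Alphabet) -> tuple:
    """Default (weight, dont_care, count) for random pattern generation.

    The weight scales with the log of the mean sequence length so that a
    random spaced word is expected to occur roughly once per position by
    chance; the pattern length is twice the weight, and ten patterns are
    generated (the averaging over patterns is what stabilizes the distance;
    more patterns help further but cost run time).
    """
    if not seqs:
        raise ContractError("need at least one sequence")
    l_avg = sum(len(s) for s in seqs) / len(seqs)
    base = len(alphabet.symbols)
    raw = math.ceil(math.log(l_avg) / math.log(base) - 1e-9)
    if alphabet.kind == "DNA":
        w = min(max(raw + 2, 4), 14)
    else:
        w = min(max(raw + 1, 2), 6)
    return w, w, DEFAULT_NUM_PATTERNS
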