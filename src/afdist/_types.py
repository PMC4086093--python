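"""Core value types shared across modules: sequences, alphabets, distance matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError

DNA_SYMBOLS = frozenset("ACGT")
PROTEIN_SYMBOLS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Alphabet:
    """A residue alphabet: the four nucleotides or the twenty amino acids."""

    kind: str
    symbols: frozenset

    def __contains__(self, ch: str) -> bool:
        return ch in self.symbols


DNA = Alphabet("DNA", DNA_SYMBOLS)
PROTEIN = Alphabet("PROTEIN", PROTEIN_SYMBOLS)


@dataclass(frozen=True)
class Sequence:
    """A named residue string.

    ``name`` is the FASTA header up to the first whitespace; ``residues`` is
    the uppercased residue string with gap/stop characters removed.
    """

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ContractError("sequence name must be non-empty")
        if not self.residues:
            raise ContractError(f"empty sequence: {self.name}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class DistanceMatrix:
    """A symmetric, zero-diagonal matrix of pairwise distances over named sequences."""

    names: list = field(default_factory=list)
    values: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ContractError(
                f"distance matrix shape {self.values.shape} does not match {n} names"
            )
        if len(set(self.names)) != n:
            raise ContractError("duplicate names in distance matrix")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("distance matrix contains non-finite values")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ContractError("distance matrix is not symmetric")
        if not np.all(self.values.diagonal() == 0.0):
            raise ContractError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.names)

    def __getitem__(self, pair) -> float:
        a, b = pair
        i = self.names.index(a) if isinstance(a, str) else a
        j = self.names.index(b) if isinstance(b, str) else b
        return float(self.values[i, j])
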