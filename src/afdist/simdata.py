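"""Synthetic sequence and matrix generators used for testing and simulation.

The mutation model is deliberately minimal: independent per-site
substitutions at a fixed rate (each hit is replaced by a *different*
symbol drawn uniformly), with an optional per-site deletion probability
for unaligned-sequence scenarios. This is enough to exercise the
distance methods' rank behaviour — distance should grow with divergence —
without modelling rate heterogeneity, indel length distributions or
back-substitution corrections. All generators are pure functions of their
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._types import DNA, Alphabet, DistanceMatrix, Sequence
from .errors import ContractError
from .njtree import TreeNode, tree_distance_matrix


@dataclass(frozen=True)
class MutationModel:
    """Per-site substitution (and optional deletion) probabilities."""

    substitution_rate: float
    seed: int
    deletion_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ContractError("substitution_rate must be in [0, 1]")
        if not 0.0 <= self.deletion_rate <= 1.0:
            raise ContractError("deletion_rate must be in [0, 1]")


def random_sequences(
    n: int, length: int, alphabet: Alphabet = DNA, seed: int = 0
) -> list:
    """``n`` i.i.d. uniform random sequences named ``sim_1`` .. ``sim_n``."""
    if n < 1 or length < 1:
        raise ContractError("n and length must be >= 1")
    symbols = np.array(sorted(alphabet.symbols))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(symbols), size=(n, length))
    return [
        Sequence(f"sim_{i + 1}", "".join(symbols[row])) for i, row in enumerate(idx)
    ]


def mutate(seq: Sequence, model: MutationModel, alphabet: Alphabet = DNA) -> Sequence:
    """Apply the mutation model to a sequence.

    Each site is independently substituted with probability
    ``substitution_rate``; the replacement is drawn uniformly from the
    alphabet *excluding* the original symbol. Deletions (if enabled) are
    applied after substitution.
    """
    symbols = sorted(alphabet.symbols)
    index = {c: i for i, c in enumerate(symbols)}
    s = len(symbols)
    rng = np.random.default_rng(model.seed)
    chars = list(seq.residues)
    hits = rng.random(len(chars)) < model.substitution_rate
    offsets = rng.integers(1, s, size=len(chars))
    for i in np.flatnonzero(hits):
        orig = index.get(chars[i], int(rng.integers(0, s)))
        chars[i] = symbols[(orig + int(offsets[i])) % s]
    if model.deletion_rate > 0.0:
        dels = rng.random(len(chars)) < model.deletion_rate
        chars = [c for c, gone in zip(chars, dels) if not gone]
    if not chars:
        raise ContractError("mutation deleted the entire sequence")
    return Sequence(f"{seq.name}_mut", "".join(chars))


def random_additive_matrix(n: int, seed: int = 0):
    """A random additive distance matrix and its generating tree.

    Builds a random rooted binary tree over ``n`` leaves (random pair
    agglomeration) with branch lengths uniform in (0.1, 2.0) and returns
    the leaf path-length matrix together with the tree. Such a matrix
    satisfies the four-point condition by construction, so NJ must recover
    the topology and path lengths exactly.
    """
    if n < 4:
        raise ContractError("need at least 4 leaves for an additive matrix")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"leaf_{i + 1}") for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode(children=[a, b])
        nodes = [nd for t, nd in enumerate(nodes) if t not in (i, j)] + [parent]
    root = nodes[0]
    names = [f"leaf_{i + 1}" for i in range(n)]
    return tree_distance_matrix(root, names), root
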