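"""Neighbour-Joining tree reconstruction from a distance matrix.

Standard Saitou–Nei agglomeration with the Studier–Keppler Q-criterion.
The output is an unrooted tree represented with a trifurcating root for
n >= 3 (the Phylip ``neighbor`` convention); negative branch-length
estimates are clamped to zero. Ties in the Q matrix are broken by the
lexicographically smallest index pair, so the output is deterministic.
NJ is consistent: on an additive (tree-realizable) matrix it recovers the
generating topology and branch lengths exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._types import DistanceMatrix
from .errors import ContractError

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    """A tree node; ``length`` is the branch length to the parent (None at the root)."""

    name: str = None
    children: list = field(default_factory=list)
    length: float = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list:
        return [l.name for l in self.leaves()]


def _clamp(length: float) -> float:
    if length < 0.0:
        logger.debug("negative branch length %.6g clamped to 0", length)
        return 0.0
    return length


def neighbor_joining(m: DistanceMatrix) -> TreeNode:
    """Build a Neighbour-Joining tree from a distance matrix."""
    n = m.n
    if n < 2:
        raise ContractError("neighbor joining needs at least 2 sequences")
    d = m.values.astype(float).copy()
    nodes = [TreeNode(name=nm) for nm in m.names]

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        # Mask the diagonal and lower triangle; flat argmin then scans the
        # upper triangle row-major, i.e. lexicographic (i, j) tie-breaking.
        q[np.tril_indices(r)] = np.inf
        i, j = divmod(int(np.argmin(q)), r)
        dij = d[i, j]
        li = dij / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        a, b = nodes[i], nodes[j]
        a.length = _clamp(li)
        b.length = _clamp(lj)
        parent = TreeNode(children=[a, b])
        dnew = (d[i, :] + d[j, :] - dij) / 2.0
        keep = [t for t in range(r) if t not in (i, j)]
        d2 = np.empty((r - 1, r - 1))
        d2[: r - 2, : r - 2] = d[np.ix_(keep, keep)]
        d2[: r - 2, r - 2] = d2[r - 2, : r - 2] = dnew[keep]
        d2[r - 2, r - 2] = 0.0
        d = d2
        nodes = [nodes[t] for t in keep] + [parent]

    if len(nodes) == 2:
        half = d[0, 1] / 2.0
        nodes[0].length = _clamp(half)
        nodes[1].length = _clamp(half)
        return TreeNode(children=nodes)

    # Final trifurcation: branch of node t = (d(t,u) + d(t,v) - d(u,v)) / 2.
    l0 = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    l1 = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    l2 = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = _clamp(ln)
    return TreeNode(children=nodes)


def tree_distance_matrix(tree: TreeNode, names=None) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    dists: dict = {}

    def visit(node: TreeNode) -> dict:
        if node.is_leaf():
            return {node.name: 0.0}
        maps = []
        for child in node.children:
            cm = visit(child)
            edge = child.length if child.length is not None else 0.0
            maps.append({leaf: dd + edge for leaf, dd in cm.items()})
        for a in range(len(maps)):
            for b in range(a + 1, len(maps)):
                for la, da in maps[a].items():
                    for lb, db in maps[b].items():
                        dists[frozenset((la, lb))] = da + db
        merged = {}
        for cm in maps:
            merged.update(cm)
        return merged

    visit(tree)
    if names is None:
        names = sorted(tree.leaf_names())
    k = len(names)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = dists[frozenset((names[i], names[j]))]
    return DistanceMatrix(list(names), values)


def splits(tree: TreeNode) -> set:
    """Non-trivial bipartitions of the leaf set, one frozenset per internal edge.

    Each split is normalized to the side *not* containing the
    lexicographically smallest leaf, so rooted trees that represent the same
    unrooted topology produce identical split sets.
    """
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out = set()

    def visit(node: TreeNode) -> frozenset:
        if node.is_leaf():
            return frozenset((node.name,))
        below = frozenset().union(*(visit(c) for c in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = all_leaves - below if ref in below else below
            out.add(side)
        return below

    for child in tree.children:
        visit(child)
    return out
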