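"""Shared oracles for tree tests: random ultrametric/additive inputs and
brute-force reference computations independent of the package internals."""

import numpy as np

from proofer import DistanceMatrix


def random_distance_matrix(rng, n, low=0.05, high=1.0):
    """Random symmetric matrix with (almost surely) distinct off-diagonals."""
    vals = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals[iu] = rng.uniform(low, high, size=len(iu[0]))
    vals = vals + vals.T
    ids = tuple(f"t{i}" for i in range(n))
    return DistanceMatrix(ids=ids, values=vals)


class _Node:
    def __init__(self, name=None, children=(), lengths=()):
        self.name = name
        self.children = list(children)
        self.lengths = list(lengths)  # edge length to each child

    def leaves(self):
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def random_additive_tree(rng, n):
    """Random rooted binary tree over n leaves with branch lengths in
    [0.1, 1]; returns (root, leaf-to-leaf path distance DistanceMatrix)."""
    assert n >= 3
    roots = [_Node(name=f"t{i}") for i in range(n)]
    while len(roots) > 2:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        a, b = roots[i], roots[j]
        parent = _Node(children=(a, b), lengths=tuple(rng.uniform(0.1, 1.0, 2)))
        roots = [r for k, r in enumerate(roots) if k not in (i, j)] + [parent]
    root = _Node(children=tuple(roots), lengths=tuple(rng.uniform(0.1, 1.0, 2)))

    # depth of every leaf below every ancestor -> pairwise path lengths
    depths = {}  # leaf -> {ancestor id: distance}

    def walk(node, acc):
        if not node.children:
            depths[node.name] = dict(acc)
            depths[node.name][id(node)] = 0.0
            return
        for child, length in zip(node.children, node.lengths):
            walk(child, {**{k: v + length for k, v in acc.items()}, id(node): length})

    walk(root, {})
    names = sorted(depths, key=lambda s: int(s[1:]))
    m = np.zeros((n, n))
    for i, x in enumerate(names):
        for j in range(i + 1, n):
            y = names[j]
            common = set(depths[x]) & set(depths[y])
            m[i, j] = m[j, i] = min(depths[x][k] + depths[y][k] for k in common)
    return root, DistanceMatrix(ids=tuple(names), values=m)


def skbio_tip_distances(tree_node):
    """Leaf-pair path-length matrix of a skbio tree as {frozenset: float}."""
    dm = tree_node.tip_tip_distances()
    out = {}
    ids = list(dm.ids)
    for i, x in enumerate(ids):
        for j in range(i + 1, len(ids)):
            out[frozenset((x, ids[j]))] = float(dm[i, j])
    return out
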