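"""Binary distances, hierarchical clustering, neighbor-joining and the
tree-trimming group-count statistic.

Articles are compared by their binary term profiles through a 2x2
contingency per pair (a = shared presences, b/c = mismatches, d = shared
absences). Asymmetric coefficients (Jaccard, Sorensen, Ochiai,
Kulczynski II) ignore d — two articles are not similar merely because both
lack a term — while symmetric ones (simple matching, Rogers-Tanimoto,
Hamann) reward shared absence. The default seven-coefficient panel mirrors a
3-symmetric / 4-asymmetric split; note that under the (1-S)/2 normalization
the Hamann distance coincides numerically with simple matching, so it is
kept as a named alias of that family rather than an independent signal.

Agglomerative linkage (single, complete, UPGMA, WPGMA/McQuitty) produces
ultrametric dendrograms with node height = merge distance / 2; ties are
broken by merging the lexicographically smallest pair of cluster ids so
results are platform-stable. Neighbor-joining produces an unrooted additive
tree (exact on additive inputs); for group counting it is midpoint-rooted.

Group counting trims the labeled tree: each round removes every maximal
label-pure internal subtree (one recovered group each) and suppresses unary
nodes; when no pure internal subtree remains, every residual leaf is its own
group.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "BinaryContingency",
    "DistanceMatrix",
    "LabeledTree",
    "DistanceUndefinedError",
    "COEFFICIENTS",
    "SYMMETRIC_COEFFICIENTS",
    "ASYMMETRIC_COEFFICIENTS",
    "DEFAULT_COEFFICIENTS",
    "LINKAGE_METHODS",
    "contingency",
    "binary_distance",
    "pairwise_distances",
    "linkage_cluster",
    "neighbor_joining",
    "prune_count_groups",
    "sweep",
]


class DistanceUndefinedError(ValueError):
    """A coefficient's denominator is zero for the given pair."""


# ---------------------------------------------------------------------------
# binary distance coefficients
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinaryContingency:
    """2x2 contingency for one pair of binary presence vectors."""

    a: int  # 1/1
    b: int  # 1/0
    c: int  # 0/1
    d: int  # 0/0

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency(x: Sequence[int], y: Sequence[int]) -> BinaryContingency:
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return BinaryContingency(
        a=int(np.sum(x & y)),
        b=int(np.sum(x & ~y)),
        c=int(np.sum(~x & y)),
        d=int(np.sum(~x & ~y)),
    )


def _checked(num: float, den: float, name: str) -> float:
    if den == 0:
        raise DistanceUndefinedError(f"{name} distance undefined: zero denominator")
    return num / den


def _jaccard(t: BinaryContingency) -> float:
    return 1.0 - _checked(t.a, t.a + t.b + t.c, "jaccard")


def _sorensen(t: BinaryContingency) -> float:
    return 1.0 - _checked(2 * t.a, 2 * t.a + t.b + t.c, "sorensen")


def _ochiai(t: BinaryContingency) -> float:
    return 1.0 - _checked(t.a, math.sqrt((t.a + t.b) * (t.a + t.c)), "ochiai")


def _kulczynski2(t: BinaryContingency) -> float:
    if t.a + t.b == 0 or t.a + t.c == 0:
        raise DistanceUndefinedError("kulczynski2 distance undefined: zero denominator")
    return 1.0 - 0.5 * (t.a / (t.a + t.b) + t.a / (t.a + t.c))


def _simple_matching(t: BinaryContingency) -> float:
    return _checked(t.b + t.c, t.n, "simple_matching")


def _rogers_tanimoto(t: BinaryContingency) -> float:
    return _checked(2 * (t.b + t.c), t.a + t.d + 2 * (t.b + t.c), "rogers_tanimoto")


def _sokal_sneath(t: BinaryContingency) -> float:
    return 1.0 - _checked(t.a, t.a + 2 * (t.b + t.c), "sokal_sneath")


def _hamann(t: BinaryContingency) -> float:
    # (1 - (a+d-b-c)/n) / 2, algebraically equal to (b+c)/n
    if t.n == 0:
        raise DistanceUndefinedError("hamann distance undefined: zero denominator")
    return (1.0 - (t.a + t.d - t.b - t.c) / t.n) / 2.0


COEFFICIENTS: dict[str, Callable[[BinaryContingency], float]] = {
    "jaccard": _jaccard,
    "sorensen": _sorensen,
    "ochiai": _ochiai,
    "kulczynski2": _kulczynski2,
    "simple_matching": _simple_matching,
    "rogers_tanimoto": _rogers_tanimoto,
    "sokal_sneath": _sokal_sneath,
    "hamann": _hamann,
}

#: Coefficients whose value depends on joint absences (d).
SYMMETRIC_COEFFICIENTS = ("simple_matching", "rogers_tanimoto", "hamann")
#: Coefficients ignoring joint absences.
ASYMMETRIC_COEFFICIENTS = ("jaccard", "sorensen", "ochiai", "kulczynski2", "sokal_sneath")

#: Default analysis panel: 3 symmetric + 4 asymmetric.
DEFAULT_COEFFICIENTS = (
    "simple_matching",
    "rogers_tanimoto",
    "hamann",
    "jaccard",
    "sorensen",
    "ochiai",
    "kulczynski2",
)


def binary_distance(x: Sequence[int], y: Sequence[int], coefficient: str) -> float:
    """Distance in [0, 1] between two binary presence vectors."""
    try:
        fn = COEFFICIENTS[coefficient]
    except KeyError:
        raise ValueError(
            f"unknown coefficient {coefficient!r}; choose from {sorted(COEFFICIENTS)}"
        ) from None
    return fn(contingency(x, y))


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.isfinite(self.values).all():
            raise ValueError("distance matrix must be finite")
        if (self.values < -1e-12).any():
            raise ValueError("distance matrix must be nonnegative")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=tuple(str(i) for i in df.index), values=df.to_numpy())


def pairwise_distances(matrix, coefficient: str) -> DistanceMatrix:
    """All-pairs article distances from an occurrence matrix.

    Raises :class:`DistanceUndefinedError` naming the first offending pair
    when a denominator vanishes (e.g. two all-zero articles under an
    asymmetric coefficient).
    """
    binary = matrix.binary if hasattr(matrix, "binary") else pd.DataFrame(matrix)
    ids = tuple(str(i) for i in binary.index)
    x = binary.to_numpy(dtype=np.int64)
    n = len(ids)
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = COEFFICIENTS[coefficient](contingency(x[i], x[j]))
            except DistanceUndefinedError as exc:
                raise DistanceUndefinedError(
                    f"{exc} (articles {ids[i]!r}, {ids[j]!r})"
                ) from None
            out[i, j] = out[j, i] = d
    return DistanceMatrix(ids=ids, values=out)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class LabeledTree:
    """A tree over article leaves plus optional per-leaf group labels.

    ``labels`` maps leaf name -> {'family': ..., 'superfamily': ...}.
    Dendrograms are rooted and ultrametric; neighbor-joining trees are
    unrooted (stored with a trifurcating root node).
    """

    tree: TreeNode
    rooted: bool = True
    labels: dict[str, dict[str, str]] | None = None

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def attach_labels(self, labels: pd.DataFrame | Mapping[str, Mapping[str, str]]) -> None:
        if isinstance(labels, pd.DataFrame):
            self.labels = {
                str(idx): {
                    level: str(row[level])
                    for level in ("family", "superfamily")
                    if level in labels.columns
                }
                for idx, row in labels.iterrows()
            }
        else:
            self.labels = {k: dict(v) for k, v in labels.items()}

    def label_of(self, leaf: str, level: str) -> str:
        if self.labels is None or leaf not in self.labels or level not in self.labels[leaf]:
            raise ValueError(f"leaf {leaf!r} has no {level!r} label")
        return self.labels[leaf][level]

    def write_newick(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.newick())

    def newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue()

    @classmethod
    def read_newick(cls, path: str | Path, rooted: bool = True) -> "LabeledTree":
        return cls(tree=TreeNode.read(str(path), format="newick"), rooted=rooted)


LINKAGE_METHODS = ("single", "complete", "upgma", "wpgma")


def linkage_cluster(dist: DistanceMatrix, method: str) -> LabeledTree:
    """Agglomerative hierarchical clustering via Lance-Williams updates.

    Returns an ultrametric dendrogram: each merge at distance D creates a
    node at height D/2, so cophenetic distances equal merge distances. Among
    equally close pairs the lexicographically smallest pair of cluster ids
    (each cluster named by its smallest leaf) merges first.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}, got {method!r}")
    n = len(dist)
    if n < 2:
        raise ValueError("need at least 2 leaves to cluster")

    # cluster id -> (tree node, size, height); pair distances keyed by ids
    nodes: dict[str, tuple[TreeNode, int, float]] = {
        name: (TreeNode(name=name), 1, 0.0) for name in dist.ids
    }
    d: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((dist.ids[i], dist.ids[j]))] = float(dist.values[i, j])

    while len(nodes) > 1:
        best: tuple[float, str, str] | None = None
        for pair, dij in d.items():
            u, v = sorted(pair)
            key = (dij, u, v)
            if best is None or key < best:
                best = key
        dij, u, v = best
        node_u, size_u, h_u = nodes.pop(u)
        node_v, size_v, h_v = nodes.pop(v)
        height = dij / 2.0
        node_u.length = max(height - h_u, 0.0)
        node_v.length = max(height - h_v, 0.0)
        merged = TreeNode(children=[node_u, node_v])
        new_id = u  # u < v lexicographically

        del d[frozenset((u, v))]
        for w in list(nodes):
            duw = d.pop(frozenset((u, w)))
            dvw = d.pop(frozenset((v, w)))
            if method == "single":
                dnew = min(duw, dvw)
            elif method == "complete":
                dnew = max(duw, dvw)
            elif method == "upgma":
                dnew = (size_u * duw + size_v * dvw) / (size_u + size_v)
            else:  # wpgma (McQuitty)
                dnew = (duw + dvw) / 2.0
            d[frozenset((new_id, w))] = dnew
        nodes[new_id] = (merged, size_u + size_v, height)

    (root, _, _), = nodes.values()
    root.length = None
    return LabeledTree(tree=root, rooted=True)


def neighbor_joining(dist: DistanceMatrix) -> LabeledTree:
    """Saitou-Nei neighbor-joining; exact on additive distance matrices.

    Negative branch length estimates are clamped to zero with the deficit
    moved to the sibling branch so pairwise path lengths are preserved.
    Requires >= 3 leaves (use :func:`linkage_cluster` for fewer).
    """
    n = len(dist)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 leaves; use linkage_cluster")

    ids = list(dist.ids)
    D = dist.values.copy()
    nodes: dict[str, TreeNode] = {name: TreeNode(name=name) for name in ids}

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(ids) > 3:
        m = len(ids)
        totals = D.sum(axis=1)
        # Q-matrix; deterministic tie-break on (Q, id pair)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - totals[i] - totals[j]
                u, v = sorted((ids[i], ids[j]))
                key = (q, u, v)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        child_i, child_j = nodes[ids[i]], nodes[ids[j]]
        child_i.length = li
        child_j.length = lj
        new_name = min(ids[i], ids[j])
        merged = TreeNode(children=[child_i, child_j])

        dnew = 0.5 * (D[:, i] + D[:, j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = {name: nodes[name] for name in (ids[k] for k in keep)}
        nodes[new_name] = merged
        ids = [ids[k] for k in keep] + [new_name]

    # resolve the final three subtrees around a central node
    (x, y, z) = ids
    dxy, dxz, dyz = D[0, 1], D[0, 2], D[1, 2]
    lx = 0.5 * (dxy + dxz - dyz)
    ly = 0.5 * (dxy + dyz - dxz)
    lz = 0.5 * (dxz + dyz - dxy)
    lx, ly, lz = (max(v, 0.0) for v in (lx, ly, lz))
    for name, length in ((x, lx), (y, ly), (z, lz)):
        nodes[name].length = length
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    return LabeledTree(tree=root, rooted=False)


# ---------------------------------------------------------------------------
# group counting by tree trimming
# ---------------------------------------------------------------------------


class _N:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []


def _to_plain(node: TreeNode, labels: Mapping[str, str]) -> _N:
    if node.is_tip():
        if node.name not in labels:
            raise ValueError(f"leaf {node.name!r} has no group label")
        return _N(label=labels[node.name])
    return _N(children=[_to_plain(c, labels) for c in node.children])


def _leaf_labels(node: _N) -> set[str]:
    if not node.children:
        return {node.label}
    out: set[str] = set()
    for c in node.children:
        out |= _leaf_labels(c)
    return out


def _trim_round(node: _N) -> tuple[_N | None, int]:
    """Remove every maximal label-pure internal subtree; return the trimmed
    tree (None if nothing remains) and the number of groups removed."""
    if not node.children:
        return node, 0
    if len(_leaf_labels(node)) == 1:
        return None, 1
    removed = 0
    new_children: list[_N] = []
    for child in node.children:
        kept, r = _trim_round(child)
        removed += r
        if kept is not None:
            new_children.append(kept)
    if not new_children:
        return None, removed
    if len(new_children) == 1:
        return new_children[0], removed
    return _N(children=new_children), removed


def _count_leaves(node: _N) -> int:
    if not node.children:
        return 1
    return sum(_count_leaves(c) for c in node.children)


def prune_count_groups(tree: LabeledTree, level: str) -> int:
    """Number of taxon groups recovered by trimming a labeled tree.

    Rounds of trimming remove every maximal subtree whose leaves all share
    one label at ``level`` (counting one group per removal) until no pure
    internal subtree is left; each remaining leaf then counts as a group of
    its own. A perfectly sorted tree yields the number of distinct labels; a
    perfectly shuffled one yields the number of leaves.
    """
    if tree.labels is None:
        raise ValueError("tree carries no group labels; call attach_labels first")
    labels = {leaf: tree.label_of(leaf, level) for leaf in tree.leaf_names}

    topo = tree.tree
    if not tree.rooted and len(labels) > 2:
        topo = tree.tree.copy().root_at_midpoint()

    plain = _to_plain(topo, labels)
    count = 0
    while plain is not None:
        if not plain.children:  # single residual leaf
            count += 1
            break
        plain, removed = _trim_round(plain)
        if removed == 0:
            count += _count_leaves(plain)
            break
        count += removed
    return count


# ---------------------------------------------------------------------------
# the coefficient x method x threshold sweep
# ---------------------------------------------------------------------------


def build_tree(
    matrix,
    coefficient: str,
    method: str,
    labels: pd.DataFrame | None = None,
) -> LabeledTree:
    """Distance -> tree for one (coefficient, method) cell; ``method`` is a
    linkage name or 'nj'."""
    dist = pairwise_distances(matrix, coefficient)
    if method == "nj":
        tree = neighbor_joining(dist)
    else:
        tree = linkage_cluster(dist, method)
    lab = labels if labels is not None else getattr(matrix, "labels", None)
    if lab is not None:
        tree.attach_labels(lab)
    return tree


def sweep(
    matrix,
    coefficients: Iterable[str] = DEFAULT_COEFFICIENTS,
    methods: Iterable[str] = LINKAGE_METHODS + ("nj",),
    thresholds: Iterable[int] = (2, 10, 50, 100),
    level: str = "superfamily",
    count_mode: str = "articles",
    newick_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Full factorial grid of recovered group counts.

    Returns a DataFrame with columns coefficient, method, threshold,
    n_terms, n_groups, error. Cells whose distances are undefined (or with
    too few usable terms) record the error and leave n_groups empty.
    """
    from .occurrence import filter_by_occurrence

    thresholds = sorted(thresholds)
    if newick_dir is not None:
        newick_dir = Path(newick_dir)
        newick_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k in thresholds:
        sub = filter_by_occurrence(matrix, k, mode=count_mode)
        for coefficient in coefficients:
            for method in methods:
                row = {
                    "coefficient": coefficient,
                    "method": method,
                    "threshold": k,
                    "n_terms": sub.shape[1],
                    "n_groups": np.nan,
                    "error": "",
                }
                try:
                    if sub.shape[1] == 0:
                        raise DistanceUndefinedError("no terms left at this threshold")
                    tree = build_tree(sub, coefficient, method)
                    row["n_groups"] = prune_count_groups(tree, level)
                    if newick_dir is not None:
                        tree.write_newick(
                            newick_dir / f"{coefficient}_{method}_k{k}.nwk"
                        )
                except (DistanceUndefinedError, ValueError) as exc:
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)
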