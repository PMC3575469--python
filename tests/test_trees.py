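"""Hierarchical clustering, neighbor-joining and the group-count statistic,
cross-checked against scipy and scikit-bio."""

import io

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix as SkbioDM, TreeNode
from skbio.tree import nj as skbio_nj

from proofer import (
    DistanceMatrix,
    LabeledTree,
    LINKAGE_METHODS,
    linkage_cluster,
    neighbor_joining,
    prune_count_groups,
)
from _helpers import random_additive_tree, random_distance_matrix, skbio_tip_distances

SCIPY_METHOD = {"single": "single", "complete": "complete",
                "upgma": "average", "wpgma": "weighted"}


def labeled(newick: str, labels: dict[str, str], rooted=True) -> LabeledTree:
    tree = LabeledTree(
        tree=TreeNode.read(io.StringIO(newick)), rooted=rooted
    )
    tree.attach_labels({leaf: {"family": g, "superfamily": g} for leaf, g in labels.items()})
    return tree


class TestLinkage:
    def test_two_leaves_form_a_cherry_at_half_distance(self):
        dm = DistanceMatrix(ids=("A", "B"), values=np.array([[0.0, 4.0], [4.0, 0.0]]))
        tree = linkage_cluster(dm, "single")
        (a, b) = tree.tree.children
        assert {a.name, b.name} == {"A", "B"}
        assert a.length == b.length == 2.0

    def test_hand_traced_upgma_three_leaves(self):
        dm = DistanceMatrix(
            ids=("A", "B", "C"),
            values=np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float),
        )
        tree = linkage_cluster(dm, "upgma")
        dists = skbio_tip_distances(tree.tree)
        assert dists[frozenset(("A", "B"))] == pytest.approx(2.0)
        assert dists[frozenset(("A", "C"))] == pytest.approx(6.0)
        assert dists[frozenset(("B", "C"))] == pytest.approx(6.0)
        c = next(t for t in tree.tree.tips() if t.name == "C")
        assert c.length == pytest.approx(3.0)

    def test_single_and_complete_differ_on_chained_similarities(self):
        # A-B close, B-C close, A-C far: single chains, complete does not
        vals = squareform([0.1, 0.9, 0.15, 0.95, 0.2, 0.92])
        dm = DistanceMatrix(ids=("A", "B", "C", "D"), values=vals)
        single = skbio_tip_distances(linkage_cluster(dm, "single").tree)
        complete = skbio_tip_distances(linkage_cluster(dm, "complete").tree)
        assert single != complete

    @pytest.mark.parametrize("method", LINKAGE_METHODS)
    def test_dendrograms_are_ultrametric(self, method, rng):
        dm = random_distance_matrix(rng, 7)
        tree = linkage_cluster(dm, method)
        depths = {t.name: t.accumulate_to_ancestor(tree.tree) for t in tree.tree.tips()}
        assert max(depths.values()) == pytest.approx(min(depths.values()))

    @pytest.mark.parametrize("method", LINKAGE_METHODS)
    def test_agrees_with_scipy_on_random_matrices(self, method, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            dm = random_distance_matrix(rng, n)
            tree = linkage_cluster(dm, method)
            mine = skbio_tip_distances(tree.tree)
            Z = linkage(squareform(dm.values, checks=False), method=SCIPY_METHOD[method])
            ref = squareform(cophenet(Z))
            for i in range(n):
                for j in range(i + 1, n):
                    key = frozenset((dm.ids[i], dm.ids[j]))
                    assert mine[key] == pytest.approx(ref[i, j], abs=1e-9)

    def test_rejects_tiny_or_asymmetric_input(self):
        with pytest.raises(ValueError):
            linkage_cluster(DistanceMatrix(ids=("A",), values=np.zeros((1, 1))), "single")
        with pytest.raises(ValueError):
            DistanceMatrix(ids=("A", "B"), values=np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_deterministic_under_ties(self):
        vals = squareform([0.5] * 6)  # every pair equidistant
        dm = DistanceMatrix(ids=("d", "c", "b", "a"), values=vals)
        t1 = linkage_cluster(dm, "upgma").newick()
        t2 = linkage_cluster(dm, "upgma").newick()
        assert t1 == t2


class TestNeighborJoining:
    def test_exact_on_spec_four_taxon_additive_matrix(self):
        # path lengths on ((A:1,B:2):1,(C:3,D:4))
        ids = ("A", "B", "C", "D")
        vals = squareform([3, 5, 6, 6, 7, 7])
        tree = neighbor_joining(DistanceMatrix(ids=ids, values=vals.astype(float)))
        assert tree.rooted is False
        dists = skbio_tip_distances(tree.tree)
        for (i, j), expect in {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
                               ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}.items():
            assert dists[frozenset((i, j))] == pytest.approx(expect, abs=1e-9)
        # the A,B cherry is resolved
        a = next(t for t in tree.tree.tips() if t.name == "A")
        assert {t.name for t in a.parent.tips()} == {"A", "B"}

    def test_three_leaves_solved_by_three_point_formulas(self):
        vals = squareform([3.0, 4.0, 5.0])
        tree = neighbor_joining(DistanceMatrix(ids=("X", "Y", "Z"), values=vals))
        lengths = {t.name: t.length for t in tree.tree.tips()}
        assert lengths == pytest.approx({"X": 1.0, "Y": 2.0, "Z": 3.0})

    def test_recovers_random_additive_trees_exactly(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 11))
            _, dm = random_additive_tree(rng, n)
            tree = neighbor_joining(dm)
            dists = skbio_tip_distances(tree.tree)
            for i in range(n):
                for j in range(i + 1, n):
                    key = frozenset((dm.ids[i], dm.ids[j]))
                    assert dists[key] == pytest.approx(dm.values[i, j], abs=1e-9)

    def test_agrees_with_skbio_nj_on_additive_input(self, rng):
        _, dm = random_additive_tree(rng, 7)
        mine = skbio_tip_distances(neighbor_joining(dm).tree)
        ref_tree = skbio_nj(SkbioDM(dm.values, ids=dm.ids))
        ref = skbio_tip_distances(ref_tree)
        for key, val in mine.items():
            assert val == pytest.approx(ref[key], abs=1e-9)

    def test_rejects_fewer_than_three_leaves(self):
        dm = DistanceMatrix(ids=("A", "B"), values=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="linkage_cluster"):
            neighbor_joining(dm)

    def test_branch_lengths_never_negative(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            dm = random_distance_matrix(rng, n)  # generally non-additive
            tree = neighbor_joining(dm)
            assert all(t.length >= 0 for t in tree.tree.postorder() if t.length is not None)


class TestPruneCount:
    def test_perfectly_sorted_tree_counts_labels(self):
        tree = labeled("((a1,a2),(b1,b2));", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert prune_count_groups(tree, "family") == 2

    def test_perfectly_shuffled_tree_counts_leaves(self):
        tree = labeled("((a1,b1),(a2,b2));", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert prune_count_groups(tree, "family") == 4

    def test_caterpillar_trim_merges_residual_pure_group(self):
        tree = labeled(
            "(a1,(a2,(b1,(b2,b3))));",
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"},
        )
        assert prune_count_groups(tree, "family") == 2

    def test_single_label_tree_is_one_group(self):
        tree = labeled("((x1,x2),(x3,(x4,x5)));", {f"x{i}": "X" for i in range(1, 6)})
        assert prune_count_groups(tree, "family") == 1

    def test_interleaved_caterpillar_counts_each_leaf(self):
        tree = labeled("(a1,(b1,a2));", {"a1": "A", "a2": "A", "b1": "B"})
        assert prune_count_groups(tree, "family") == 3

    def test_missing_label_names_the_leaf(self):
        tree = LabeledTree(tree=TreeNode.read(io.StringIO("(a1,b1);")))
        tree.attach_labels({"a1": {"family": "A"}})
        with pytest.raises(ValueError, match="b1"):
            prune_count_groups(tree, "family")

    def test_bounds_and_label_permutation_invariance(self, rng):
        labels_pool = ["A", "B", "C"]
        for _ in range(25):
            n = int(rng.integers(4, 12))
            root, dm = random_additive_tree(rng, n)
            assignment = {f"t{i}": labels_pool[int(rng.integers(3))] for i in range(n)}
            tree = neighbor_joining(dm)
            tree.attach_labels({k: {"family": v, "superfamily": v} for k, v in assignment.items()})
            count = prune_count_groups(tree, "family")
            assert len(set(assignment.values())) <= count <= n
            # bijective relabeling leaves the count unchanged
            perm = {"A": "Z", "B": "Y", "C": "X"}
            tree.attach_labels(
                {k: {"family": perm[v], "superfamily": perm[v]} for k, v in assignment.items()}
            )
            assert prune_count_groups(tree, "family") == count

    def test_unrooted_trees_are_midpoint_rooted_first(self, rng):
        _, dm = random_additive_tree(rng, 6)
        tree = neighbor_joining(dm)
        tree.attach_labels({f"t{i}": {"superfamily": "G"} for i in range(6)})
        assert prune_count_groups(tree, "superfamily") == 1


class TestNewick:
    def test_round_trip(self, tmp_path, rng):
        dm = random_distance_matrix(rng, 5)
        tree = linkage_cluster(dm, "upgma")
        path = tmp_path / "tree.nwk"
        tree.write_newick(path)
        reread = LabeledTree.read_newick(path)
        assert skbio_tip_distances(reread.tree) == pytest.approx(
            skbio_tip_distances(tree.tree)
        )
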