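import random

import dendropy
import numpy as np
import pytest

from barcodegap.distances import distance_matrix
from barcodegap.errors import TreeError
from barcodegap.njtree import Node, Tree, bootstrap_support, nj, write_newick
from conftest import matrix_from_dict
from helpers import make_locus, random_additive_case


def nj_from_dict(ids, dists):
    return nj(matrix_from_dict(ids, dists))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        tree = nj_from_dict(
            ["a", "b", "c"], {("a", "b"): 0.3, ("a", "c"): 0.5, ("b", "c"): 0.6}
        )
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_four_taxon_additive_example(self):
        # additive matrix with topology AB|CD and lengths A:1 B:2 C:3 D:4, internal 1
        dists = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
                 ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
        tree = nj_from_dict(["A", "B", "C", "D"], dists)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        paths = tree.path_lengths()
        for (x, y), d in dists.items():
            key = (x, y) if x < y else (y, x)
            assert paths[key] == pytest.approx(d, abs=1e-9)
        leaf_lengths = {
            n.name: n.length for n in tree.root.walk() if n.is_leaf
        }
        assert leaf_lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_equidistant_matrix_fits_paths(self):
        ids = ["a", "b", "c", "d"]
        dists = {(x, y): 0.4 for i, x in enumerate(ids) for y in ids[i + 1:]}
        tree = nj_from_dict(ids, dists)
        for d in tree.path_lengths().values():
            assert d == pytest.approx(0.4, abs=1e-9)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(TreeError, match=">= 3"):
            nj_from_dict(["a", "b"], {("a", "b"): 0.1})

    def test_non_finite_rejected(self):
        m = matrix_from_dict(
            ["a", "b", "c"],
            {("a", "b"): np.inf, ("a", "c"): 0.1, ("b", "c"): 0.1},
        )
        with pytest.raises(TreeError, match="non-finite"):
            nj(m)

    def test_recovers_random_additive_trees(self):
        """NJ is consistent on additive matrices: exact topology and
        path-length fit for random 5-8 leaf trees."""
        rng = random.Random(20240901)
        for trial in range(30):
            n = rng.randint(5, 8)
            ids, dists, true_biparts = random_additive_case(rng, n)
            tree = nj_from_dict(ids, dists)
            assert tree.bipartitions() == true_biparts
            paths = tree.path_lengths()
            for (a, b), d in paths.items():
                assert d == pytest.approx(dists[(a, b)], abs=1e-9)

    def test_leaf_permutation_gives_isomorphic_tree(self):
        rng = random.Random(7)
        ids, dists, _ = random_additive_case(rng, 6)
        tree = nj_from_dict(ids, dists)
        shuffled = ids[::-1]
        tree2 = nj_from_dict(shuffled, dists)
        assert tree.bipartitions() == tree2.bipartitions()
        assert tree.path_lengths() == pytest.approx(tree2.path_lengths())

    def test_agrees_with_independent_implementation(self):
        """Cross-check topology against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        rng = random.Random(99)
        ids, dists, _ = random_additive_case(rng, 7)
        ours = nj_from_dict(ids, dists)
        dm = skbio.DistanceMatrix(
            np.array([[dists[(a, b)] for b in ids] for a in ids]), ids
        )
        theirs = skbio.tree.nj(dm)
        ref = min(ids)
        all_leaves = frozenset(ids)
        their_biparts = set()
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(ids) - 2:
                their_biparts.add(side if ref not in side else all_leaves - side)
        assert ours.bipartitions() == their_biparts


class TestBootstrap:
    def two_clade_locus(self):
        block_a = "A" * 30
        block_b = "A" * 20 + "G" * 5 + "T" * 5
        return make_locus("toy", {
            "a1": block_a, "a2": block_a, "a3": block_a,
            "b1": block_b, "b2": block_b,
        })

    def test_deterministic_signal_gives_full_support(self):
        locus = self.two_clade_locus()
        tree = nj(distance_matrix(locus))
        result = bootstrap_support(locus, tree, replicates=100, seed=5)
        split = frozenset({"b1", "b2"})
        assert result.supports[split] == 100.0
        assert result.replicates_failed == 0

    def test_supports_bounded_and_leaf_order_invariant(self):
        locus = self.two_clade_locus()
        reversed_locus = make_locus("toy", dict(
            (r.sample_id, r.sequence) for r in reversed(locus.records)
        ))
        t1 = nj(distance_matrix(locus))
        t2 = nj(distance_matrix(reversed_locus))
        r1 = bootstrap_support(locus, t1, replicates=50, seed=1)
        r2 = bootstrap_support(reversed_locus, t2, replicates=50, seed=1)
        for r in (r1, r2):
            assert all(0.0 <= s <= 100.0 for s in r.supports.values())
        split = frozenset({"b1", "b2"})
        assert r1.supports[split] == r2.supports[split] == 100.0

    def test_degenerate_alignment_reproduces_reference_every_replicate(self):
        # identical sequences: every resample regenerates the same (zero)
        # matrix, and deterministic tie-breaking yields the same tree
        locus = make_locus("toy", {k: "ACGT" * 10 for k in "abcde"})
        tree = nj(distance_matrix(locus))
        result = bootstrap_support(locus, tree, replicates=30, seed=3)
        assert all(s == 100.0 for s in result.supports.values())

    def test_annotation_lands_on_reference_branches(self):
        locus = self.two_clade_locus()
        tree = nj(distance_matrix(locus))
        bootstrap_support(locus, tree, replicates=20, seed=2)
        supports = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert supports and all(0 <= s <= 100 for s in supports)

    def test_mismatched_leaves_rejected(self):
        locus = self.two_clade_locus()
        other = make_locus("toy", {"x": "AAAAAA", "y": "AAAAGA", "z": "AATTAA"})
        tree = nj(distance_matrix(other))
        with pytest.raises(TreeError, match="do not match"):
            bootstrap_support(locus, tree, replicates=5, seed=0)


class TestNewickOutput:
    def test_three_taxon_newick_parses(self, tmp_path):
        tree = nj_from_dict(
            ["a", "b", "c"], {("a", "b"): 0.3, ("a", "c"): 0.5, ("b", "c"): 0.6}
        )
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == {"a", "b", "c"}

    def test_support_below_threshold_omitted(self):
        inner = Node(children=[Node("a", 0.1), Node("b", 0.1)], length=0.2)
        inner.support = 49.9
        tree = Tree(Node(children=[inner, Node("c", 0.3), Node("d", 0.4)]))
        assert "49.9" not in tree.to_newick(support_threshold=50.0)
        assert "49.9" in tree.to_newick(support_threshold=None)

    def test_round_trip_topology_and_lengths(self, tmp_path):
        rng = random.Random(11)
        ids, dists, _ = random_additive_case(rng, 6)
        tree = nj_from_dict(ids, dists)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        # topology is preserved ...
        parsed_biparts = set()
        all_leaves = frozenset(ids)
        ref = min(ids)
        for edge in parsed.preorder_edge_iter():
            head = edge.head_node
            if head.is_leaf() or head.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in head.leaf_iter())
            if 2 <= len(side) <= len(ids) - 2:
                parsed_biparts.add(side if ref not in side else all_leaves - side)
        assert parsed_biparts == tree.bipartitions()
        # ... and every branch length survives to 1e-6
        ours = sorted(
            n.length for n in tree.root.walk() if n is not tree.root
        )
        theirs = sorted(
            e.length for e in parsed.preorder_edge_iter() if e.length is not None
        )
        assert theirs == pytest.approx(ours, abs=1e-6)
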