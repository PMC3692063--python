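import pandas as pd
import pytest

import orthoplace as op
from orthoplace.io import OrthologyLabeling
from orthoplace.trees import PhyloTree

from .oracles import (
    oracle_brackets,
    oracle_duplications,
    oracle_kerf_valid,
    oracle_phog_groups,
    random_tree,
)


def _identity_frame(ids, values):
    df = pd.DataFrame(1.0, index=ids, columns=ids)
    for (a, b), v in values.items():
        df.loc[a, b] = df.loc[b, a] = v
    return df


class TestNewick:
    def test_round_trip(self):
        text = "((a:1,b:2):0.5,c:3);"
        tree = PhyloTree.from_newick(text)
        again = PhyloTree.from_newick(tree.to_newick())
        assert tree == again
        assert sorted(tree.leaf_ids) == ["a", "b", "c"]

    def test_unrooted_gets_midpoint_rooted(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="orthoplace.trees"):
            tree = PhyloTree.from_newick("(a:1,b:1,c:10);")
        assert "midpoint" in caplog.text
        assert len(tree.root.children) == 2

    def test_prune_leaf_suppresses_degree_one(self):
        tree = PhyloTree.from_newick("((a:1,b:2):0.5,c:3);")
        pruned = tree.prune_leaf("b")
        assert sorted(pruned.leaf_ids) == ["a", "c"]
        # a's branch absorbs the suppressed internal node's length
        assert pruned.node("a").length == pytest.approx(1.5)


class TestIdentityMatrix:
    def test_examples(self):
        aln = op.FamilyAlignment(["x", "y", "z"], ["AC-D", "AC-E", "A---"])
        ident = op.pairwise_identity_matrix(aln)
        assert ident.loc["x", "x"] == 1.0
        assert ident.loc["x", "y"] == pytest.approx(2 / 3)

    def test_no_cooccupied_columns(self):
        aln = op.FamilyAlignment(["x", "y"], ["A---", "---A"])
        assert op.pairwise_identity_matrix(aln).loc["x", "y"] == 0.0


class TestKerf:
    def test_whole_tree_when_all_similar(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,c:1);")
        ident = _identity_frame(["a", "b", "c"], {})
        clades = op.kerf_cut(tree, ident, 0.7)
        assert len(clades) == 1 and clades[0].members == frozenset("abc")

    def test_threshold_splits(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,c:1);")
        ident = _identity_frame(
            ["a", "b", "c"], {("a", "b"): 0.9, ("a", "c"): 0.6, ("b", "c"): 0.6}
        )
        clades = op.kerf_cut(tree, ident, 0.7)
        assert {frozenset(c.members) for c in clades} == {
            frozenset({"a", "b"}),
            frozenset({"c"}),
        }

    def test_single_leaf(self):
        tree = PhyloTree.from_newick("a;")
        clades = op.kerf_cut(tree, _identity_frame(["a"], {}), 0.7)
        assert [set(c.members) for c in clades] == [{"a"}]

    def test_random_trees_partition_and_maximality(self, rng):
        """Partition, identity floor, and maximality on random <=10-leaf trees."""
        for _ in range(25):
            n = int(rng.integers(2, 11))
            ids = [f"s{i}" for i in range(n)]
            tree = random_tree(rng, ids)
            vals = {}
            for i in range(n):
                for j in range(i + 1, n):
                    vals[(ids[i], ids[j])] = float(rng.uniform(0.2, 1.0))
            ident = _identity_frame(ids, vals)
            clades = op.kerf_cut(tree, ident, 0.7)
            assert oracle_kerf_valid(tree, ident, 0.7, clades)


class TestDuplications:
    def test_all_distinct_taxa(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,c:1);")
        taxa = {"a": "t1", "b": "t2", "c": "t3"}
        assert op.infer_duplication_nodes(tree, taxa) == set()

    def test_mirrored_subtrees_flag_root(self):
        tree = PhyloTree.from_newick("((a_hum:1,a_mus:1):1,(b_hum:1,b_mus:1):1);")
        taxa = {"a_hum": "hum", "a_mus": "mus", "b_hum": "hum", "b_mus": "mus"}
        dups = op.infer_duplication_nodes(tree, taxa)
        assert dups == {tree.root.node_id}

    def test_same_taxon_cherry(self):
        tree = PhyloTree.from_newick("((a1:1,a2:1):1,b:1);")
        taxa = {"a1": "tA", "a2": "tA", "b": "tB"}
        dups = op.infer_duplication_nodes(tree, taxa)
        cherry = tree.node("a1").parent.node_id
        assert dups == {cherry}

    def test_agrees_with_oracle_on_random_trees(self, rng):
        for _ in range(20):
            ids = [f"s{i}" for i in range(16)]
            tree = random_tree(rng, ids)
            taxa = {s: f"t{int(rng.integers(0, 6))}" for s in ids}
            assert op.infer_duplication_nodes(tree, taxa) == oracle_duplications(
                tree, taxa
            )


class TestPhogT0:
    def test_duplication_free_tree_single_group(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,c:1);")
        taxa = {"a": "t1", "b": "t2", "c": "t3"}
        groups = op.phog_t0_groups(tree, taxa)
        assert [set(g.members) for g in groups] == [{"a", "b", "c"}]

    def test_mirrored_subtrees_two_groups(self):
        tree = PhyloTree.from_newick("((a_hum:1,a_mus:1):1,(b_hum:1,b_mus:1):1);")
        taxa = {"a_hum": "hum", "a_mus": "mus", "b_hum": "hum", "b_mus": "mus"}
        groups = {frozenset(g.members) for g in op.phog_t0_groups(tree, taxa)}
        assert groups == {
            frozenset({"a_hum", "a_mus"}),
            frozenset({"b_hum", "b_mus"}),
        }

    def test_chain_of_duplications_gives_singletons(self):
        tree = PhyloTree.from_newick("((a1:1,a2:1):1,a3:1);")
        taxa = {"a1": "tA", "a2": "tA", "a3": "tA"}
        groups = {frozenset(g.members) for g in op.phog_t0_groups(tree, taxa)}
        assert groups == {frozenset({"a1"}), frozenset({"a2"}), frozenset({"a3"})}

    def test_random_trees_against_oracle(self, rng):
        """Partition, taxon uniqueness and agreement with exhaustive search."""
        for _ in range(20):
            ids = [f"s{i}" for i in range(16)]
            tree = random_tree(rng, ids)
            taxa = {s: f"t{int(rng.integers(0, 6))}" for s in ids}
            dups = op.infer_duplication_nodes(tree, taxa)
            groups = op.phog_t0_groups(tree, taxa, dups)
            members = [g.members for g in groups]
            all_leaves = [s for m in members for s in m]
            assert sorted(all_leaves) == sorted(ids)  # partition
            for m in members:
                taxa_in = [taxa[s] for s in m]
                assert len(taxa_in) == len(set(taxa_in))  # no taxon repeated
            assert {frozenset(m) for m in members} == oracle_phog_groups(tree, dups)


class TestBracketing:
    def test_no_labels_no_brackets(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,c:1);")
        assert op.subtree_bracket(tree, OrthologyLabeling("src", {})) == []

    def test_unlabeled_member_carried_along(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        labeling = OrthologyLabeling("src", {"A": "G1", "B": "G1", "D": "G1"})
        clades = op.subtree_bracket(tree, labeling)
        assert len(clades) == 1
        assert clades[0].members == frozenset({"A", "B", "C", "D"})

    def test_root_fails_both_children_criterion(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        labeling = OrthologyLabeling("src", {"A": "G1", "B": "G1"})
        clades = op.subtree_bracket(tree, labeling)
        assert len(clades) == 1
        assert clades[0].members == frozenset({"A", "B"})

    def test_random_labeled_trees_against_oracle(self, rng):
        for _ in range(25):
            ids = [f"s{i}" for i in range(16)]
            tree = random_tree(rng, ids)
            assignments = {
                s: f"G{int(rng.integers(0, 3))}" for s in ids if rng.random() < 0.6
            }
            labeling = OrthologyLabeling("src", assignments)
            clades = op.subtree_bracket(tree, labeling)
            got = {frozenset(c.members) for c in clades}
            assert got == oracle_brackets(tree, assignments)
            # pairwise disjoint
            flat = [s for c in clades for s in c.members]
            assert len(flat) == len(set(flat))


class TestEnclosingClade:
    def _tree(self):
        return PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")

    def test_exact_supported_clade(self):
        tree = self._tree()
        node = tree.node("a").parent.node_id
        supports = [
            op.SupportedClade(node, frozenset({"kerf"}), frozenset({"a", "b"}))
        ]
        clade = op.resolve_enclosing_clade(tree, node, supports)
        assert clade.members == frozenset({"a", "b"})
        assert clade.sources == frozenset({"kerf"})

    def test_larger_containing_clade_wins(self):
        tree = self._tree()
        cherry = tree.node("a").parent.node_id
        supports = [
            op.SupportedClade(cherry, frozenset({"kerf"}), frozenset({"a", "b"})),
            op.SupportedClade(
                tree.root.node_id,
                frozenset({"phog_t0"}),
                frozenset({"a", "b", "c", "d"}),
            ),
        ]
        clade = op.resolve_enclosing_clade(tree, "a", supports)
        assert clade.members == frozenset({"a", "b", "c", "d"})

    def test_fallback_is_top_node_with_no_support(self):
        tree = self._tree()
        supports = [
            op.SupportedClade(
                tree.node("c").parent.node_id, frozenset({"kerf"}),
                frozenset({"c", "d"}),
            )
        ]
        clade = op.resolve_enclosing_clade(tree, "a", supports)
        assert clade.members == frozenset({"a"})
        assert clade.sources == frozenset({"none"})

    def test_result_contains_top_node(self, rng):
        for _ in range(10):
            ids = [f"s{i}" for i in range(8)]
            tree = random_tree(rng, ids)
            taxa = {s: f"t{int(rng.integers(0, 4))}" for s in ids}
            supports = op.phog_t0_groups(tree, taxa)
            for node in tree.preorder():
                clade = op.resolve_enclosing_clade(tree, node.node_id, supports)
                assert tree.leaves_under(node.node_id) <= clade.members
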