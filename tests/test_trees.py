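"""Gene-tree data model: newick I/O, outgroup rooting, clade queries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phyloconflict.errors import (
    MissingSpeciesError,
    NewickParseError,
    RootingError,
)
from phyloconflict.trees import (
    GeneTree,
    GroupScheme,
    MissingBranchLengthWarning,
    read_newick,
    root_by_outgroup,
    write_newick,
)

from conftest import random_tree_newick


class TestReadNewick:
    def test_supports_parsed_from_internal_labels(self):
        tree = read_newick("((a:1,b:1)95:1,(c:1,d:1)88:1);")
        assert sorted(tree.leaf_labels()) == ["a", "b", "c", "d"]
        supports = sorted(n.support for n in tree.root.postorder()
                          if not n.is_leaf and n is not tree.root)
        assert supports == [88.0, 95.0]

    def test_minimal_two_tip_tree_has_no_support(self):
        with pytest.warns(MissingBranchLengthWarning):
            tree = read_newick("(a,b);")
        assert tree.n_tips() == 2
        assert all(n.support is None for n in tree.root.postorder())

    def test_malformed_newick_raises_parse_error_with_offset(self):
        with pytest.raises(NewickParseError, match="offset"):
            read_newick("((a,b")

    def test_missing_species_mapping_is_an_error(self):
        with pytest.raises(Exception, match="species"):
            read_newick("((a:1,b:1):1,c:1);", species_map={"a": "A", "b": "B"})

    def test_species_map_applied(self):
        tree = read_newick("((g1:1,g2:1):1,g3:1);",
                           species_map={"g1": "sp1", "g2": "sp1", "g3": "sp2"})
        assert tree.species_set() == {"sp1", "sp2"}

    def test_support_comment_dialect(self):
        tree = read_newick("((a:1,b:1)[&support=77]:1,c:1);",
                           support_dialect="comment")
        node = next(n for n in tree.root.postorder()
                    if not n.is_leaf and n is not tree.root)
        assert node.support == pytest.approx(77.0)

    def test_out_of_range_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            read_newick("((a:1,b:1)150:1,c:1);")


@given(st.integers(0, 10_000), st.integers(3, 12))
def test_newick_round_trip_preserves_topology_and_lengths(seed, n_tips):
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_tips)]
    text = random_tree_newick(rng, labels)
    tree = read_newick(text)
    again = read_newick(write_newick(tree))
    assert tree.topology_key() == again.topology_key()
    d1, d2 = tree.depths(), again.depths()
    tips1 = {l.label: d1[l] for l in tree.leaves()}
    tips2 = {l.label: d2[l] for l in again.leaves()}
    for label in tips1:
        assert tips1[label] == pytest.approx(tips2[label], rel=1e-9)


class TestMonophyly:
    def test_simple_clade_present(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert tree.is_monophyletic({"a", "b"})
        assert not read_newick("((a:1,c:1):1,(b:1,d:1):1);").is_monophyletic(
            {"a", "b"})

    def test_missing_species_listed(self):
        tree = read_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(MissingSpeciesError, match="zz"):
            tree.is_monophyletic({"a", "zz"})

    @given(st.integers(0, 5_000))
    def test_agrees_with_mrca_oracle_on_random_trees(self, seed):
        """Independent oracle: a species set is monophyletic iff the leafset
        under the MRCA of its tips equals exactly those tips."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels = [f"t{i}" for i in range(n)]
        tree = read_newick(random_tree_newick(rng, labels))
        k = int(rng.integers(2, n))
        target = set(rng.choice(labels, size=k, replace=False))

        def leafset(node):
            if node.is_leaf:
                return {node.label}
            return set().union(*(leafset(c) for c in node.children))

        node = tree.mrca(target)
        expected = leafset(node) == target
        assert tree.is_monophyletic(target) == expected


class TestRootByOutgroup:
    scheme = GroupScheme({"out": "og", "o1": "og", "o2": "og",
                          "a": "in", "b": "in", "c": "in", "d": "in"},
                         outgroup="og")

    def test_forced_placement(self):
        tree = read_newick("((out:1,a:1):1,(b:1,c:1):1);")
        rooted = root_by_outgroup(tree, self.scheme)
        kids = [frozenset(l.label for l in ch.leaves())
                for ch in rooted.root.children]
        assert frozenset(["out"]) in kids
        assert "outgroup_non_monophyletic" not in rooted.flags

    def test_idempotent(self):
        tree = read_newick("((out:1,a:1):1,(b:1,c:1):1);")
        once = root_by_outgroup(tree, self.scheme)
        twice = root_by_outgroup(once, self.scheme)
        assert once.topology_key() == twice.topology_key()

    def test_non_monophyletic_outgroup_flagged(self):
        tree = read_newick(
            "(((o1:1,a:1):1,(o2:1,b:1):1):1,(c:1,d:1):1);")
        rooted = root_by_outgroup(tree, self.scheme)
        assert "outgroup_non_monophyletic" in rooted.flags

    def test_no_outgroup_tips_is_error(self):
        tree = read_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(RootingError):
            root_by_outgroup(tree, self.scheme)

    def test_all_outgroup_is_error(self):
        tree = read_newick("((o1:1,o2:1):1,out:1);")
        with pytest.raises(RootingError):
            root_by_outgroup(tree, self.scheme)

    def test_root_separates_outgroup_after_rerooting(self):
        tree = read_newick("(((a:1,out:1):1,b:1):1,(c:1,d:1):1);")
        rooted = root_by_outgroup(tree, self.scheme)
        kids = [frozenset(l.label for l in ch.leaves())
                for ch in rooted.root.children]
        assert frozenset(["out"]) in kids


class TestPruning:
    def test_prune_sums_lengths(self):
        tree = read_newick("(((a:1,b:1):2,c:3):1,d:4);")
        pruned = tree.prune_to_species({"a", "c", "d"})
        depths = pruned.depths()
        tip = {l.label: depths[l] for l in pruned.leaves()}
        assert tip["a"] == pytest.approx(4.0)  # 1 + 2 + 1
        assert tip["d"] == pytest.approx(4.0)

    def test_prune_support_is_min_over_merged_edges(self):
        tree = read_newick("(((a:1,b:1)60:1,c:1)90:1,(d:1,e:1)80:1);")
        pruned = tree.prune_to_species({"a", "b", "d", "e"})
        # clade (a,b) merged with its 90-support parent edge -> min(60, 90)
        node = next(n for n, tips in pruned.clade_tip_sets()
                    if tips == frozenset(["a", "b"]))
        assert node.support == 60.0
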