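"""Topology census: classification, aggregation, chromosome homogeneity."""

import math
import warnings

import numpy as np
import pytest

from phyloconflict.census import (
    CensusResult,
    TypeDefinition,
    census,
    chromosome_homogeneity_test,
    classify_tree,
)
from phyloconflict.errors import MissingSpeciesError
from phyloconflict.network import SpeciesNetwork
from phyloconflict.simulate import SimConfig, simulate_msc_gene_trees
from phyloconflict.trees import GroupScheme, read_newick

SCHEME = GroupScheme(
    {"cm1": "chloranthales_magnoliids", "cm2": "chloranthales_magnoliids",
     "mo1": "monocots", "mo2": "monocots",
     "eu1": "eudicots", "eu2": "eudicots",
     "out": "outgroup"},
    outgroup="outgroup")


def _tree(newick):
    return read_newick(newick)


class TestClassifyTree:
    def test_type_i_textbook_topology(self):
        tree = _tree("(out:1,(cm1:1,(mo1:1,eu1:1)100:1)100:1);")
        assert classify_tree(tree, SCHEME) == "I"

    def test_support_filter_sends_to_other(self):
        tree = _tree("(out:1,(mo1:1,(cm1:1,eu1:1)65:1)100:1);")
        assert classify_tree(tree, SCHEME, support_threshold=70) == "other"
        assert classify_tree(tree, SCHEME, support_threshold=60) == "II"

    def test_type_iii(self):
        tree = _tree("(out:1,(eu1:1,(cm1:1,mo1:1)99:1)100:1);")
        assert classify_tree(tree, SCHEME) == "III"

    def test_missing_focal_group_is_error(self):
        tree = _tree("(out:1,(cm1:1,eu1:1)100:1);")
        with pytest.raises(MissingSpeciesError, match="monocots"):
            classify_tree(tree, SCHEME)

    def test_nonfocal_species_are_ignored(self):
        extra = GroupScheme(dict(SCHEME.groups, ce1="ceratophyllales"),
                            outgroup="outgroup")
        tree = _tree("(out:1,(cm1:1,(ce1:1,(mo1:1,eu1:1)100:1)100:1)100:1);")
        assert classify_tree(tree, extra) == "I"

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_clade_oracle(self, seed):
        """Panel of random 7-tip trees vs an independent recursive
        clade-set evaluation of the diagnostic definitions."""
        from conftest import random_tree_newick

        rng = np.random.default_rng(seed)
        labels = ["cm1", "cm2", "mo1", "mo2", "eu1", "eu2", "out"]
        tree = read_newick(random_tree_newick(rng, labels))
        from phyloconflict.trees import root_by_outgroup

        rooted = root_by_outgroup(tree, SCHEME)
        got = classify_tree(rooted, SCHEME, support_threshold=0)

        def clades(node):
            if node.is_leaf:
                return [{node.label}]
            all_sets = []
            for child in node.children:
                all_sets.extend(clades(child))
            all_sets.append({l.label for l in node.leaves()})
            return all_sets

        sets = [frozenset(s) for s in clades(rooted.root)]
        focal = {"cm1", "cm2", "mo1", "mo2", "eu1", "eu2"}
        sets = [s & focal for s in sets]
        g1, g2, g3 = {"cm1", "cm2"}, {"mo1", "mo2"}, {"eu1", "eu2"}
        expected = "other"
        for label, target in (("I", g2 | g3), ("II", g1 | g3),
                              ("III", g1 | g2)):
            if any(s == target for s in sets):
                expected = label
        assert got == expected

    def test_diagnostic_clades_mutually_exclusive_on_simulated_trees(self):
        net = SpeciesNetwork.from_newick(
            "((((cm1:1,cm2:1):1,(eu1:1,eu2:1):2):0.3,(mo1:1,mo2:1):2.3):1,"
            "out:4.3);")
        scheme = SCHEME
        trees = simulate_msc_gene_trees(net, SimConfig(seed=0, n_trees=300))
        for tree in trees:
            # classify_tree asserts internally that at most one type matches
            classify_tree(tree, scheme, support_threshold=0)


class TestCensus:
    def test_printed_count_arithmetic(self):
        result = CensusResult.from_counts(
            {"I": 454}, other=742 - 454)
        assert round(100 * result.counts["I"].raw / 742) == 61

    def test_monophyly_fraction_arithmetic(self):
        result = CensusResult.from_counts(
            {"I": 316, "II": 496, "III": 203},
            monophyly_counts={"I": 168, "II": 297, "III": 122})
        fracs = {k: round(100 * c.monophyly_fraction, 1)
                 for k, c in result.counts.items()}
        assert fracs == {"I": 53.2, "II": 59.9, "III": 60.1}

    def test_identical_trees_give_single_type(self):
        trees = [_tree("(out:1,(cm1:1,(mo1:1,eu1:1)100:1)100:1);")
                 for _ in range(10)]
        result = census(trees, SCHEME)
        assert result.counts["I"].proportion == 1.0
        assert result.counts["II"].bs_pass == 0

    def test_proportions_invariant_under_permutation(self):
        net = SpeciesNetwork.from_newick(
            "((((cm1:1,cm2:1):1,(eu1:1,eu2:1):2):0.3,(mo1:1,mo2:1):2.3):1,"
            "out:4.3);")
        trees = simulate_msc_gene_trees(net, SimConfig(seed=4, n_trees=400))
        a = census(trees, SCHEME)
        rng = np.random.default_rng(0)
        shuffled = [trees[i] for i in rng.permutation(len(trees))]
        b = census(shuffled, SCHEME)
        for label in ("I", "II", "III"):
            assert a.counts[label].proportion == b.counts[label].proportion

    def test_trees_missing_outgroup_are_skipped(self):
        trees = [_tree("(out:1,(cm1:1,(mo1:1,eu1:1)100:1)100:1);"),
                 _tree("((cm1:1,mo1:1):1,eu1:1);")]
        result = census(trees, SCHEME)
        assert result.skipped == 1

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            census([], SCHEME)

    def test_concordant_type_dominates_and_minor_types_match_msc(self):
        """One species per focal group: every resolved gene tree is typed,
        so minor-type frequencies follow the (1/3) e^-t closed form."""
        t = 0.7
        net = SpeciesNetwork.from_newick(
            f"(((cm1:1,eu1:1):{t},mo1:{1 + t}):1,out:{2 + t});")
        n = 4000
        trees = simulate_msc_gene_trees(net, SimConfig(seed=8, n_trees=n))
        result = census(trees, SCHEME)
        minor = (1 / 3) * math.exp(-t)
        se = math.sqrt(minor * (1 - minor) / n)
        assert result.counts["II"].bs_pass > result.counts["I"].bs_pass
        for label in ("I", "III"):
            assert abs(result.counts[label].bs_pass / n - minor) < 3 * se


class TestChromosomeHomogeneity:
    def test_identical_distributions_give_zero_statistic(self):
        result = chromosome_homogeneity_test(
            {"I": ["c1"] * 5 + ["c2"] * 5, "II": ["c1"] * 5 + ["c2"] * 5})
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        result = chromosome_homogeneity_test(np.array([[10, 20], [20, 10]]))
        assert result.statistic == pytest.approx(6.6667, abs=1e-4)
        assert result.df == 1
        assert result.p_value == pytest.approx(0.009823, abs=1e-6)

    def test_all_zero_column_dropped_with_warning(self):
        table = np.array([[10, 20, 0], [20, 10, 0]])
        with pytest.warns(UserWarning, match="dropping"):
            result = chromosome_homogeneity_test(table)
        assert result.df == 1

    def test_single_category_is_error(self):
        with pytest.raises(ValueError):
            chromosome_homogeneity_test(np.array([[10], [20]]))
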