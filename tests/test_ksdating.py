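"""NG86 Ks, node weighting, UPGMA family trees, KDE peaks, age dating."""

import itertools
import math

import numpy as np
import pytest

from phyloconflict.errors import SaturationError
from phyloconflict.ksdating import (
    GeneFamily,
    MultimodalKsWarning,
    WeightedKsRecord,
    build_family_tree,
    ks_peak,
    molecular_age,
    ng86,
    weight_family,
)
from phyloconflict.simulate import SimConfig, simulate_ks_families

# ---------------------------------------------------------------------------
# independent NG86 oracle (structurally distinct re-implementation)
# ---------------------------------------------------------------------------

_BASES = "TCAG"


def _codon_table():
    aa = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
          "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
    table = {}
    for i, (b1, b2, b3) in enumerate(itertools.product(_BASES, repeat=3)):
        table[b1 + b2 + b3] = aa[i]
    return table


TABLE = _codon_table()
CODONS = [c for c in TABLE if TABLE[c] != "*"]


def oracle_sites(codon):
    syn = 0.0
    for pos, base in itertools.product(range(3), _BASES):
        alt = codon[:pos] + base + codon[pos + 1:]
        if alt != codon and TABLE[alt] == TABLE[codon] and TABLE[alt] != "*":
            syn += 1 / 3
    return syn


def oracle_diffs(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        codons = [c1]
        for pos in order:
            codons.append(codons[-1][:pos] + c2[pos] + codons[-1][pos + 1:])
        if all(TABLE[c] != "*" for c in codons[1:]):
            paths.append(codons)
    if not paths:
        for order in itertools.permutations(positions):
            codons = [c1]
            for pos in order:
                codons.append(
                    codons[-1][:pos] + c2[pos] + codons[-1][pos + 1:])
            paths.append(codons)
    sd = nd = 0.0
    for codons in paths:
        for before, after in zip(codons, codons[1:]):
            if TABLE[before] == TABLE[after]:
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths)


class TestNg86:
    def test_identical_sequences_give_zero(self):
        assert ng86("ATGGCT", "ATGGCT").ks == 0.0

    def test_fourfold_site_worked_example(self):
        result = ng86("GGTGGC", "GGCGGC")
        assert result.S == pytest.approx(2.0)
        assert result.Sd == pytest.approx(1.0)
        assert result.pS == pytest.approx(0.5)
        assert result.ks == pytest.approx(-0.75 * math.log(1 / 3), abs=1e-4)

    def test_saturation_guard(self):
        # alternating synonymous third positions everywhere
        s1 = "GGT" * 40
        s2 = "GGA" * 40
        with pytest.raises(SaturationError):
            ng86(s1, s2)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86("TAAGGT", "TGGGGT")

    def test_matches_pathway_oracle_on_all_codon_pairs(self):
        for c1, c2 in itertools.product(CODONS, repeat=2):
            exp_sd, exp_nd = oracle_diffs(c1, c2)
            exp_s = 0.5 * (oracle_sites(c1) + oracle_sites(c2)) + 1.0
            if exp_sd / exp_s >= 0.75:
                with pytest.raises(SaturationError):
                    ng86(c1 + "GGT", c2 + "GGT")
                continue
            got = ng86(c1 + "GGT", c2 + "GGT")  # pad to keep S > 0
            assert got.Sd == pytest.approx(exp_sd, abs=1e-10)
            assert got.Nd == pytest.approx(exp_nd, abs=1e-10)
            assert got.S == pytest.approx(exp_s, abs=1e-10)


# ---------------------------------------------------------------------------
# weighting
# ---------------------------------------------------------------------------

def _family(genes, ks, tree=None):
    table = {frozenset(p): v for p, v in ks.items()}
    return GeneFamily("fam", tuple(genes), table, tree=tree)


class TestWeightFamily:
    def test_pair_family_single_record(self):
        fam = _family("AB", {("A", "B"): 0.4}, tree=("A", "B"))
        (rec,) = weight_family(fam)
        assert rec.weight == 1.0
        assert rec.ks == 0.4

    def test_balanced_quartet_weights(self):
        ks = {("A", "B"): 0.2, ("C", "D"): 0.3, ("A", "C"): 1.0,
              ("A", "D"): 1.1, ("B", "C"): 0.9, ("B", "D"): 1.0}
        fam = _family("ABCD", ks, tree=(("A", "B"), ("C", "D")))
        records = weight_family(fam)
        assert len(records) == 6
        weights = sorted(r.weight for r in records)
        assert weights == pytest.approx([0.25] * 4 + [1.0, 1.0])
        assert sum(r.weight for r in records) == pytest.approx(3.0)

    def test_triple_weights(self):
        ks = {("A", "B"): 0.2, ("A", "C"): 0.9, ("B", "C"): 1.0}
        fam = _family("ABC", ks, tree=(("A", "B"), "C"))
        weights = sorted(r.weight for r in weight_family(fam))
        assert weights == pytest.approx([0.5, 0.5, 1.0])

    def test_missing_pair_named_in_error(self):
        fam = _family("ABC", {("A", "B"): 0.2, ("A", "C"): 0.9},
                      tree=(("A", "B"), "C"))
        with pytest.raises(KeyError, match="B.*C|C.*B"):
            weight_family(fam)

    def test_per_node_weights_sum_to_one_on_simulated_families(self):
        fams = simulate_ks_families(100, 0.9, 0.6, 0.1, SimConfig(seed=5))
        for fam in fams:
            records = weight_family(fam)
            n = fam.size
            assert len(records) == n * (n - 1) // 2
            by_node = {}
            for rec in records:
                by_node.setdefault(rec.node_id, 0.0)
                by_node[rec.node_id] += rec.weight
            for total in by_node.values():
                assert total == pytest.approx(1.0)
            assert sum(by_node.values()) == pytest.approx(n - 1)


class TestBuildFamilyTree:
    def test_closest_pair_joined_first(self):
        ks = {("A", "B"): 0.2, ("A", "C"): 0.9, ("B", "C"): 1.0}
        assert build_family_tree(_family("ABC", ks)) == (("A", "B"), "C")

    def test_ultrametric_matrix_recovered_exactly(self):
        ks = {("A", "B"): 0.2, ("C", "D"): 0.4, ("A", "C"): 1.0,
              ("A", "D"): 1.0, ("B", "C"): 1.0, ("B", "D"): 1.0}
        assert build_family_tree(_family("ABCD", ks)) == \
            (("A", "B"), ("C", "D"))

    def test_nan_distance_rejected(self):
        ks = {("A", "B"): float("nan"), ("A", "C"): 0.9, ("B", "C"): 1.0}
        with pytest.raises(ValueError, match="NaN"):
            build_family_tree(_family("ABC", ks))

    def test_near_ultrametric_matches_exhaustive_fit_oracle(self):
        """Random near-ultrametric 4x4 matrices: UPGMA equals the best
        least-squares ultrametric topology over all 15 rooted shapes."""
        rng = np.random.default_rng(3)
        genes = ["A", "B", "C", "D"]
        for _ in range(20):
            # build a random ultrametric tree, perturb slightly
            h1, h2, h3 = np.sort(rng.uniform(0.2, 2.0, 3))
            perm = rng.permutation(genes)
            true = ((tuple(sorted(perm[:2])), perm[2]), perm[3])
            d = {}
            p0, p1, p2, p3 = perm
            d[frozenset((p0, p1))] = h1
            for x in (p0, p1):
                d[frozenset((x, p2))] = h2
            for x in (p0, p1, p2):
                d[frozenset((x, p3))] = h3
            noisy = {k: v * (1 + rng.normal(0, 0.01)) for k, v in d.items()}
            fam = GeneFamily("f", tuple(sorted(genes)), noisy)
            tree = build_family_tree(fam)

            def leafset(node):
                if isinstance(node, str):
                    return frozenset([node])
                return frozenset().union(*map(leafset, node))

            def clades(node, acc):
                if isinstance(node, str):
                    return
                acc.append(leafset(node))
                for child in node:
                    clades(child, acc)

            got, expected = [], []
            clades(tree, got)
            clades(((tuple(sorted(perm[:2])), perm[2]), perm[3]), expected)
            assert set(got) == set(expected)


class TestKsPeakAndAges:
    def test_point_mass_mode(self):
        records = [WeightedKsRecord("f", "n", "a", "b", 0.9, 1.0)] * 20
        assert ks_peak(records).mode == pytest.approx(0.9)

    def test_mode_invariant_under_half_weight_duplication(self):
        """Weight linearity: duplicating every record at half weight leaves
        the weighted KDE unchanged (at a fixed bandwidth; automatic
        bandwidth selection depends on the effective sample size)."""
        rng = np.random.default_rng(6)
        records = [WeightedKsRecord("f", "n", "a", "b", v, 1.0)
                   for v in rng.lognormal(-0.1, 0.3, 400)]
        halved = [WeightedKsRecord(r.family_id, r.node_id, r.gene_i,
                                   r.gene_j, r.ks, 0.5)
                  for r in records for _ in range(2)]
        a = ks_peak(records, bandwidth=0.1)
        b = ks_peak(halved, bandwidth=0.1)
        assert a.mode == pytest.approx(b.mode)
        assert a.density == pytest.approx(b.density, rel=0.05)

    def test_two_cohorts_warn_multimodal(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([rng.normal(0.3, 0.02, 200),
                                 rng.normal(1.2, 0.02, 200)])
        records = [WeightedKsRecord("f", "n", "a", "b", v, 1.0)
                   for v in values]
        with pytest.warns(MultimodalKsWarning):
            peak = ks_peak(records, bandwidth=0.05)
        assert peak.multimodal

    def test_values_outside_interval_rejected(self):
        records = [WeightedKsRecord("f", "n", "a", "b", 3.5, 1.0)] * 5
        with pytest.raises(ValueError, match="interval"):
            ks_peak(records)

    def test_age_examples(self):
        assert molecular_age(0.0, 1.51e-9) == 0.0
        assert molecular_age(0.0302, 1.51e-9) == pytest.approx(1.0e7)
        with pytest.raises(ValueError):
            molecular_age(0.03, 0.0)
        with pytest.raises(ValueError):
            molecular_age(-0.1, 1.51e-9)
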