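"""Node-weighted Ks distributions, peak detection, and molecular age dating.

A gene family of n members yields n(n-1)/2 pairwise Ks estimates but only
n-1 retained duplication events.  To undo this redundancy, every duplication
node of the family tree contributes all m = |L|*|R| cross-pairs between its
child clades, each down-weighted to 1/m, so the weights at one node sum to
exactly 1 and a family contributes total weight n-1.  The mode of the
weighted distribution locates WGD cohorts; ages follow T = K / (2r) with r
in substitutions per synonymous site per year.

Pairwise Ks comes from a Nei-Gojobori (1986) counting estimator on codon
alignments (equal-weight pathway averaging for multi-hit codons, Jukes-
Cantor correction), with a saturation guard at pS >= 0.75.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .errors import FamilySizeError, SaturationError

__all__ = [
    "GeneFamily",
    "WeightedKsRecord",
    "NG86Result",
    "ng86",
    "ng86_ks",
    "weight_family",
    "build_family_tree",
    "ks_peak",
    "KsPeak",
    "molecular_age",
    "MultimodalKsWarning",
    "DEFAULT_RATE",
]

#: substitutions per synonymous site per year (magnoliid-calibrated default)
DEFAULT_RATE = 1.51e-9


class MultimodalKsWarning(UserWarning):
    """The weighted KDE has more than one local maximum in the interval."""


# ---------------------------------------------------------------------------
# gene families
# ---------------------------------------------------------------------------

FamilyTree = "str | tuple"  # nested tuples of gene ids, e.g. (("a","b"),"c")


@dataclass
class GeneFamily:
    """A low-copy paralog family (2 <= n <= 4 after the 1 < n < 5 filter).

    ``ks`` maps frozenset({gene_i, gene_j}) -> observed pairwise Ks.
    ``tree`` is a rooted binary topology over the members, written as nested
    tuples; when absent it can be rebuilt by :func:`build_family_tree`.
    ``true_ks`` (simulated families only) holds the noise-free values.
    """

    family_id: str
    genes: tuple[str, ...]
    ks: dict[frozenset, float]
    tree: object | None = None
    true_ks: dict[frozenset, float] | None = None

    def __post_init__(self):
        n = len(self.genes)
        if not 1 < n < 5:
            raise FamilySizeError(
                f"family {self.family_id!r} has {n} members; the low-copy "
                f"filter requires 1 < n < 5")
        for value in self.ks.values():
            if value < 0:
                raise ValueError("negative Ks value")

    @property
    def size(self) -> int:
        return len(self.genes)

    def pair_ks(self, a: str, b: str) -> float:
        try:
            return self.ks[frozenset((a, b))]
        except KeyError:
            raise KeyError(
                f"family {self.family_id!r} lacks a Ks value for the pair "
                f"({a!r}, {b!r})") from None


@dataclass(frozen=True)
class WeightedKsRecord:
    """One pairwise Ks estimate attached to a duplication node, weight 1/m."""

    family_id: str
    node_id: str
    gene_i: str
    gene_j: str
    ks: float
    weight: float


# ---------------------------------------------------------------------------
# NG86 counting Ks
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_CODON_TABLE = {}


def _build_codon_table():
    aa = ("FFLLSSSSYY**CC*W"
          "LLLLPPPPHHQQRRRR"
          "IIIMTTTTNNKKSSRR"
          "VVVVAAAADDEEGGGG")
    i = 0
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                _CODON_TABLE[b1 + b2 + b3] = aa[i]
                i += 1


_build_codon_table()


class NG86Result(NamedTuple):
    S: float     # synonymous sites (average of both sequences)
    N: float     # nonsynonymous sites
    Sd: float    # synonymous differences
    Nd: float    # nonsynonymous differences
    pS: float
    pN: float
    ks: float
    ka: float | None


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Changes producing stop codons count as nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if _CODON_TABLE[alt] == aa and _CODON_TABLE[alt] != "*":
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all pathways are used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _CODON_TABLE[nxt] == "*":
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked]
    if not usable:
        usable = [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in usable:
        for before, after in steps:
            if _CODON_TABLE[before] == _CODON_TABLE[after]:
                sd += 1.0
            else:
                nd += 1.0
    return sd / len(usable), nd / len(usable)


def ng86(seq1: str, seq2: str) -> NG86Result:
    """Nei-Gojobori (1986) synonymous/nonsynonymous divergence.

    Sequences must be aligned, gap-free, of equal length divisible by 3 and
    free of internal stop codons.  Codon columns containing ambiguity
    characters are skipped.
    """
    seq1, seq2 = seq1.upper().replace("U", "T"), seq2.upper().replace("U", "T")
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("sequence length not divisible by 3")
    s1 = s2 = sd = nd = 0.0
    n1 = n2 = 0.0
    n_codons = len(seq1) // 3
    for i in range(n_codons):
        c1, c2 = seq1[3 * i:3 * i + 3], seq2[3 * i:3 * i + 3]
        if any(b not in _BASES for b in c1 + c2):
            continue
        if _CODON_TABLE[c1] == "*" or _CODON_TABLE[c2] == "*":
            if i < n_codons - 1:
                raise ValueError(f"internal stop codon at codon {i + 1}")
            continue
        a_s, a_n = _codon_sites(c1)
        b_s, b_n = _codon_sites(c2)
        s1 += a_s; n1 += a_n
        s2 += b_s; n2 += b_n
        d_s, d_n = _codon_differences(c1, c2)
        sd += d_s; nd += d_n
    S = 0.5 * (s1 + s2)
    N = 0.5 * (n1 + n2)
    if S <= 0:
        raise ValueError("no synonymous sites in the alignment")
    pS = sd / S
    pN = nd / N if N > 0 else 0.0
    if pS >= 0.75:
        raise SaturationError(
            f"pS = {pS:.3f} >= 0.75; synonymous divergence is saturated")
    ks = -0.75 * math.log(1.0 - 4.0 * pS / 3.0)
    ka = (-0.75 * math.log(1.0 - 4.0 * pN / 3.0)) if pN < 0.75 else None
    return NG86Result(S, N, sd, nd, pS, pN, ks, ka)


def ng86_ks(seq1: str, seq2: str) -> float:
    """Pairwise Ks of an aligned codon pair (see :func:`ng86`)."""
    return ng86(seq1, seq2).ks


# ---------------------------------------------------------------------------
# family trees and node weighting
# ---------------------------------------------------------------------------

def build_family_tree(family: GeneFamily):
    """UPGMA tree on the pairwise Ks matrix, as nested tuples.

    Ties between cluster pairs break lexicographically on the sorted member
    names, so the result is deterministic.
    """
    clusters: list[tuple] = [(g,) for g in sorted(family.genes)]
    trees: list = [g for g in sorted(family.genes)]
    dist: dict[frozenset, float] = {}
    for a, b in itertools.combinations(range(len(clusters)), 2):
        value = family.pair_ks(clusters[a][0], clusters[b][0])
        if math.isnan(value):
            raise ValueError(
                f"NaN distance for pair ({clusters[a][0]}, {clusters[b][0]})")
        dist[frozenset((a, b))] = value

    ids = list(range(len(clusters)))
    members = {i: clusters[i] for i in ids}
    subtree = {i: trees[i] for i in ids}
    next_id = len(ids)
    while len(ids) > 1:
        best = None
        for a, b in itertools.combinations(sorted(ids), 2):
            d = dist[frozenset((a, b))]
            key = (d, tuple(sorted(members[a] + members[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        merged = tuple(sorted(members[a] + members[b]))
        new_tree = (subtree[a], subtree[b]) \
            if min(members[a]) <= min(members[b]) else (subtree[b], subtree[a])
        ids.remove(a); ids.remove(b)
        for c in ids:
            na, nb, nc = len(members[a]), len(members[b]), len(members[c])
            d = (na * dist[frozenset((a, c))] + nb * dist[frozenset((b, c))]) \
                / (na + nb)
            dist[frozenset((next_id, c))] = d
        members[next_id] = merged
        subtree[next_id] = new_tree
        ids.append(next_id)
        next_id += 1
    return subtree[ids[0]]


def _leafset(node) -> tuple[str, ...]:
    if isinstance(node, str):
        return (node,)
    out: tuple[str, ...] = ()
    for child in node:
        out += _leafset(child)
    return out


def weight_family(family: GeneFamily) -> list[WeightedKsRecord]:
    """Emit one 1/m-weighted record per cross-pair of each duplication node.

    A node with child clades L and R contributes the m = |L|*|R| pairwise Ks
    values between them, each with weight 1/m; a family of n members thus
    yields n(n-1)/2 records of total weight n-1.
    """
    tree = family.tree if family.tree is not None else build_family_tree(family)
    records: list[WeightedKsRecord] = []

    def visit(node, path: str) -> None:
        if isinstance(node, str):
            return
        left, right = node
        lset, rset = _leafset(left), _leafset(right)
        m = len(lset) * len(rset)
        for a in lset:
            for b in rset:
                records.append(WeightedKsRecord(
                    family_id=family.family_id, node_id=path,
                    gene_i=a, gene_j=b,
                    ks=family.pair_ks(a, b), weight=1.0 / m))
        visit(left, path + "L")
        visit(right, path + "R")

    visit(tree, "n")
    return records


# ---------------------------------------------------------------------------
# peak detection and dating
# ---------------------------------------------------------------------------

@dataclass
class KsPeak:
    mode: float
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    multimodal: bool


def ks_peak(records: Iterable[WeightedKsRecord],
            bandwidth: float | str | None = None,
            interval: tuple[float, float] = (0.05, 2.0),
            grid_step: float = 0.005) -> KsPeak:
    """Mode of the weighted Gaussian KDE of the Ks records.

    The KDE is fitted to all records (Silverman bandwidth by default, on the
    weighted sample) and the mode searched on a ``grid_step`` grid over the
    half-open ``interval``; the lower cut excludes the allelic/recent-
    duplicate spike near 0.  Emits :class:`MultimodalKsWarning` when the
    density has several local maxima.
    """
    records = list(records)
    values = np.array([r.ks for r in records])
    weights = np.array([r.weight for r in records])
    if len(values) == 0 or weights.sum() <= 0:
        raise ValueError("no weighted Ks records")
    lo, hi = interval
    if not np.any((values > lo) & (values <= hi)):
        raise ValueError(
            f"no Ks values inside the search interval ({lo}, {hi}]")
    if np.ptp(values) == 0:
        # point mass: KDE degenerate, mode is the common value
        grid = np.arange(lo + grid_step, hi + grid_step / 2, grid_step)
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - values[0]))] = 1.0
        return KsPeak(float(values[0]), grid, dens, 0.0, False)
    kde = gaussian_kde(values, weights=weights,
                       bw_method=bandwidth if bandwidth is not None
                       else "silverman")
    grid = np.arange(lo + grid_step, hi + grid_step / 2, grid_step)
    dens = kde(grid)
    mode = float(grid[int(np.argmax(dens))])
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
    multimodal = int(interior.sum()) > 1
    if multimodal:
        warnings.warn(
            "weighted Ks density has multiple local maxima; reporting the "
            "global mode", MultimodalKsWarning, stacklevel=2)
    return KsPeak(mode, grid, dens,
                  float(kde.factor * values.std(ddof=1)), multimodal)


def molecular_age(K: float, r: float = DEFAULT_RATE) -> float:
    """Age in years from a divergence K via T = K / (2 r).

    Used both for LTR insertion times (K = 5'/3' LTR divergence) and for
    WGD dating (K = Ks peak position); ``r`` is the substitution rate per
    site per year.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    if r <= 0:
        raise ValueError("substitution rate r must be positive")
    return K / (2.0 * r)
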