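"""ABBA-BABA D-statistic with block-jackknife standard errors.

For a quartet (((P1, P2), P3), O) with the outgroup carrying the ancestral
allele, a biallelic site is ABBA when (P1,P2,P3,O) = (A,B,B,A) and BABA when
(B,A,B,A).  Under ILS alone both patterns are equally likely;

    D = (nABBA - nBABA) / (nABBA + nBABA)

deviates from 0 under gene flow involving P3.  Uncertainty comes from a
delete-one block jackknife over genomic blocks and |Z| > 3 is the default
significance rule.  Counting operates on haploid 0/1 derived-allele codes
(one allele per taxon per site), the error-free equivalent of read-sampling
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import MissingSpeciesError, UndefinedStatisticError
from .network import SpeciesNetwork
from .simulate import SitePatternBlocks
from .trees import GeneTree

__all__ = [
    "DStatResult",
    "count_patterns",
    "d_statistic",
    "conformity_filter",
]


@dataclass(frozen=True)
class DStatResult:
    taxa: tuple[str, str, str, str]
    n_abba: int
    n_baba: int
    d: float
    se: float
    z: float
    significant: bool
    conforms_species_tree: bool | None = None


def count_patterns(genotypes: np.ndarray | Sequence[Sequence[int]],
                   block_size: int,
                   taxa: tuple[str, str, str, str] = ("P1", "P2", "P3", "O"),
                   ) -> SitePatternBlocks:
    """Count ABBA/BABA patterns from per-site derived-allele indicators.

    ``genotypes`` is (n_sites, 4) with 0 = ancestral, 1 = derived for
    (P1, P2, P3, O).  Sites where the outgroup carries the derived allele or
    any value is outside {0, 1} are skipped (they still occupy their block's
    site tally, mirroring a fixed-width genomic window).
    """
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[1] != 4:
        raise ValueError("genotypes must be an (n_sites, 4) array")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n_sites = g.shape[0]
    valid = np.isin(g, (0, 1)).all(axis=1) & (g[:, 3] == 0)
    abba = valid & (g[:, 0] == 0) & (g[:, 1] == 1) & (g[:, 2] == 1)
    baba = valid & (g[:, 0] == 1) & (g[:, 1] == 0) & (g[:, 2] == 1)

    n_blocks = int(np.ceil(n_sites / block_size))
    edges = np.arange(1, n_blocks + 1) * block_size
    edges[-1] = n_sites
    starts = np.concatenate([[0], edges[:-1]])
    n_abba = np.add.reduceat(abba.astype(np.int64), starts)
    n_baba = np.add.reduceat(baba.astype(np.int64), starts)
    sizes = edges - starts
    return SitePatternBlocks(taxa, n_abba, n_baba, sizes)


def d_statistic(blocks: SitePatternBlocks,
                z_threshold: float = 3.0) -> DStatResult:
    """D, block-jackknife SE and Z from per-block ABBA/BABA counts."""
    a = blocks.n_abba.astype(float)
    b = blocks.n_baba.astype(float)
    ta, tb = a.sum(), b.sum()
    if ta + tb == 0:
        raise UndefinedStatisticError(
            "no informative (ABBA or BABA) sites; D is undefined")
    if blocks.n_blocks < 2:
        raise UndefinedStatisticError("block jackknife requires >= 2 blocks")
    informative = (a + b) > 0
    if informative.sum() < 2:
        raise UndefinedStatisticError(
            "all informative sites fall in a single block; jackknife "
            "variance is undefined")
    d = (ta - tb) / (ta + tb)
    # delete-one estimates
    di = (ta - a - (tb - b)) / (ta - a + tb - b)
    m = blocks.n_blocks
    se = float(np.sqrt((m - 1) / m * np.sum((di - di.mean()) ** 2)))
    if se == 0:
        z = 0.0 if d == 0 else np.inf * np.sign(d)
    else:
        z = float(d / se)
    return DStatResult(blocks.taxa, int(ta), int(tb), float(d), se, z,
                       abs(z) > z_threshold)


def conformity_filter(quartet: tuple[str, str, str, str],
                      species_tree: GeneTree | SpeciesNetwork | str) -> bool:
    """True iff (((P1, P2), P3), O) matches the species-tree quartet.

    Results on non-conforming quartets are reported downstream but flagged
    excluded, mirroring the topology-conformity rule of clade-level D-tests.
    """
    p1, p2, p3, o = quartet
    tree = _as_tree(species_tree)
    missing = {p1, p2, p3, o} - tree.species_set()
    if missing:
        raise MissingSpeciesError(
            f"taxa absent from species tree: {sorted(missing)}")
    pruned = tree.prune_to_species({p1, p2, p3, o})
    sets = {tips for _, tips in _species_clades(pruned)}
    pair = frozenset((p1, p2))
    triple = frozenset((p1, p2, p3))
    return pair in sets and triple in sets


def _species_clades(tree: GeneTree):
    for node, tips in tree.clade_tip_sets():
        yield node, frozenset(tree.tip_species[t] for t in tips)


def _as_tree(species_tree) -> GeneTree:
    if isinstance(species_tree, GeneTree):
        return species_tree
    if isinstance(species_tree, SpeciesNetwork):
        return species_tree.to_gene_tree()
    if isinstance(species_tree, str):
        return SpeciesNetwork.from_newick(species_tree).to_gene_tree()
    raise TypeError(f"cannot interpret {type(species_tree)!r} as species tree")
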