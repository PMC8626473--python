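"""Simulation-based false-positive control for the hybridization tests.

Gene trees are simulated under a reticulation-free species tree (ILS as the
only source of discordance), the triplet mixture protocol (and optionally
the topology census) is re-run on each replicate, and the report summarizes
how often any species pair is spuriously flagged as hybridizing.  The
control passes when at least 90% of replicates are flag-free for the focal
pairs.  Under this null the two minor census types are equally frequent;
the report carries a binomial symmetry test of that prediction, whose
violation on real data is the signature of hybridization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .census import CensusResult, TypeDefinition, census, classify_tree
from .errors import NetworkError
from .network import SpeciesNetwork
from .simulate import SimConfig, simulate_msc_gene_trees, _sub_seed
from .trees import GeneTree, GroupScheme
from .triplet import ProtocolResult, run_protocol

__all__ = ["FPReplicate", "FPReport", "run_fp_control"]


@dataclass
class FPReplicate:
    index: int
    protocol: ProtocolResult
    flagged_focal_pairs: set[frozenset]
    census: CensusResult | None = None


@dataclass
class FPReport:
    replicates: list[FPReplicate]
    fraction_flag_free: float
    passed: bool
    minor_type_counts: tuple[int, int] | None = None
    minor_type_symmetry_p: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep in self.replicates:
            rows.append({
                "replicate": rep.index,
                "n_flagged_focal_pairs": len(rep.flagged_focal_pairs),
                "flagged_pairs": ";".join(
                    "-".join(sorted(p)) for p in sorted(
                        rep.flagged_focal_pairs, key=sorted)),
            })
        return pd.DataFrame(rows)


def run_fp_control(species_tree: SpeciesNetwork,
                   n_trees: int = 2329,
                   n_replicates: int = 10,
                   seed: int = 0,
                   n_runs: int = 10,
                   trees_per_run: int = 500,
                   triplet_species: Sequence[str] | None = None,
                   focal_pairs: Iterable[Iterable[str]] | None = None,
                   scheme: GroupScheme | None = None,
                   defs: TypeDefinition | None = None,
                   rate_threshold: float = 0.1) -> FPReport:
    """Run the ILS-only false-positive control.

    Per replicate: simulate ``n_trees`` MSC gene trees under the (strictly
    tree-shaped) ``species_tree``, run the triplet protocol, and record any
    hybridization flags among ``focal_pairs`` (default: every pair of
    ``triplet_species``).  When a :class:`GroupScheme` is supplied the
    topology census is also computed per replicate and the minor-type
    symmetry test added to the summary.
    """
    if not isinstance(species_tree, SpeciesNetwork):
        species_tree = SpeciesNetwork.from_newick(str(species_tree))
    if not species_tree.is_tree:
        raise NetworkError(
            "the false-positive control requires a species tree without "
            "reticulations")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    stree = species_tree.to_gene_tree()
    if focal_pairs is not None:
        focal = {frozenset(p) for p in focal_pairs}
    else:
        focal = None

    concordant_label = None
    if scheme is not None:
        defs = defs or TypeDefinition()
        concordant_label = classify_tree(
            _rooted_species_tree(stree, scheme), scheme, defs,
            support_threshold=0.0)

    replicates: list[FPReplicate] = []
    minor_counts = np.zeros(2, dtype=int)
    minor_labels: list[str] = []
    for rep in range(n_replicates):
        config = SimConfig(seed=_sub_seed(seed, "fp-replicate", rep),
                           n_trees=n_trees)
        trees = simulate_msc_gene_trees(species_tree, config)
        protocol = run_protocol(
            trees, stree, n_runs=n_runs,
            trees_per_run=min(trees_per_run, n_trees),
            seed=_sub_seed(seed, "fp-protocol", rep),
            triplet_species=triplet_species,
            rate_threshold=rate_threshold)
        flagged = protocol.flagged_pairs
        if focal is not None:
            flagged = {p for p in flagged if p in focal}
        cens = None
        if scheme is not None:
            cens = census(trees, scheme, defs)
            if concordant_label in ("I", "II", "III"):
                minor_labels = [l for l in ("I", "II", "III")
                                if l != concordant_label]
                minor_counts += np.array(
                    [cens.counts[minor_labels[0]].bs_pass,
                     cens.counts[minor_labels[1]].bs_pass])
        replicates.append(FPReplicate(rep, protocol, flagged, cens))

    n_free = sum(1 for r in replicates if not r.flagged_focal_pairs)
    fraction = n_free / n_replicates
    symmetry_p = None
    counts_out = None
    if scheme is not None and minor_counts.sum() > 0:
        symmetry_p = float(binomtest(int(minor_counts[0]),
                                     int(minor_counts.sum()), 0.5).pvalue)
        counts_out = (int(minor_counts[0]), int(minor_counts[1]))
    return FPReport(replicates, fraction, fraction >= 0.9,
                    counts_out, symmetry_p)


def _rooted_species_tree(stree: GeneTree, scheme: GroupScheme) -> GeneTree:
    from .trees import root_by_outgroup

    try:
        return root_by_outgroup(stree, scheme)
    except Exception:
        return stree
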