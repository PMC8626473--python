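"""Census of gene-tree topology types for three focal clades.

Each rooted gene tree is classified by which of three diagnostic clades it
contains, after restricting to the focal species (everything outside the
three groups and the outgroup is ignored):

* Type I   -- a clade of all G2+G3 species excluding G1 (G1 sister to the rest)
* Type II  -- a clade of all G1+G3 species excluding G2
* Type III -- a clade of all G1+G2 species excluding G3

with default groups G1 = Chloranthales+magnoliids, G2 = monocots,
G3 = eudicots.  The diagnostic clades are mutually exclusive on any tree, so
at most one type matches.  A bootstrap filter (default 70) applies to the
single branch subtending the diagnostic clade; group monophyly is reported
separately per type, never used as a gate.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import MissingSpeciesError, RootingError
from .trees import GeneTree, GroupScheme, root_by_outgroup

__all__ = [
    "TypeDefinition",
    "TypeCount",
    "CensusResult",
    "classify_tree",
    "census",
    "chromosome_homogeneity_test",
    "ChiSquareResult",
]

logger = logging.getLogger(__name__)

TYPE_LABELS = ("I", "II", "III")


@dataclass(frozen=True)
class TypeDefinition:
    """Names of the three focal groups in a :class:`GroupScheme`."""

    group1: str = "chloranthales_magnoliids"
    group2: str = "monocots"
    group3: str = "eudicots"

    def diagnostic_groups(self) -> dict[str, tuple[str, str]]:
        return {
            "I": (self.group2, self.group3),
            "II": (self.group1, self.group3),
            "III": (self.group1, self.group2),
        }

    @property
    def groups(self) -> tuple[str, str, str]:
        return (self.group1, self.group2, self.group3)


def classify_tree(tree: GeneTree,
                  scheme: GroupScheme,
                  defs: TypeDefinition | None = None,
                  support_threshold: float = 70.0) -> str:
    """Topology type of one rooted gene tree, or ``"other"``.

    The tree must be rooted (by outgroup) and contain at least one species
    of each focal group; species outside the focal groups are pruned before
    matching.  Returns the type whose diagnostic clade is present with
    subtending support >= ``support_threshold`` (edges without a support
    value pass), else ``"other"``.
    """
    defs = defs or TypeDefinition()
    present = tree.species_set()
    group_tips: dict[str, set[str]] = {g: set() for g in defs.groups}
    focal_species = set()
    for sp in present:
        g = scheme.group_of(sp)
        if g in group_tips:
            focal_species.add(sp)
    for g in defs.groups:
        if not any(scheme.group_of(sp) == g for sp in present):
            raise MissingSpeciesError(
                f"focal group {g!r} absent from tree {tree.tree_id!r}")

    pruned = tree.prune_to_species(focal_species)
    tips_by_group: dict[str, frozenset[str]] = {}
    for g in defs.groups:
        tips_by_group[g] = frozenset(
            t for t in pruned.leaf_labels()
            if scheme.group_of(pruned.tip_species[t]) == g)

    clades = pruned.clade_tip_sets()
    matched = []
    for label, (ga, gb) in defs.diagnostic_groups().items():
        target = tips_by_group[ga] | tips_by_group[gb]
        for node, tips in clades:
            if tips == target:
                matched.append((label, node.support))
                break
    assert len(matched) <= 1, "diagnostic clades must be mutually exclusive"
    if not matched:
        return "other"
    label, support = matched[0]
    if support is not None and support < support_threshold:
        return "other"
    return label


@dataclass
class TypeCount:
    raw: int = 0
    bs_pass: int = 0
    proportion: float = 0.0
    monophyly_fraction: float | None = None


@dataclass
class CensusResult:
    """Aggregated topology census.

    ``proportion`` is among support-passing typed trees; ``raw`` ignores the
    support filter.  ``monophyly_fraction`` is the per-type fraction of
    (support-passing) trees in which the designated species set is
    monophyletic.
    """

    counts: dict[str, TypeCount]
    other: int
    skipped: int
    total: int
    support_threshold: float
    labels: list[str] = field(default_factory=list)

    @property
    def n_typed(self) -> int:
        return sum(c.bs_pass for c in self.counts.values())

    @classmethod
    def from_counts(cls,
                    type_counts: Mapping[str, int],
                    monophyly_counts: Mapping[str, int] | None = None,
                    other: int = 0,
                    support_threshold: float = 70.0) -> "CensusResult":
        """Build a result directly from printed per-type counts."""
        typed = sum(type_counts.values())
        counts = {}
        for label, n in type_counts.items():
            frac = None
            if monophyly_counts and label in monophyly_counts:
                frac = monophyly_counts[label] / n if n else None
            counts[label] = TypeCount(
                raw=n, bs_pass=n,
                proportion=n / typed if typed else 0.0,
                monophyly_fraction=frac)
        return cls(counts, other, 0, typed + other, support_threshold)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, c in self.counts.items():
            rows.append({"type": label, "count": c.raw,
                         "count_bs_pass": c.bs_pass,
                         "proportion": c.proportion,
                         "monophyly_fraction": c.monophyly_fraction})
        rows.append({"type": "other", "count": self.other,
                     "count_bs_pass": self.other,
                     "proportion": np.nan, "monophyly_fraction": np.nan})
        return pd.DataFrame(rows)


def census(trees: Sequence[GeneTree],
           scheme: GroupScheme,
           defs: TypeDefinition | None = None,
           support_threshold: float = 70.0,
           monophyly_species: Iterable[str] | None = None,
           root_trees: bool = True) -> CensusResult:
    """Classify a batch of gene trees and aggregate type proportions.

    Trees missing the outgroup or a focal group are skipped with a logged
    warning (never an error in batch mode).  ``monophyly_species`` defaults
    to the species of group 1 (Chloranthales + magnoliids).
    """
    if not trees:
        raise ValueError("census requires at least one tree")
    defs = defs or TypeDefinition()
    if monophyly_species is None:
        monophyly_species = scheme.species_in(defs.group1)
    monophyly_species = set(monophyly_species)

    counts = {label: TypeCount() for label in TYPE_LABELS}
    mono_hits = Counter()
    other = skipped = 0
    labels: list[str] = []
    for tree in trees:
        try:
            rooted = root_by_outgroup(tree, scheme) if root_trees else tree
            raw_label = classify_tree(rooted, scheme, defs, support_threshold=0.0)
            bs_label = classify_tree(rooted, scheme, defs, support_threshold)
        except (RootingError, MissingSpeciesError) as exc:
            logger.warning("skipping tree %s: %s", tree.tree_id, exc)
            skipped += 1
            labels.append("skipped")
            continue
        if raw_label != "other":
            counts[raw_label].raw += 1
        if bs_label != "other":
            counts[bs_label].bs_pass += 1
            target = monophyly_species & rooted.species_set()
            if len(target) >= 2 and rooted.is_monophyletic(target):
                mono_hits[bs_label] += 1
        else:
            other += 1
        labels.append(bs_label)

    typed = sum(c.bs_pass for c in counts.values())
    for label, c in counts.items():
        c.proportion = c.bs_pass / typed if typed else 0.0
        c.monophyly_fraction = (mono_hits[label] / c.bs_pass
                                if c.bs_pass else None)
    return CensusResult(counts, other, skipped, len(trees),
                        support_threshold, labels)


class ChiSquareResult(NamedTuple):
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame


def chromosome_homogeneity_test(
        genes_by_type: Mapping[str, Sequence[str]] | pd.DataFrame | np.ndarray,
) -> ChiSquareResult:
    """Pearson chi-square homogeneity test of chromosome use across types.

    Accepts either a mapping type -> sequence of chromosome labels, or a
    ready-made contingency table (rows = types).  All-zero rows/columns are
    dropped with a warning; no continuity correction is applied.
    """
    if isinstance(genes_by_type, Mapping):
        rows = sorted(genes_by_type)
        cats = sorted({c for labels in genes_by_type.values() for c in labels})
        table = pd.DataFrame(0, index=rows, columns=cats)
        for t, labels in genes_by_type.items():
            for c, n in Counter(labels).items():
                table.loc[t, c] = n
    else:
        table = pd.DataFrame(genes_by_type)

    zero_cols = table.columns[(table.sum(axis=0) == 0)]
    zero_rows = table.index[(table.sum(axis=1) == 0)]
    if len(zero_cols) or len(zero_rows):
        warnings.warn(
            f"dropping empty categories (rows {list(zero_rows)}, "
            f"columns {list(zero_cols)})", UserWarning, stacklevel=2)
        table = table.drop(index=zero_rows, columns=zero_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            "homogeneity test needs >= 2 types and >= 2 chromosome categories")
    stat, p, df, _ = chi2_contingency(table.to_numpy(), correction=False)
    return ChiSquareResult(float(stat), int(df), float(p), table)
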