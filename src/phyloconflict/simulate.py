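"""Synthetic data generators for every pipeline stage.

Four generators, all seed-deterministic:

* multispecies-coalescent (MSC) gene trees on a species tree or network,
  with inheritance probabilities at reticulate nodes;
* unlinked biallelic site patterns for a 4-taxon (((P1,P2),P3),O) tree with
  an optional introgression pulse P3 -> P2 (infinite-sites, one derived
  mutation placed uniformly on each genealogy);
* paralog gene families carrying a WGD duplication cohort at a fixed true Ks
  plus a uniform small-scale-duplication background, with multiplicative
  lognormal noise;
* LTR 5'/3' divergences clustered around a burst value (truncated normal).

Time is measured in coalescent units (2N generations); ``mutation_scale``
converts simulated durations to emitted branch lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .errors import NetworkError
from .ksdating import GeneFamily
from .network import SpeciesNetwork
from .trees import GeneTree, TreeNode

__all__ = [
    "SimConfig",
    "SitePatternBlocks",
    "simulate_msc_gene_trees",
    "simulate_site_patterns",
    "simulate_ks_families",
    "simulate_ltr_divergences",
]


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation settings.

    ``support_value`` is the constant bootstrap support written on simulated
    internal edges (default 100, which keeps census support filters inert);
    set ``support_beta=(a, b)`` instead to draw supports as 100*Beta(a, b).
    """

    seed: int = 0
    n_trees: int = 1
    mutation_scale: float = 1.0
    support_value: float = 100.0
    support_beta: tuple[float, float] | None = None
    block_count: int = 200
    sites_per_block: int = 250
    samples_per_species: int = 1

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mutation_scale <= 0:
            raise ValueError("mutation_scale must be positive")
        if self.block_count < 1 or self.sites_per_block < 1:
            raise ValueError("block_count and sites_per_block must be >= 1")


def _sub_seed(seed: int, *names) -> int:
    """Deterministic sub-stream seed derived from a master seed (< 2**31)."""
    import hashlib

    digest = hashlib.sha256(
        ("|".join(str(n) for n in names)).encode()).digest()
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF,
         int.from_bytes(digest[:4], "big") & 0x7FFFFFFF])
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# MSC gene trees on a species tree / network
# ---------------------------------------------------------------------------

def simulate_msc_gene_trees(network: SpeciesNetwork,
                            config: SimConfig) -> list[GeneTree]:
    """Simulate ``config.n_trees`` gene trees under the network MSC.

    Within a branch carrying ``k`` lineages the waiting time to the next
    coalescence is Exponential with rate k(k-1)/2 (coalescent units) and a
    uniformly chosen pair merges; at a reticulate node each lineage follows
    a parent edge independently with its inheritance probability; all
    remaining lineages coalesce above the root.  Emitted branch lengths are
    durations multiplied by ``config.mutation_scale``.
    """
    nodes = network.nodes()
    if not any(n.is_leaf for n in nodes):
        raise NetworkError("network has no species")
    heights = network.heights()
    rng = np.random.default_rng(_sub_seed(config.seed, "msc-gene-trees"))
    k = config.samples_per_species
    scale = config.mutation_scale

    trees = []
    for i in range(config.n_trees):
        root_lineage = _simulate_one_gene_tree(nodes, heights, k, rng)
        _scale_lengths(root_lineage, scale)
        _assign_supports(root_lineage, config, rng)
        tip_species = {}
        for leaf in root_lineage.leaves():
            species = leaf.label.rsplit("|", 1)[0] if "|" in leaf.label else leaf.label
            tip_species[leaf.label] = species
        trees.append(GeneTree(root_lineage, tip_species, tree_id=f"sim_{i}",
                              validate=False))
    return trees


def _simulate_one_gene_tree(nodes, heights, samples_per_species, rng) -> TreeNode:
    edge_lineages: dict[int, list[tuple[TreeNode, float]]] = {}
    for node in nodes:
        if node.is_leaf:
            if samples_per_species == 1:
                incoming = [(TreeNode(node.name), 0.0)]
            else:
                incoming = [(TreeNode(f"{node.name}|{j}"), 0.0)
                            for j in range(samples_per_species)]
        else:
            incoming = []
            for e in node.child_edges:
                lin = edge_lineages.pop(id(e), [])
                incoming.extend(
                    _coalesce(lin, heights[id(e.child)], heights[id(node)], rng))
        if not node.parent_edges:  # root
            survivors = _coalesce(incoming, heights[id(node)], math.inf, rng)
            return survivors[0][0]
        if len(node.parent_edges) == 1:
            edge_lineages.setdefault(id(node.parent_edges[0]), []).extend(incoming)
        else:
            e0, e1 = node.parent_edges
            for lineage in incoming:
                # degenerate gamma routes deterministically without an RNG
                # draw, so a gamma = 1 network reproduces the pruned tree
                if e0.gamma >= 1.0:
                    target = e0
                elif e0.gamma <= 0.0:
                    target = e1
                else:
                    target = e0 if rng.random() < e0.gamma else e1
                edge_lineages.setdefault(id(target), []).append(lineage)
    raise AssertionError("network traversal ended without reaching a root")


def _coalesce(lineages, t_start, t_end, rng):
    lineages = list(lineages)
    t = t_start
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        if t >= t_end:
            break
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, ta = lineages[i]
        b, tb = lineages[j]
        parent = TreeNode()
        parent.add(a)
        a.length = t - ta
        parent.add(b)
        b.length = t - tb
        merged = (parent, t)
        keep = [lineages[x] for x in range(k) if x not in (i, j)]
        keep.append(merged)
        lineages = keep
    return lineages


def _scale_lengths(root: TreeNode, scale: float) -> None:
    if scale == 1.0:
        return
    for node in root.postorder():
        if node is not root:
            node.length *= scale


def _assign_supports(root: TreeNode, config: SimConfig, rng) -> None:
    for node in root.postorder():
        if node.is_leaf or node is root:
            continue
        if config.support_beta is not None:
            a, b = config.support_beta
            node.support = 100.0 * rng.beta(a, b)
        else:
            node.support = config.support_value


# ---------------------------------------------------------------------------
# 4-taxon site patterns (ABBA/BABA input)
# ---------------------------------------------------------------------------

@dataclass
class SitePatternBlocks:
    """Per-block ABBA/BABA counts for a fixed (P1, P2, P3, O) quartet."""

    taxa: tuple[str, str, str, str]
    n_abba: np.ndarray
    n_baba: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self):
        self.n_abba = np.asarray(self.n_abba, dtype=np.int64)
        self.n_baba = np.asarray(self.n_baba, dtype=np.int64)
        self.n_sites = np.asarray(self.n_sites, dtype=np.int64)
        if not (len(self.n_abba) == len(self.n_baba) == len(self.n_sites)):
            raise ValueError("block arrays must have equal length")
        if np.any(self.n_abba + self.n_baba > self.n_sites):
            raise ValueError("informative counts exceed sites in a block")

    @property
    def n_blocks(self) -> int:
        return len(self.n_abba)


@njit(cache=True)
def _quartet_phase(mask, pop, birth, n, t, t_end, acc):
    """Coalesce lineages of equal pop over [t, t_end); acc = (T23, T13, Ttot)."""
    while True:
        c0 = c1 = c2 = c3 = 0
        for i in range(n):
            p = pop[i]
            if p == 0:
                c0 += 1
            elif p == 1:
                c1 += 1
            elif p == 2:
                c2 += 1
            else:
                c3 += 1
        r0 = 0.5 * c0 * (c0 - 1)
        r1 = 0.5 * c1 * (c1 - 1)
        r2 = 0.5 * c2 * (c2 - 1)
        r3 = 0.5 * c3 * (c3 - 1)
        rate = r0 + r1 + r2 + r3
        if rate <= 0.0:
            break
        t += np.random.exponential(1.0 / rate)
        if t >= t_end:
            break
        u = np.random.random() * rate
        if u < r0:
            q = 0
        elif u < r0 + r1:
            q = 1
        elif u < r0 + r1 + r2:
            q = 2
        else:
            q = 3
        # pick two distinct lineages in pop q
        cnt = 0
        for i in range(n):
            if pop[i] == q:
                cnt += 1
        a = np.random.randint(cnt)
        b = np.random.randint(cnt - 1)
        if b >= a:
            b += 1
        i1 = -1
        i2 = -1
        seen = 0
        for i in range(n):
            if pop[i] == q:
                if seen == a:
                    i1 = i
                if seen == b:
                    i2 = i
                seen += 1
        acc[2] += (t - birth[i1]) + (t - birth[i2])
        if mask[i1] == 6:
            acc[0] += t - birth[i1]
        elif mask[i1] == 5:
            acc[1] += t - birth[i1]
        if mask[i2] == 6:
            acc[0] += t - birth[i2]
        elif mask[i2] == 5:
            acc[1] += t - birth[i2]
        mask[i1] |= mask[i2]
        birth[i1] = t
        mask[i2] = mask[n - 1]
        pop[i2] = pop[n - 1]
        birth[i2] = birth[n - 1]
        n -= 1
    return n, t_end


@njit(cache=True)
def _quartet_site_codes(n_sites, gamma, h1, h2, h3, h_gf, seed):
    """Per-site pattern codes: 0 uninformative, 1 ABBA, 2 BABA.

    Leaf bitmasks: P1=1, P2=2, P3=4, O=8; the branch subtending {P2,P3}
    (mask 6) yields ABBA, {P1,P3} (mask 5) yields BABA.
    """
    np.random.seed(seed)
    codes = np.zeros(n_sites, dtype=np.int8)
    mask = np.empty(4, dtype=np.int64)
    pop = np.empty(4, dtype=np.int64)
    birth = np.empty(4, dtype=np.float64)
    acc = np.empty(3, dtype=np.float64)
    for s in range(n_sites):
        mask[0] = 1; mask[1] = 2; mask[2] = 4; mask[3] = 8
        pop[0] = 0; pop[1] = 1; pop[2] = 2; pop[3] = 3
        birth[0] = 0.0; birth[1] = 0.0; birth[2] = 0.0; birth[3] = 0.0
        acc[0] = 0.0; acc[1] = 0.0; acc[2] = 0.0
        n = 4
        if gamma > 0.0 and np.random.random() < gamma:
            for i in range(n):
                if mask[i] == 2:
                    pop[i] = 2
            n, _ = _quartet_phase(mask, pop, birth, n, h_gf, h1, acc)
        for i in range(n):
            if pop[i] == 1:
                pop[i] = 0
        n, _ = _quartet_phase(mask, pop, birth, n, h1, h2, acc)
        for i in range(n):
            if pop[i] == 2:
                pop[i] = 0
        n, _ = _quartet_phase(mask, pop, birth, n, h2, h3, acc)
        for i in range(n):
            pop[i] = 0
        n, _ = _quartet_phase(mask, pop, birth, n, h3, np.inf, acc)
        u = np.random.random() * acc[2]
        if u < acc[0]:
            codes[s] = 1
        elif u < acc[0] + acc[1]:
            codes[s] = 2
    return codes


def simulate_site_patterns(tree4: SpeciesNetwork | GeneTree | str,
                           gamma: float,
                           config: SimConfig,
                           taxa: tuple[str, str, str, str] | None = None,
                           introgression_time: float | None = None,
                           ) -> SitePatternBlocks:
    """Simulate unlinked biallelic sites on a 4-taxon species tree.

    Each site draws an independent genealogy under the MSC; with probability
    ``gamma`` the P2 lineage follows the introgression edge into P3's branch
    at ``introgression_time`` (default: half the P1-P2 split height).  One
    derived mutation is placed uniformly on the genealogy and ABBA / BABA
    patterns are counted per block.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError(f"gamma {gamma} outside [0, 1]")
    tree = _as_species_tree(tree4)
    if tree.n_tips() != 4:
        raise ValueError("site-pattern simulation requires exactly 4 taxa")
    p1, p2, p3, o = taxa if taxa is not None else _infer_quartet_order(tree)
    depths = tree.depths()
    tip_height = max(depths[l] for l in tree.leaves())
    h = {}
    for pair in ((p1, p2), (p1, p3), (p1, o)):
        node = tree.mrca([_tip_of(tree, pair[0]), _tip_of(tree, pair[1])])
        h[pair] = tip_height - depths[node]
    h1, h2, h3 = h[(p1, p2)], h[(p1, p3)], h[(p1, o)]
    if not (h1 < h2 < h3):
        raise ValueError(
            "species tree heights do not satisfy (((P1,P2),P3),O)")
    h_gf = introgression_time if introgression_time is not None else 0.5 * h1
    if not (0.0 <= h_gf < h1):
        raise ValueError("introgression time must lie below the P1-P2 split")

    n_sites = config.block_count * config.sites_per_block
    seed = _sub_seed(config.seed, "site-patterns")
    codes = _quartet_site_codes(n_sites, float(gamma), float(h1), float(h2),
                                float(h3), float(h_gf), seed)
    codes = codes.reshape(config.block_count, config.sites_per_block)
    return SitePatternBlocks(
        taxa=(p1, p2, p3, o),
        n_abba=(codes == 1).sum(axis=1),
        n_baba=(codes == 2).sum(axis=1),
        n_sites=np.full(config.block_count, config.sites_per_block),
    )


def _as_species_tree(tree) -> GeneTree:
    if isinstance(tree, GeneTree):
        return tree
    if isinstance(tree, SpeciesNetwork):
        return tree.to_gene_tree()
    if isinstance(tree, str):
        return SpeciesNetwork.from_newick(tree).to_gene_tree()
    raise TypeError(f"cannot interpret {type(tree)!r} as a species tree")


def _tip_of(tree: GeneTree, species: str) -> str:
    for label, sp in tree.tip_species.items():
        if sp == species:
            return label
    raise ValueError(f"species {species!r} not in tree")


def _infer_quartet_order(tree: GeneTree) -> tuple[str, str, str, str]:
    """Read (P1, P2, P3, O) off a caterpillar (((P1,P2),P3),O) topology."""
    depths = tree.depths()
    labels = tree.leaf_labels()
    cherry = None
    for node, tips in tree.clade_tip_sets():
        if len(tips) == 2:
            if cherry is None or depths[node] > depths[cherry[0]]:
                cherry = (node, tips)
    if cherry is None:
        raise ValueError("cannot infer quartet order; pass taxa explicitly")
    p1, p2 = sorted(cherry[1])
    triple = next(tips for _, tips in tree.clade_tip_sets() if len(tips) == 3)
    (p3,) = triple - cherry[1]
    (o,) = set(labels) - triple
    sp = tree.tip_species
    return sp[p1], sp[p2], sp[p3], sp[o]


# ---------------------------------------------------------------------------
# Ks gene families with a WGD cohort
# ---------------------------------------------------------------------------

_FAMILY_SIZE_PROBS = {2: 0.5, 3: 0.3, 4: 0.2}


def simulate_ks_families(n_families: int,
                         wgd_ks: float,
                         wgd_fraction: float,
                         noise_sigma: float,
                         config: SimConfig) -> list[GeneFamily]:
    """Simulate paralog families with a WGD cohort in their Ks values.

    Family sizes are drawn from {2, 3, 4} (inside the low-copy 1 < n < 5
    filter) with probabilities (0.5, 0.3, 0.2).  Each duplication node is
    WGD-derived with probability ``wgd_fraction`` (true Ks = ``wgd_ks``) or
    background (true Ks ~ Uniform(0.05, 2)); node ages are sorted so deeper
    nodes carry larger Ks.  Observed pairwise Ks multiply the true value by
    LogNormal(0, ``noise_sigma``) noise.  Families keep their true trees so
    downstream weighting can be checked against the generating process.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if wgd_ks <= 0:
        raise ValueError("wgd_ks must be positive")
    if not (0.0 <= wgd_fraction <= 1.0):
        raise ValueError("wgd_fraction outside [0, 1]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(_sub_seed(config.seed, "ks-families"))
    sizes = rng.choice(list(_FAMILY_SIZE_PROBS), size=n_families,
                       p=list(_FAMILY_SIZE_PROBS.values()))
    families = []
    for f, n in enumerate(sizes):
        genes = [f"fam{f}_g{i}" for i in range(n)]
        # random rooted topology by sequential pair merging; creation order
        # is child-before-parent, so sorted ages stay monotone along paths
        active: list = list(genes)
        node_order = []
        while len(active) > 1:
            i, j = sorted(rng.choice(len(active), size=2, replace=False))
            merged = (active[i], active[j])
            node_order.append(merged)
            active = [active[x] for x in range(len(active)) if x not in (i, j)]
            active.append(merged)
        tree = active[0] if n > 1 else genes[0]

        is_wgd = rng.random(n - 1) < wgd_fraction
        raw = np.where(is_wgd, wgd_ks, rng.uniform(0.05, 2.0, size=n - 1))
        ages = np.sort(raw)
        node_age = {node: ages[i] for i, node in enumerate(node_order)}

        true_ks: dict[frozenset, float] = {}
        obs_ks: dict[frozenset, float] = {}
        members: dict = {g: frozenset([g]) for g in genes}
        for node in node_order:
            left, right = node
            lset, rset = _tips_of(left), _tips_of(right)
            members[node] = lset | rset
            for a in lset:
                for b in rset:
                    pair = frozenset((a, b))
                    true_ks[pair] = node_age[node]
                    noise = math.exp(rng.normal(0.0, noise_sigma)) \
                        if noise_sigma > 0 else 1.0
                    obs_ks[pair] = node_age[node] * noise
        families.append(GeneFamily(
            family_id=f"fam{f}", genes=tuple(genes), ks=obs_ks,
            tree=tree, true_ks=true_ks))
    return families


def _tips_of(node) -> frozenset:
    if isinstance(node, str):
        return frozenset([node])
    out = frozenset()
    for child in node:
        out |= _tips_of(child)
    return out


# ---------------------------------------------------------------------------
# LTR divergences
# ---------------------------------------------------------------------------

def simulate_ltr_divergences(n: int, burst_k: float, sd: float,
                             seed: int = 0) -> np.ndarray:
    """Draw LTR 5'/3' divergences ~ Normal(burst_k, sd) truncated at 0."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if burst_k <= 0:
        raise ValueError("burst_k must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(_sub_seed(seed, "ltr"))
    if sd == 0:
        return np.full(n, float(burst_k))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(burst_k, sd, size=n - filled)
        draw = draw[draw >= 0]
        out[filled:filled + len(draw)] = draw
        filled += len(draw)
    return out
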