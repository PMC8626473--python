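"""Triplet internal-branch-length mixture test for ILS vs hybridization.

Under the multispecies coalescent, the internal branch of a *discordant*
rooted triplet extracted from a gene tree is exponentially distributed; a
hybridization pulse adds a second, shifted cohort.  For each triplet and
observed topology the test compares

* a one-component model  f1(t) = (1/lam) exp(-t/lam), and
* a two-component model  pi (1/lam) exp(-(t-K)/lam) [t >= K]
                         + (1-pi) (1/lam) exp(-t/lam)

(shared rate, shift K >= 0, pi the weight of the non-ILS component), fitted
by EM with K profiled on a grid, and calls "mixture" when
DeltaBIC = BIC1 - BIC2 > 10.  A protocol of repeated subsampling runs
aggregates calls into per-species-pair hybridization rates.

A useful structural fact exploited here: for t >= K the likelihood ratio of
the two components is the constant exp(K/lam), so the E-step collapses to
prefix sums and each EM iteration costs O(1) per (K, start) after sorting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    MissingSpeciesError,
)
from .network import SpeciesNetwork
from .trees import GeneTree, TreeNode

__all__ = [
    "TripletObservation",
    "TripletExtraction",
    "MixtureFit",
    "extract_triplets",
    "fit_mixture",
    "run_protocol",
    "ProtocolResult",
]

_TINY = 1e-300


@dataclass(frozen=True)
class TripletObservation:
    """One gene tree restricted to a species triplet."""

    species: tuple[str, str, str]   # sorted
    odd: str                        # the species outside the cherry
    t: float                        # internal branch length (>= 0)
    tree_id: str | None = None


class TripletExtraction(NamedTuple):
    observations: list[TripletObservation]
    n_skipped: int


@dataclass(frozen=True)
class MixtureFit:
    """One-component vs two-component exponential fit for one topology."""

    n: int
    lambda1: float
    loglik1: float
    pi: float
    lambda2: float
    shift: float
    loglik2: float
    bic1: float
    bic2: float
    delta_bic: float
    call: str                       # "mixture" or "ILS-only"

    @property
    def ils_hybridization_ratio(self) -> float:
        """(1 - pi) / pi; infinite when the non-ILS weight is zero."""
        return (1.0 - self.pi) / self.pi if self.pi > 0 else np.inf


# ---------------------------------------------------------------------------
# triplet extraction
# ---------------------------------------------------------------------------

def _representatives(tree: GeneTree, species: Sequence[str]) -> dict[str, str]:
    """One tip per species; multi-copy species take the copy with the
    smallest total nodal distance to the other species' tips."""
    by_species: dict[str, list[str]] = {}
    for label in tree.leaf_labels():
        sp = tree.tip_species[label]
        if sp in species:
            by_species.setdefault(sp, []).append(label)
    reps: dict[str, str] = {}
    multi = [sp for sp, tips in by_species.items() if len(tips) > 1]
    if not multi:
        return {sp: tips[0] for sp, tips in by_species.items()}

    # nodal distances via depths in edge counts
    edge_depth: dict[int, int] = {id(tree.root): 0}
    for node in tree.root.preorder():
        for child in node.children:
            edge_depth[id(child)] = edge_depth[id(node)] + 1
    ancestors: dict[str, dict[int, int]] = {}
    for leaf in tree.leaves():
        path = {}
        node: TreeNode | None = leaf
        while node is not None:
            path[id(node)] = edge_depth[id(node)]
            node = node.parent
        ancestors[leaf.label] = path

    def dist(a: str, b: str) -> int:
        pa, pb = ancestors[a], ancestors[b]
        common = max(d for i, d in pa.items() if i in pb)
        return (pa[id_leaf[a]] - common) + (pb[id_leaf[b]] - common)

    id_leaf = {leaf.label: id(leaf) for leaf in tree.leaves()}
    others_tips = {sp: [t for osp, tips in by_species.items() if osp != sp
                        for t in tips] for sp in by_species}
    for sp, tips in by_species.items():
        if len(tips) == 1:
            reps[sp] = tips[0]
        else:
            reps[sp] = min(tips, key=lambda t: (
                sum(dist(t, o) for o in others_tips[sp]), t))
    return reps


def _mrca_depth_matrix(tree: GeneTree, species: Sequence[str]) -> np.ndarray:
    """(S, S) matrix of MRCA depths (branch length from root) between the
    species representatives; NaN where a species is absent."""
    S = len(species)
    out = np.full((S, S), np.nan)
    reps = _representatives(tree, species)
    depths = tree.depths()
    paths: dict[str, dict[int, float]] = {}
    for sp, tip_label in reps.items():
        leaf = next(l for l in tree.leaves() if l.label == tip_label)
        path = {}
        node: TreeNode | None = leaf
        while node is not None:
            path[id(node)] = depths[node]
            node = node.parent
        paths[sp] = path
    for i, a in enumerate(species):
        if a not in reps:
            continue
        out[i, i] = 0.0
        for j in range(i + 1, S):
            b = species[j]
            if b not in reps:
                continue
            common = max(d for nid, d in paths[a].items()
                         if nid in paths[b])
            out[i, j] = out[j, i] = common
    return out


def extract_triplets(trees: Sequence[GeneTree],
                     species_triplets: Iterable[Sequence[str]],
                     ) -> TripletExtraction:
    """Restrict each tree to each requested triplet.

    For each tree x triplet, records which species is the "odd one out" and
    the internal branch length of the restricted triplet (0 for effectively
    unresolved triplets).  Observations whose species are absent from a tree
    are skipped and counted.
    """
    triplets = [tuple(sorted(t)) for t in species_triplets]
    species = sorted({sp for t in triplets for sp in t})
    index = {sp: i for i, sp in enumerate(species)}
    observations: list[TripletObservation] = []
    skipped = 0
    for tree in trees:
        mat = _mrca_depth_matrix(tree, species)
        for trip in triplets:
            obs = _classify_triplet(mat, trip, index, tree.tree_id)
            if obs is None:
                skipped += 1
            else:
                observations.append(obs)
    return TripletExtraction(observations, skipped)


def _classify_triplet(mat, trip, index, tree_id):
    a, b, c = trip
    ia, ib, ic = index[a], index[b], index[c]
    d = (mat[ia, ib], mat[ia, ic], mat[ib, ic])
    if any(np.isnan(x) for x in d):
        return None
    odd_of = (c, b, a)  # pair orders: (a,b), (a,c), (b,c)
    top = int(np.argmax(d))
    t = float(max(d) - min(d))
    return TripletObservation(trip, odd_of[top], t, tree_id)


# ---------------------------------------------------------------------------
# mixture fitting
# ---------------------------------------------------------------------------

def fit_mixture(ts: Sequence[float],
                min_obs: int = 20,
                k_grid: int = 200,
                n_starts: int = 5,
                tol: float = 1e-8,
                max_iter: int = 500,
                delta_bic_threshold: float = 10.0) -> MixtureFit:
    """Fit the one- and two-component branch-length models to one topology.

    K is profiled on a ``k_grid``-point grid from 0 to the 99th percentile
    of the data, with EM on (pi, lambda) at each K from ``n_starts`` spread
    initializations; the grid includes K = 0, where the mixture collapses to
    the exponential, so loglik2 >= loglik1 always holds.
    """
    t = np.sort(np.asarray(ts, dtype=float))
    n = len(t)
    if n < min_obs:
        raise InsufficientDataError(
            f"insufficient observations ({n} < {min_obs})")
    if np.any(t < 0):
        raise ValueError("negative internal branch length")
    total = float(t.sum())
    if total == 0:
        raise DegenerateDataError("all internal branch lengths are zero")

    lam1 = total / n
    ll1 = -n * (np.log(lam1) + 1.0)

    kmax = float(np.quantile(t, 0.99))
    ks = np.linspace(0.0, kmax, k_grid)
    idx = np.searchsorted(t, ks, side="left")     # count of t < K
    cnt_low = idx.astype(float)
    cnt_high = (n - idx).astype(float)

    starts = np.linspace(0.1, 0.9, n_starts)
    pi = np.tile(starts[:, None], (1, k_grid))
    lam = np.full_like(pi, lam1)
    K = np.broadcast_to(ks, pi.shape)
    cl = np.broadcast_to(cnt_low, pi.shape)
    ch = np.broadcast_to(cnt_high, pi.shape)

    ll_prev = np.full_like(pi, -np.inf)
    active = np.ones(pi.shape, dtype=bool)
    for _ in range(max_iter):
        lam = np.maximum(lam, 1e-12)
        w = np.exp(np.minimum(K / lam, 700.0))
        denom = pi * w + (1.0 - pi)
        ll = (cl * np.log(np.maximum(1.0 - pi, _TINY))
              + np.where(ch > 0, ch * np.log(np.maximum(denom, _TINY)), 0.0)
              - n * np.log(lam) - total / lam)
        r = np.where(denom > 0, pi * w / np.maximum(denom, _TINY), 0.0)
        sum_r = ch * r
        pi = sum_r / n
        lam = np.maximum((total - K * sum_r) / n, 1e-12)
        done = np.abs(ll - ll_prev) <= tol * (np.abs(ll) + 1.0)
        active &= ~done
        ll_prev = ll
        if not active.any():
            break

    best = np.unravel_index(int(np.nanargmax(ll_prev)), ll_prev.shape)
    ll2 = float(ll_prev[best])
    if ll2 < ll1 - 1e-9:  # cannot happen (K = 0 column); defensive
        ll2 = ll1
        pi_hat, lam2, k_hat = 0.0, lam1, 0.0
    else:
        pi_hat = float(pi[best])
        lam2 = float(lam[best])
        k_hat = float(ks[best[1]])
    bic1 = -2.0 * ll1 + 1.0 * np.log(n)
    bic2 = -2.0 * ll2 + 3.0 * np.log(n)
    delta = bic1 - bic2
    call = "mixture" if delta > delta_bic_threshold else "ILS-only"
    return MixtureFit(n, lam1, float(ll1), pi_hat, lam2, k_hat, ll2,
                      float(bic1), float(bic2), float(delta), call)


# ---------------------------------------------------------------------------
# resampling protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolResult:
    """Aggregated output of the subsampling protocol.

    ``pair_table`` has one row per species pair united by a discordant
    topology: the mean non-ILS rate (pi-hat when called, 0 otherwise), the
    fraction of fits called "mixture", the mean ILS/hybridization ratio of
    called fits, and the hybridization flag (rate > threshold).
    """

    pair_table: pd.DataFrame
    triplet_table: pd.DataFrame
    n_runs: int
    trees_per_run: int
    rate_threshold: float

    @property
    def flagged_pairs(self) -> set[frozenset]:
        flagged = self.pair_table[self.pair_table["flagged"]]
        return {frozenset((row.pair_a, row.pair_b))
                for row in flagged.itertuples()}


def run_protocol(trees: Sequence[GeneTree],
                 species_tree: GeneTree | SpeciesNetwork | str,
                 n_runs: int = 100,
                 trees_per_run: int = 500,
                 seed: int = 0,
                 triplet_species: Sequence[str] | None = None,
                 min_obs: int = 20,
                 k_grid: int = 200,
                 delta_bic_threshold: float = 10.0,
                 rate_threshold: float = 0.1) -> ProtocolResult:
    """Repeated-subsampling triplet testing with per-pair aggregation.

    Each run samples ``trees_per_run`` trees without replacement (sub-seeded
    from ``seed``), extracts all triplets of ``triplet_species`` (default:
    every species of the species tree), fits the mixture to each *discordant*
    topology with enough observations, and aggregates per species pair.
    """
    from .simulate import _sub_seed  # local import to avoid a cycle

    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if trees_per_run > len(trees):
        raise InsufficientDataError(
            f"trees_per_run ({trees_per_run}) exceeds available trees "
            f"({len(trees)})")
    stree = _as_tree(species_tree)
    species = sorted(triplet_species) if triplet_species is not None \
        else sorted(stree.species_set())
    missing = set(species) - stree.species_set()
    if missing:
        raise MissingSpeciesError(
            f"species absent from species tree: {sorted(missing)}")
    index = {sp: i for i, sp in enumerate(species)}
    smat = _mrca_depth_matrix(stree, species)

    # per-tree depth matrices, computed once
    mats = np.stack([_mrca_depth_matrix(tree, species) for tree in trees])

    triplets = list(itertools.combinations(species, 3))
    concordant_odd = {}
    for trip in triplets:
        obs = _classify_triplet(smat, trip, index, None)
        if obs is None:
            raise MissingSpeciesError(
                f"species tree does not resolve triplet {trip}")
        concordant_odd[trip] = obs.odd

    rng = np.random.default_rng(_sub_seed(seed, "triplet-protocol"))
    pair_entries: dict[frozenset, list[MixtureFit]] = {}
    triplet_rows = []
    for run in range(n_runs):
        chosen = rng.choice(len(trees), size=trees_per_run, replace=False)
        sub = mats[chosen]
        for trip in triplets:
            a, b, c = trip
            ia, ib, ic = index[a], index[b], index[c]
            vals = np.stack([sub[:, ia, ib], sub[:, ia, ic],
                             sub[:, ib, ic]], axis=1)
            ok = ~np.isnan(vals).any(axis=1)
            vals = vals[ok]
            if not len(vals):
                continue
            top = np.argmax(vals, axis=1)
            t_all = vals.max(axis=1) - vals.min(axis=1)
            odd_of = (c, b, a)
            pair_of = ((a, b), (a, c), (b, c))
            for topo in range(3):
                odd = odd_of[topo]
                if odd == concordant_odd[trip]:
                    continue  # concordant topology: not a hybridization probe
                ts = t_all[top == topo]
                if len(ts) < min_obs:
                    continue
                try:
                    fit = fit_mixture(ts, min_obs=min_obs, k_grid=k_grid,
                                      delta_bic_threshold=delta_bic_threshold)
                except DegenerateDataError:
                    continue
                pair = frozenset(pair_of[topo])
                pair_entries.setdefault(pair, []).append(fit)
                triplet_rows.append({
                    "run": run, "triplet": "|".join(trip), "odd": odd,
                    "n": fit.n, "pi": fit.pi, "lambda": fit.lambda2,
                    "shift": fit.shift, "delta_bic": fit.delta_bic,
                    "call": fit.call})

    pair_rows = []
    for pair, fits in sorted(pair_entries.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        rates = [f.pi if f.call == "mixture" else 0.0 for f in fits]
        called = [f for f in fits if f.call == "mixture"]
        ratios = [f.ils_hybridization_ratio for f in called
                  if np.isfinite(f.ils_hybridization_ratio)]
        mean_rate = float(np.mean(rates))
        pair_rows.append({
            "pair_a": a, "pair_b": b, "n_fits": len(fits),
            "mean_nonils_rate": mean_rate,
            "mixture_fraction": len(called) / len(fits),
            "mean_ils_hyb_ratio": float(np.mean(ratios)) if ratios else np.nan,
            "flagged": mean_rate > rate_threshold})
    pair_table = pd.DataFrame(
        pair_rows, columns=["pair_a", "pair_b", "n_fits", "mean_nonils_rate",
                            "mixture_fraction", "mean_ils_hyb_ratio",
                            "flagged"])
    return ProtocolResult(pair_table, pd.DataFrame(triplet_rows),
                          n_runs, trees_per_run, rate_threshold)


def _as_tree(species_tree) -> GeneTree:
    if isinstance(species_tree, GeneTree):
        return species_tree
    if isinstance(species_tree, SpeciesNetwork):
        return species_tree.to_gene_tree()
    if isinstance(species_tree, str):
        return SpeciesNetwork.from_newick(species_tree).to_gene_tree()
    raise TypeError(f"cannot interpret {type(species_tree)!r} as species tree")
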